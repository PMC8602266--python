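"""Repertoire-level statistics: diversity, rarefaction, public clonotypes,
ordination, networks, CDR3 spectra and expansion labels."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .tcr_io import Clonotype

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # entities x k
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int
    converged: bool  # stress < 0.1, the conventional acceptability bar


@dataclass
class ExpansionLabel:
    entity_id: str
    count_A: int
    count_B: int
    log2fc: float
    label: Literal["A_enriched", "B_enriched", "shared"]


def shannon_diversity(counts: Sequence[int]) -> float:
    """Shannon H = -sum p_i ln p_i over clone counts (natural log)."""
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("counts must be nonempty")
    if np.any(c <= 0):
        raise ValueError("all counts must be positive")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def rarefaction_curve(counts: Sequence[int], step: int = 20) -> list[tuple[int, float]]:
    """Analytic rarefaction: expected richness at subsample sizes m.

    E[S(m)] = sum_i (1 - C(N - n_i, m) / C(N, m)), the hypergeometric
    expectation of the number of clonotypes seen in a random m-cell
    subsample. Evaluated at m = step, 2*step, ..., always including m = N.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    n_total = int(c.sum())
    ms = list(range(step, n_total + 1, step))
    if not ms or ms[-1] != n_total:
        ms.append(n_total)
    out = []
    # log C(N - n_i, m) - log C(N, m), computed with gammaln for stability
    for m in ms:
        keep = (n_total - c) >= m
        logp = np.full(c.shape, -np.inf)
        nm = n_total - c[keep]
        logp[keep] = (gammaln(nm + 1) - gammaln(m + 1) - gammaln(nm - m + 1)
                      - (gammaln(n_total + 1) - gammaln(m + 1)
                         - gammaln(n_total - m + 1)))
        expected = float(np.sum(1.0 - np.exp(logp)))
        out.append((m, expected))
    return out


def public_clonotypes(matrix: pd.DataFrame,
                      condition_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Clonotypes present in >= 2 samples, with per-condition membership.

    ``matrix`` is clonotype x sample counts. Returns a frame with
    n_samples, the carrying conditions, and ``condition_shared`` flagging
    clonotypes seen in more than one condition.
    """
    present = matrix > 0
    n_samples = present.sum(axis=1)
    pub = matrix.loc[n_samples >= 2]
    rows = []
    for ct_id, row in pub.iterrows():
        samples = [s for s in matrix.columns if row[s] > 0]
        conditions = sorted({condition_map[s] for s in samples}) if condition_map else []
        rows.append({
            "clonotype_id": ct_id,
            "n_samples": len(samples),
            "total_cells": int(row.sum()),
            "samples": ";".join(samples),
            "conditions": ";".join(conditions),
            "condition_shared": len(conditions) > 1,
        })
    return pd.DataFrame(rows, columns=[
        "clonotype_id", "n_samples", "total_cells", "samples",
        "conditions", "condition_shared"])


def bray_curtis(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity between rows: sum|x-y| / sum(x+y).

    A pair of all-zero rows (0/0) is defined as dissimilarity 0.
    """
    x = np.asarray(matrix, dtype=float)
    return squareform(np.nan_to_num(pdist(x, metric="braycurtis"), nan=0.0))


def kruskal_stress(coordinates: np.ndarray, dissimilarity: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding via monotone (isotonic) regression."""
    d = pdist(coordinates)
    dis = squareform(np.asarray(dissimilarity, float))
    iso = IsotonicRegression()
    dhat = iso.fit_transform(dis, d)
    denom = float(np.sum(d ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def nmds(dissimilarity: np.ndarray, k: int = 2, seed: int = 0,
         n_restarts: int = 50, max_iter: int = 500) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorization with monotone regression.

    Best of ``n_restarts`` random initializations; the reported stress is
    Kruskal stress-1 recomputed from the winning configuration. A stress
    >= 0.1 is flagged (``converged=False``), the conventional bar for an
    acceptable ordination.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity must be non-negative and hollow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords, _ = smacof(
            D, metric=False, n_components=k, n_init=n_restarts,
            max_iter=max_iter, eps=1e-14, random_state=seed,
            normalized_stress=True)
    stress = kruskal_stress(coords, D)
    if stress >= 0.1:
        warnings.warn(f"NMDS stress {stress:.3f} >= 0.1: ordination unreliable")
    return OrdinationResult(coordinates=coords, stress=stress,
                            n_restarts=n_restarts, seed=seed,
                            converged=stress < 0.1)


def sample_clonotype_network(clonotypes: Sequence[Clonotype],
                             min_size: int = 10) -> nx.Graph:
    """Unweighted bipartite sample/clonotype graph of expanded clonotypes.

    Only clonotypes with size strictly greater than ``min_size`` become
    nodes; one edge per (sample, clonotype) with a positive cell count.
    """
    g = nx.Graph()
    for ct in clonotypes:
        if ct.size <= min_size:
            continue
        g.add_node(ct.clonotype_id, bipartite="clonotype", size=ct.size)
        for sample, count in ct.per_sample_counts.items():
            if count > 0:
                g.add_node(sample, bipartite="sample")
                g.add_edge(sample, ct.clonotype_id)
    return g


def expansion_labels(counts: pd.DataFrame, log2fc_threshold: float = 2.5,
                     size_floor: int = 10, pseudocount: float = 1.0,
                     condition_a: str | None = None,
                     condition_b: str | None = None) -> list[ExpansionLabel]:
    """Label entities as enriched in condition A, B, or shared.

    ``counts`` has two columns (A then B, or named by ``condition_a`` /
    ``condition_b``) of non-negative cell counts per entity. log2fc =
    log2((B + pc) / (A + pc)); an entity is enriched only when |log2fc|
    exceeds the threshold AND total count exceeds the size floor.
    """
    if condition_a is None or condition_b is None:
        condition_a, condition_b = counts.columns[:2]
    a = counts[condition_a].to_numpy()
    b = counts[condition_b].to_numpy()
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    log2fc = np.log2((b + pseudocount) / (a + pseudocount))
    out = []
    for ent, ca, cb, fc in zip(counts.index, a, b, log2fc):
        if abs(fc) > log2fc_threshold and (ca + cb) > size_floor:
            label = "B_enriched" if fc > 0 else "A_enriched"
        else:
            label = "shared"
        out.append(ExpansionLabel(entity_id=str(ent), count_A=int(ca),
                                  count_B=int(cb), log2fc=float(fc), label=label))
    return out


def cdr3_spectrum(cdr3s: Sequence[str],
                  length: int | None = None) -> tuple[pd.Series, pd.DataFrame]:
    """Length histogram plus a position frequency matrix at one length.

    Returns ``(histogram, pfm)`` where pfm is length x 20 relative
    frequencies (rows sum to 1) over sequences of the requested length
    (default: the modal length).
    """
    lengths = pd.Series([len(s) for s in cdr3s], dtype=int)
    hist = lengths.value_counts().sort_index()
    if length is None and len(hist):
        length = int(hist.idxmax())
    subset = [s for s in cdr3s if len(s) == length] if length else []
    pfm = pd.DataFrame(0.0, index=range(1, (length or 0) + 1), columns=list(AA))
    for s in subset:
        for i, a in enumerate(s):
            if a in pfm.columns:
                pfm.loc[i + 1, a] += 1.0
    if subset:
        pfm = pfm.div(pfm.sum(axis=1), axis=0)
    return hist, pfm


def geometric_mean_clone_size(clonotypes: Sequence[Clonotype] | Sequence[int]) -> float:
    """exp(mean(ln size)) over clonotypes (or raw sizes)."""
    sizes = np.asarray(
        [ct.size if isinstance(ct, Clonotype) else int(ct) for ct in clonotypes],
        dtype=float)
    if sizes.size == 0 or np.any(sizes <= 0):
        raise ValueError("sizes must be positive and nonempty")
    return float(np.exp(np.mean(np.log(sizes))))
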