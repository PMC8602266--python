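"""GLIPH-style TCR specificity grouping.

Clonotypes are clustered into predicted antigen-specificity groups two
ways: by *local* similarity — shared interior CDR3beta k-mers enriched
over a reference repertoire (one-sided Fisher exact test) — and by
*global* similarity — same-length CDR3beta pairs differing at a single
position with a non-negative BLOSUM62 substitution score. Groups are then
scored for V-gene bias and CDR3-length concentration and filtered on
clonotype count, sample span, V-bias p and a composite final score.

The final score here is the product of the motif, V-bias and length
Fisher p-values; it is interpretable in those terms but is not a numeric
replica of GLIPH2's published score.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

from .tcr_io import Clonotype

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class MotifHit:
    motif: str
    sample_count_in_query: int
    unique_cdr3_count_in_query: int
    count_in_reference: int
    fisher_p: float
    weight_flag: bool = False
    weight: float = 1.0


@dataclass
class SpecificityGroup:
    group_id: str
    seed: str  # motif string, or representative CDR3 for global clusters
    kind: str  # "local" | "global"
    member_clonotype_ids: list[str]
    n_unique_clonotypes: int
    n_samples: int
    per_condition_cell_counts: dict[str, int]
    motif_p: float = 1.0
    vgene_bias_p: float = 1.0
    length_p: float = 1.0
    final_score: float = 1.0
    passes_filter: bool = False
    enrichment_label: str = "shared"
    enrichment_log2fc: float = 0.0
    annotations: list[dict] = field(default_factory=list)
    annotation_ambiguous: bool = False


@dataclass
class ReferenceRepertoire:
    """Background CDR3beta repertoire with precomputed motif counts."""

    cdr3b: list[str]
    v_genes: list[str] | None = None
    motif_counts: dict[str, int] = field(default_factory=dict)
    n_unique: int = 0

    @classmethod
    def from_sequences(cls, cdr3b: Iterable[str], v_genes: Iterable[str] | None = None,
                       k_values: Sequence[int] = (2, 3, 4),
                       trim: tuple[int, int] = (3, 2)) -> "ReferenceRepertoire":
        seqs = list(cdr3b)
        unique = sorted(set(seqs))
        counts: Counter = Counter()
        for s in unique:
            for m in set(interior_kmers(s, k_values, trim)):
                counts[m] += 1
        if not unique:
            raise ValueError("reference repertoire is empty")
        return cls(cdr3b=seqs, v_genes=list(v_genes) if v_genes is not None else None,
                   motif_counts=dict(counts), n_unique=len(unique))

    @classmethod
    def from_table(cls, df: pd.DataFrame, **kwargs) -> "ReferenceRepertoire":
        v = df["v_gene"].tolist() if "v_gene" in df.columns else None
        return cls.from_sequences(df["cdr3b"].tolist(), v, **kwargs)


def interior_kmers(cdr3: str, k_values: Sequence[int] = (2, 3, 4),
                   trim: tuple[int, int] = (3, 2)) -> list[str]:
    """All k-mers of the trimmed CDR3 interior (drop first 3, last 2)."""
    interior = cdr3[trim[0]: len(cdr3) - trim[1]]
    out = []
    for k in k_values:
        out.extend(interior[i:i + k] for i in range(len(interior) - k + 1))
    return out


def extract_motifs(cdr3b_samples: Sequence[tuple[str, str]],
                   k_values: Sequence[int] = (2, 3, 4),
                   trim: tuple[int, int] = (3, 2)) -> pd.DataFrame:
    """Count interior k-mers over (cdr3b, sample_id) observations.

    Returns a frame indexed by motif with raw occurrence count, the number
    of distinct CDR3s containing the motif, and per-sample presence.
    Duplicate CDR3s inflate ``n_total`` but not ``n_unique_cdr3``.
    """
    raw: Counter = Counter()
    unique_cdr3: dict[str, set[str]] = defaultdict(set)
    samples: dict[str, set[str]] = defaultdict(set)
    for cdr3, sample in cdr3b_samples:
        kmers = interior_kmers(cdr3, k_values, trim)
        for m in kmers:
            raw[m] += 1
        for m in set(kmers):
            unique_cdr3[m].add(cdr3)
            samples[m].add(sample)
    rows = [{"motif": m, "k": len(m), "n_total": raw[m],
             "n_unique_cdr3": len(unique_cdr3[m]), "n_samples": len(samples[m])}
            for m in sorted(raw)]
    return pd.DataFrame(rows, columns=["motif", "k", "n_total",
                                       "n_unique_cdr3", "n_samples"]).set_index("motif")


def fisher_greater(a: int, n_query: int, c: int, n_ref: int) -> float:
    """One-sided (greater) Fisher exact p for motif over-representation.

    2x2 table: [a, n_query - a; c, n_ref - c]. p = P(X >= a) under the
    hypergeometric null with N = n_query + n_ref, K = a + c draws of
    n_query.
    """
    if a == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, n_query + n_ref, a + c, n_query))


def motif_enrichment(query_motifs: pd.DataFrame, reference: ReferenceRepertoire,
                     n_query_unique: int, k_test: Sequence[int] = (3, 4),
                     nontemplated_motifs: set[str] | None = None,
                     np_weight: float = 2.0) -> list[MotifHit]:
    """Fisher-exact motif enrichment of the query over the reference.

    ``query_motifs`` comes from :func:`extract_motifs`; counts are unique
    CDR3 counts on both sides. Motifs whose codons are non-templated (set
    supplied by the caller from nucleotide evidence) get a multiplicative
    ranking weight, never an altered p-value.
    """
    sub = query_motifs[query_motifs["k"].isin(list(k_test))]
    a = sub["n_unique_cdr3"].to_numpy(np.int64)
    c = np.array([reference.motif_counts.get(m, 0) for m in sub.index], np.int64)
    nq, nr = n_query_unique, reference.n_unique
    p = hypergeom.sf(a - 1, nq + nr, a + c, nq)
    p = np.where(a == 0, 1.0, p)
    hits = []
    flagged = nontemplated_motifs or set()
    for motif, ai, ci, pi, ns in zip(sub.index, a, c, p, sub["n_samples"]):
        flag = motif in flagged
        hits.append(MotifHit(
            motif=motif, sample_count_in_query=int(ns),
            unique_cdr3_count_in_query=int(ai), count_in_reference=int(ci),
            fisher_p=float(min(pi, 1.0)), weight_flag=flag,
            weight=np_weight if flag else 1.0))
    hits.sort(key=lambda h: (h.fisher_p / h.weight, h.motif))
    return hits


def non_templated_positions(cdr3_nt: str, v_nt: str, j_nt: str) -> set[int]:
    """Amino-acid positions of a CDR3 whose codons are not germline-templated.

    Germline coverage is the longest common prefix with the V segment and
    the longest common suffix with the J segment; codons containing any
    nucleotide outside both are non-templated (N/P additions).
    """
    n = len(cdr3_nt)
    pre = 0
    while pre < min(n, len(v_nt)) and cdr3_nt[pre] == v_nt[pre]:
        pre += 1
    suf = 0
    while suf < min(n - pre, len(j_nt)) and cdr3_nt[n - 1 - suf] == j_nt[len(j_nt) - 1 - suf]:
        suf += 1
    return {i // 3 for i in range(pre, n - suf)}


def global_clusters(cdr3b: Sequence[str]) -> list[list[str]]:
    """Connected components of the single-substitution similarity graph.

    Edges join equal-length CDR3betas at Hamming distance <= 1 whose
    substituted position scores >= 0 in BLOSUM62. Components qualify when
    they span >= 2 sequences counting duplicates.
    """
    multiplicity = Counter(cdr3b)
    by_len: dict[int, list[str]] = defaultdict(list)
    for s in sorted(multiplicity):
        by_len[len(s)].append(s)
    g = nx.Graph()
    g.add_nodes_from(multiplicity)
    for seqs in by_len.values():
        if len(seqs) < 2:
            continue
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
        for i in range(len(seqs)):
            diff = arr[i + 1:] != arr[i]
            nd = diff.sum(axis=1)
            for off in np.nonzero(nd <= 1)[0]:
                j = i + 1 + off
                if nd[off] == 0:
                    g.add_edge(seqs[i], seqs[j])
                    continue
                pos = int(np.nonzero(diff[off])[0][0])
                x, y = seqs[i][pos], seqs[j][pos]
                try:
                    score = _BLOSUM62[x, y]
                except IndexError:  # letter outside the matrix alphabet
                    continue
                if score >= 0:
                    g.add_edge(seqs[i], seqs[j])
    clusters = []
    for comp in nx.connected_components(g):
        total = sum(multiplicity[s] for s in comp)
        if total >= 2 and (len(comp) >= 2 or multiplicity[next(iter(comp))] >= 2):
            clusters.append(sorted(comp))
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def _group_counts(members: list[Clonotype]) -> tuple[int, dict[str, int]]:
    samples = set()
    cond: Counter = Counter()
    for ct in members:
        samples.update(ct.per_sample_counts)
        cond.update(ct.per_condition_counts)
    return len(samples), dict(sorted(cond.items()))


def assemble_groups(hits: Sequence[MotifHit], clusters: Sequence[Sequence[str]],
                    clonotypes: Sequence[Clonotype], p_motif: float = 1e-3,
                    trim: tuple[int, int] = (3, 2)) -> list[SpecificityGroup]:
    """One group per significant motif plus one per global cluster.

    Local members are clonotypes whose trimmed CDR3beta interior contains
    the motif; clonotypes may belong to any number of groups.
    """
    by_cdr3b: dict[str, list[Clonotype]] = defaultdict(list)
    for ct in clonotypes:
        by_cdr3b[ct.cdr3b_aa].append(ct)
    groups: list[SpecificityGroup] = []
    idx = 0
    for hit in hits:
        if hit.fisher_p >= p_motif:
            continue
        members = [ct for ct in clonotypes
                   if hit.motif in ct.cdr3b_aa[trim[0]: len(ct.cdr3b_aa) - trim[1]]]
        if not members:
            continue
        idx += 1
        n_samples, cond = _group_counts(members)
        groups.append(SpecificityGroup(
            group_id=f"SG{idx:05d}", seed=hit.motif, kind="local",
            member_clonotype_ids=[ct.clonotype_id for ct in members],
            n_unique_clonotypes=len(members), n_samples=n_samples,
            per_condition_cell_counts=cond, motif_p=hit.fisher_p))
    for cluster in clusters:
        members = [ct for s in cluster for ct in by_cdr3b.get(s, [])]
        if not members:
            continue
        idx += 1
        n_samples, cond = _group_counts(members)
        groups.append(SpecificityGroup(
            group_id=f"SG{idx:05d}", seed=cluster[0], kind="global",
            member_clonotype_ids=[ct.clonotype_id for ct in members],
            n_unique_clonotypes=len(members), n_samples=n_samples,
            per_condition_cell_counts=cond, motif_p=1.0))
    return groups


def _concentration_p(member_values: Sequence, repertoire_values: Sequence) -> float:
    """Fisher tail for over-concentration of the members' modal value."""
    if not member_values:
        return 1.0
    counts = Counter(member_values)
    modal = min(counts, key=lambda v: (-counts[v], str(v)))
    k = counts[modal]
    rep_values = list(repertoire_values)
    rep = Counter(rep_values)
    K = rep.get(modal, k)
    N = max(len(rep_values), 1)
    n = len(member_values)
    return float(hypergeom.sf(k - 1, N, K, n))


def vgene_bias(group: SpecificityGroup, clonotypes: Mapping[str, Clonotype]) -> float:
    """One-sided Fisher p for over-representation of the group's modal TRBV."""
    members = [clonotypes[i] for i in group.member_clonotype_ids]
    return _concentration_p([ct.vb_gene for ct in members],
                            [ct.vb_gene for ct in clonotypes.values()])


def length_bias(group: SpecificityGroup, clonotypes: Mapping[str, Clonotype]) -> float:
    """Fisher p for CDR3beta-length concentration of members vs repertoire."""
    members = [clonotypes[i] for i in group.member_clonotype_ids]
    return _concentration_p([len(ct.cdr3b_aa) for ct in members],
                            [len(ct.cdr3b_aa) for ct in clonotypes.values()])


def final_score(group: SpecificityGroup) -> float:
    """Product of the motif, V-bias and length p-values (smaller = stronger)."""
    return group.motif_p * group.vgene_bias_p * group.length_p


def score_groups(groups: Sequence[SpecificityGroup],
                 clonotypes: Sequence[Clonotype]) -> None:
    """Fill vgene_bias_p, length_p and final_score in place."""
    by_id = {ct.clonotype_id: ct for ct in clonotypes}
    for g in groups:
        g.vgene_bias_p = vgene_bias(g, by_id)
        g.length_p = length_bias(g, by_id)
        g.final_score = final_score(g)


def filter_groups(groups: Sequence[SpecificityGroup], min_clonotypes: int = 4,
                  min_samples: int = 3, vgene_p: float = 0.05,
                  final: float = 1e-5) -> list[SpecificityGroup]:
    """Apply the group filters; sets ``passes_filter`` and returns passers.

    Defaults follow the stricter published filter (>= 4 unique clonotypes
    from >= 3 samples, V-bias p < 0.05, final score < 1e-5); the
    alternative >= 4 *samples* variant is reachable via ``min_samples``.
    """
    passing = []
    for g in groups:
        g.passes_filter = (
            g.n_unique_clonotypes >= min_clonotypes
            and g.n_samples >= min_samples
            and g.vgene_bias_p < vgene_p
            and g.final_score < final)
        if g.passes_filter:
            passing.append(g)
    return passing


def run_gliph(clonotypes: Sequence[Clonotype], reference: ReferenceRepertoire,
              k_values: Sequence[int] = (2, 3, 4), k_test: Sequence[int] = (3, 4),
              trim: tuple[int, int] = (3, 2), p_motif: float = 1e-3,
              min_clonotypes: int = 4, min_samples: int = 3,
              vgene_p: float = 0.05, final: float = 1e-5,
              ) -> tuple[list[SpecificityGroup], list[MotifHit]]:
    """Full specificity-grouping pass over a clonotype repertoire."""
    obs = [(ct.cdr3b_aa, s) for ct in clonotypes for s in ct.per_sample_counts]
    motifs = extract_motifs(obs, k_values, trim)
    n_unique = len({ct.cdr3b_aa for ct in clonotypes})
    hits = motif_enrichment(motifs, reference, n_unique, k_test)
    clusters = global_clusters([ct.cdr3b_aa for ct in clonotypes])
    groups = assemble_groups(hits, clusters, clonotypes, p_motif, trim)
    score_groups(groups, clonotypes)
    filter_groups(groups, min_clonotypes, min_samples, vgene_p, final)
    return groups, hits


def groups_to_frame(groups: Sequence[SpecificityGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append({
            "group_id": g.group_id, "seed": g.seed, "kind": g.kind,
            "n_unique_clonotypes": g.n_unique_clonotypes,
            "n_samples": g.n_samples,
            "condition_cells": ";".join(f"{k}:{v}" for k, v in
                                        g.per_condition_cell_counts.items()),
            "motif_p": g.motif_p, "vgene_bias_p": g.vgene_bias_p,
            "length_p": g.length_p, "final_score": g.final_score,
            "passes_filter": g.passes_filter,
            "enrichment_label": g.enrichment_label,
            "enrichment_log2fc": g.enrichment_log2fc,
            "annotations": ";".join(a.get("peptide", "") for a in g.annotations),
            "annotation_ambiguous": g.annotation_ambiguous,
            "members": ";".join(g.member_clonotype_ids),
        })
    return pd.DataFrame(rows)
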