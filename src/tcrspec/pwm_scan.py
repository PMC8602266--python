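"""Position-weighted-matrix antigen prediction.

Peptides annotated to preferentially expanded clonotypes (clone size > 3,
log2 fold-change sign matching the condition of interest) are weighted by
clone size x fold enrichment and summarized as a 9 x 20 matrix of
positional amino-acid enrichment ratios over a background composition.
Every 9-mer window of a proteome is then scored by the log-sum of its
positional ratios, with empirical significance taken over the realized
distribution of all window scores and a Bonferroni correction across
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}
PEPTIDE_LENGTH = 9


@dataclass(frozen=True)
class WeightedPeptide:
    peptide: str
    weight: float

    def __post_init__(self) -> None:
        if len(self.peptide) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide {self.peptide!r} is not 9 aa")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class PWM:
    """9 x 20 positional enrichment ratios over a background composition."""

    matrix: np.ndarray  # ratios, strictly positive
    background: np.ndarray  # length-20 frequency vector
    pseudocount: float
    n_training_peptides: int
    condition: str = ""

    def __post_init__(self) -> None:
        assert self.matrix.shape == (PEPTIDE_LENGTH, 20)
        assert np.all(np.isfinite(self.matrix)) and np.all(self.matrix > 0)


@dataclass
class ProteomeHit:
    protein_id: str
    start: int  # 1-based
    peptide: str
    score: float
    p: float
    p_bonferroni: float


def select_weighted_peptides(
    annotations: pd.DataFrame,
    expansion: pd.DataFrame,
    condition: Literal["A", "B"],
    min_clone_size: int = 3,
) -> list[WeightedPeptide]:
    """Pick 9-mer peptides of expanded clonotypes, weighted for PWM training.

    ``annotations`` carries (clonotype_id, peptide) from exact database
    matching; ``expansion`` is indexed by clonotype_id with columns
    ``size`` and ``log2fc``. Kept: clone size strictly greater than
    ``min_clone_size`` and log2fc sign matching the condition (negative
    for A, positive for B). Weight = clone_size x 2^|log2fc| — fold
    enrichment on the linear scale.
    """
    out = []
    for row in annotations.itertuples(index=False):
        if row.clonotype_id not in expansion.index:
            continue
        size = float(expansion.loc[row.clonotype_id, "size"])
        fc = float(expansion.loc[row.clonotype_id, "log2fc"])
        if size <= min_clone_size:
            continue
        if (condition == "B" and fc <= 0) or (condition == "A" and fc >= 0):
            continue
        if len(row.peptide) != PEPTIDE_LENGTH or not set(row.peptide) <= set(AA):
            continue
        out.append(WeightedPeptide(peptide=row.peptide,
                                   weight=size * 2.0 ** abs(fc)))
    return out


def build_pwm(peptides: Sequence[WeightedPeptide],
              background: np.ndarray | None = None,
              pseudocount: float = 0.01,
              condition: str = "") -> PWM:
    """Weighted positional enrichment ratios from training peptides.

    f(j,a) = (sum of weights with a at j + pc) / (total weight + 20 pc);
    entry(j,a) = f(j,a) / background(a). Uniform background by default;
    pass the scanned proteome's composition to normalize against it.
    Weights are first rescaled to mean 1 so only their ratios matter: the
    PWM is exactly invariant under global weight rescaling.
    """
    if not peptides:
        raise ValueError("cannot build a PWM from zero peptides")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, float)
    raw_total = sum(wp.weight for wp in peptides)
    scale = len(peptides) / raw_total
    counts = np.zeros((PEPTIDE_LENGTH, 20))
    for wp in peptides:
        for j, a in enumerate(wp.peptide):
            counts[j, _AA_INDEX[a]] += wp.weight * scale
    total = float(len(peptides))
    freq = (counts + pseudocount) / (total + 20 * pseudocount)
    return PWM(matrix=freq / background, background=background,
               pseudocount=pseudocount, n_training_peptides=len(peptides),
               condition=condition)


def score_peptide(pwm: PWM, peptide: str) -> float:
    """Log-sum of positional enrichment ratios of a 9-mer."""
    if len(peptide) != PEPTIDE_LENGTH:
        raise ValueError("peptide must be 9 aa")
    idx = [_AA_INDEX[a] for a in peptide]
    return float(np.log(pwm.matrix[np.arange(PEPTIDE_LENGTH), idx]).sum())


def proteome_composition(proteins: Mapping[str, str]) -> np.ndarray:
    """Amino-acid frequency vector of a proteome (unknown letters ignored)."""
    counts = np.zeros(20)
    for seq in proteins.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for a, i in _AA_INDEX.items():
            counts[i] += int((arr == ord(a)).sum())
    total = counts.sum()
    return counts / total if total else np.full(20, 1.0 / 20)


def read_proteome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Scores and start offsets of all valid 9-mer windows of one protein."""
    n = len(seq)
    if n < PEPTIDE_LENGTH:
        return np.empty(0), np.empty(0, int)
    code = np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)
    valid = code >= 0
    logm = np.log(pwm.matrix)
    starts = np.arange(n - PEPTIDE_LENGTH + 1)
    window_idx = starts[:, None] + np.arange(PEPTIDE_LENGTH)[None, :]
    ok = valid[window_idx].all(axis=1)
    starts = starts[ok]
    scores = logm[np.arange(PEPTIDE_LENGTH)[None, :],
                  code[window_idx[ok]]].sum(axis=1)
    return scores, starts


def scan_proteome(pwm: PWM, proteins: Mapping[str, str],
                  p_mode: Literal["empirical_all_windows", "shuffled_pwm"] = "empirical_all_windows",
                  top_n: int | None = None, p_threshold: float | None = None,
                  seed: int = 0, n_shuffles: int = 100,
                  ) -> tuple[list[ProteomeHit], int]:
    """Score every 9-residue window and attach empirical significance.

    p(window) = (number of windows scoring >= it) / n_windows under the
    realized all-windows null (ties share the larger rank), so the unique
    best window has p = 1/n_windows; Bonferroni = min(1, p * n_windows).
    ``shuffled_pwm`` instead draws the null scores from column-shuffled
    copies of the PWM applied to the same windows. Windows containing
    letters outside the 20-aa alphabet are skipped. Returns the hits
    (sorted by score, optionally cut by ``top_n`` or ``p_threshold``) and
    the total number of windows scored.
    """
    all_scores: list[np.ndarray] = []
    index: list[tuple[str, int]] = []
    for pid in proteins:
        scores, starts = _window_scores(pwm, proteins[pid])
        all_scores.append(scores)
        index.extend((pid, int(s)) for s in starts)
    if not index:
        return [], 0
    scores = np.concatenate(all_scores)
    n_windows = len(scores)

    if p_mode == "empirical_all_windows":
        null = scores
    else:
        rng = np.random.default_rng(seed)
        null_parts = []
        for _ in range(n_shuffles):
            shuffled = PWM(matrix=rng.permuted(pwm.matrix, axis=0),
                           background=pwm.background, pseudocount=pwm.pseudocount,
                           n_training_peptides=pwm.n_training_peptides)
            null_parts.extend(_window_scores(shuffled, proteins[pid])[0]
                              for pid in proteins)
        null = np.concatenate(null_parts)
    # p = fraction of null scores >= observed, ties counted
    order = np.sort(null)
    ge = len(null) - np.searchsorted(order, scores, side="left")
    p = ge / len(null)
    p = np.maximum(p, 1.0 / len(null))
    bonf = np.minimum(1.0, p * n_windows)

    rank = np.argsort(-scores, kind="stable")
    if top_n is not None:
        rank = rank[:top_n]
    hits = []
    for i in rank:
        if p_threshold is not None and p[i] > p_threshold:
            continue
        pid, start = index[i]
        hits.append(ProteomeHit(
            protein_id=pid, start=start + 1,
            peptide=proteins[pid][start: start + PEPTIDE_LENGTH],
            score=float(scores[i]), p=float(p[i]), p_bonferroni=float(bonf[i])))
    return hits, n_windows


def hits_to_frame(hits: Sequence[ProteomeHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"protein_id": h.protein_id, "start": h.start, "peptide": h.peptide,
          "score": h.score, "p": h.p, "p_bonferroni": h.p_bonferroni}
         for h in hits],
        columns=["protein_id", "start", "peptide", "score", "p", "p_bonferroni"])
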