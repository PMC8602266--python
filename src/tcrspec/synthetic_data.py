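"""Synthetic paired scTCR/scRNA data with recorded ground truth.

Emulates the study design the pipeline targets: 10 bone-marrow-chimera
samples in two conditions (5 non-autoimmune "WT", 5 autoimmune "AUTO"),
power-law clone-size distributions per sample, a small set of public
clonotypes shared between conditions, planted CDR3beta specificity motifs
(shared or condition-biased), a gene-expression matrix containing genes
whose log-mean is monotone in log clone size or shifted by condition, an
annotated CDR3beta reference database carrying the planted motifs, and a
toy proteome with planted 9-mer target peptides.

All randomness flows from ``SynthConfig.seed``; every generator derives an
independent numpy ``Generator`` from (seed, stream) so the four generators
are individually reproducible and mutually consistent (the reference
database and proteome re-derive the same motif-associated peptides).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

AA = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per amino acid, for back-translated cdr3_nt columns
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_DEFAULT_TRBV = [f"TRBV{i}" for i in (1, 2, 3, 4, 5, 12, 13, 16, 19, 31)]
_DEFAULT_TRBJ = [f"TRBJ{i}" for i in (1, 2)]
_DEFAULT_TRAV = [f"TRAV{i}" for i in (1, 3, 6, 7, 9, 12, 14)]
_DEFAULT_TRAJ = [f"TRAJ{i}" for i in (12, 15, 21, 31)]

_CLUSTERS = ["TFH", "TFR", "TFH_CM", "TFH_eff"]

# rng stream ids; keeping them fixed makes each generator reproducible alone
_S_REPERTOIRE, _S_PEPTIDES, _S_GENES, _S_EXPR, _S_REFDB, _S_PROTEOME, _S_REFREP = (
    11, 101, 201, 202, 301, 401, 501)


@dataclass
class PlantedMotif:
    """A CDR3beta k-mer to plant, its condition bias, and carrier fraction."""

    motif: str
    bias: Literal["shared", "WT", "AUTO"] = "shared"
    carrier_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (2 <= len(self.motif) <= 4):
            raise ValueError(f"motif {self.motif!r}: length must be 2-4 aa")
        if not set(self.motif) <= set(AA):
            raise ValueError(f"motif {self.motif!r}: non-standard letters")
        if not (0 < self.carrier_fraction <= 1):
            raise ValueError(f"motif {self.motif!r}: carrier fraction not in (0,1]")


@dataclass
class SynthConfig:
    n_samples_per_condition: int = 5
    clones_per_sample: int = 300
    clone_size_alpha: float = 2.5
    clone_size_max: int = 50
    n_public_clonotypes: int = 8
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    v_gene_pool: list[str] = field(default_factory=lambda: list(_DEFAULT_TRBV))
    j_gene_pool: list[str] = field(default_factory=lambda: list(_DEFAULT_TRBJ))
    cdr3_length_range: tuple[int, int] = (10, 17)
    decoy_fraction: float = 0.0
    #: probability a motif carrier draws its motif's dedicated TRBV gene
    #: (specificity groups share V usage in real repertoires; 0 disables)
    carrier_v_bias: float = 0.9
    n_genes: int = 200
    n_size_correlated_genes: int = 10
    n_condition_shifted_genes: int = 5
    effect_size: float = 1.0
    nb_dispersion: float = 0.5
    n_target_peptides: int = 5
    proteome_n_proteins: int = 200
    protein_length: int = 300
    refdb_background_entries: int = 300
    refdb_entries_per_motif: int = 30
    refdb_n_duplicates: int = 10
    refdb_n_invalid: int = 5
    reference_repertoire_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size_alpha <= 1:
            raise ValueError("clone_size_alpha must exceed 1")
        if self.cdr3_length_range[0] < 6:
            raise ValueError("cdr3 lengths must be >= 6")
        if self.n_size_correlated_genes + self.n_condition_shifted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")

    @property
    def samples(self) -> list[tuple[str, str]]:
        n = self.n_samples_per_condition
        return ([(f"WT{i + 1}", "WT") for i in range(n)]
                + [(f"AUTO{i + 1}", "AUTO") for i in range(n)])

    @property
    def condition_map(self) -> dict[str, str]:
        return dict(self.samples)


@dataclass
class GroundTruth:
    """Everything planted, keyed so downstream recovery can be scored."""

    motif_carriers: dict[str, list[tuple[str, str]]]
    motif_bias: dict[str, str]
    motif_peptide: dict[str, str]
    public_clonotypes: list[tuple[str, str]]
    cells: pd.DataFrame  # sample_id, barcode, condition, cdr3a, cdr3b, clone_size
    condition_map: dict[str, str]
    size_correlated_genes: dict[str, tuple[int, float]]  # gene -> (sign, effect)
    condition_shifted_genes: dict[str, tuple[int, float]]
    peptide_placements: dict[str, list[tuple[str, int]]]  # peptide -> [(protein, 0-based pos)]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _zipf_sizes(rng: np.random.Generator, n: int, alpha: float, smax: int) -> np.ndarray:
    s = np.arange(1, smax + 1, dtype=float)
    p = s ** -alpha
    p /= p.sum()
    return rng.choice(np.arange(1, smax + 1), size=n, p=p)


def _random_cdr3(rng: np.random.Generator, length: int, prefix: str = "CAS") -> str:
    body = "".join(rng.choice(list(AA), size=length - len(prefix) - 1))
    return prefix + body + "F"


def _back_translate(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def _insert_motif(rng: np.random.Generator, cdr3: str, motif: str) -> str:
    """Replace an interior window with the motif.

    The motif is placed fully inside the trimmed interior (never touching
    the first 3 or last 2 residues), matching the k-mer extractor's
    trimming convention.
    """
    k = len(motif)
    lo, hi = 3, len(cdr3) - 2 - k
    if hi < lo:
        raise ValueError(f"CDR3 {cdr3!r} too short to host motif {motif!r}")
    start = int(rng.integers(lo, hi + 1))
    return cdr3[:start] + motif + cdr3[start + k:]


def _gene_truth(config: SynthConfig) -> tuple[dict[str, tuple[int, float]],
                                              dict[str, tuple[int, float]]]:
    rng = _rng(config, _S_GENES)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_planted = config.n_size_correlated_genes + config.n_condition_shifted_genes
    picked = rng.choice(config.n_genes, size=n_planted, replace=False)
    corr_idx = picked[: config.n_size_correlated_genes]
    shift_idx = picked[config.n_size_correlated_genes:]
    corr = {}
    for j, gi in enumerate(corr_idx):
        sign = 1 if j % 2 == 0 else -1
        corr[genes[gi]] = (sign, config.effect_size)
    shifted = {genes[gi]: (1, config.effect_size) for gi in shift_idx}
    return corr, shifted


def _motif_peptides(config: SynthConfig) -> dict[str, str]:
    """A 9-mer peptide per planted motif (shared by refdb and proteome)."""
    rng = _rng(config, _S_PEPTIDES)
    out = {}
    for pm in config.planted_motifs:
        out[pm.motif] = "".join(rng.choice(list(AA), size=9))
    return out


def generate_repertoire(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a 10x-dialect contig table plus the planted ground truth.

    Every retained cell contributes one productive full-length TRA and one
    TRB contig; a Bernoulli(``decoy_fraction``) coin per cell converts it
    into an unpaired TRA-only decoy instead (dropped by the pairing
    filter, and excluded from ground-truth clone sizes).
    """
    rng = _rng(config, _S_REPERTOIRE)
    samples = config.samples
    lo, hi = config.cdr3_length_range

    # --- clonotype pool -------------------------------------------------
    # per sample: clones_per_sample clonotypes; public clonotypes occupy a
    # slot in one sample per condition.
    seen_pairs: set[tuple[str, str]] = set()

    def fresh_pair() -> tuple[str, str]:
        while True:
            a = _random_cdr3(rng, int(rng.integers(lo, hi + 1)), prefix="CAV")
            b = _random_cdr3(rng, int(rng.integers(lo, hi + 1)), prefix="CAS")
            if (a, b) not in seen_pairs:
                seen_pairs.add((a, b))
                return a, b

    n_pub = min(config.n_public_clonotypes, config.clones_per_sample)
    public = [fresh_pair() for _ in range(n_pub)]

    # clone list per sample: list of (cdr3a, cdr3b)
    per_sample_clones: dict[str, list[tuple[str, str]]] = {}
    wt_samples = [s for s, c in samples if c == "WT"]
    auto_samples = [s for s, c in samples if c == "AUTO"]
    pub_wt = [wt_samples[i % len(wt_samples)] for i in range(n_pub)]
    pub_auto = [auto_samples[i % len(auto_samples)] for i in range(n_pub)]
    for sample, _cond in samples:
        clones = [p for p, host in zip(public, pub_wt) if host == sample]
        clones += [p for p, host in zip(public, pub_auto) if host == sample]
        while len(clones) < config.clones_per_sample:
            clones.append(fresh_pair())
        per_sample_clones[sample] = clones[: config.clones_per_sample]

    # --- plant motifs ---------------------------------------------------
    motif_carriers: dict[str, list[tuple[str, str]]] = {}
    motif_bias: dict[str, str] = {}
    taken: set[tuple[str, str]] = set(public)
    for pm in config.planted_motifs:
        if pm.bias == "WT":
            eligible_samples = wt_samples
        elif pm.bias == "AUTO":
            eligible_samples = auto_samples
        else:
            eligible_samples = [s for s, _ in samples]
        candidates = [(s, pair) for s in eligible_samples
                      for pair in per_sample_clones[s] if pair not in taken]
        n_carriers = round(pm.carrier_fraction * len(candidates))
        if n_carriers < 4 or len({s for s, _ in candidates}) < 3:
            raise ValueError(
                f"motif {pm.motif!r}: carrier_fraction x clones gives "
                f"{n_carriers} carriers; cannot satisfy >=4 clonotypes over "
                f">=3 samples")
        idx = rng.choice(len(candidates), size=n_carriers, replace=False)
        chosen = [candidates[i] for i in idx]
        # guarantee the >=3 sample span deterministically
        span = {s for s, _ in chosen}
        if len(span) < 3:
            for s in eligible_samples:
                if s in span:
                    continue
                extra = [(s, p) for p in per_sample_clones[s]
                         if p not in taken and (s, p) not in chosen]
                if extra:
                    chosen[-1] = extra[0]
                    span = {x for x, _ in chosen}
                if len(span) >= 3:
                    break
        carriers = []
        for s, (a, b) in chosen:
            nb = _insert_motif(rng, b, pm.motif)
            while (a, nb) in seen_pairs:
                nb = _insert_motif(
                    rng, _random_cdr3(rng, int(rng.integers(lo, hi + 1))), pm.motif)
            seen_pairs.add((a, nb))
            i = per_sample_clones[s].index((a, b))
            per_sample_clones[s][i] = (a, nb)
            taken.add((a, nb))
            carriers.append((a, nb))
        motif_carriers[pm.motif] = sorted(set(carriers))
        motif_bias[pm.motif] = pm.bias

    # --- V/J assignment (per clonotype, stable across samples) ----------
    # each motif gets a dedicated TRBV gene; its carriers draw that gene
    # with probability carrier_v_bias, emulating the V-gene sharing of
    # real specificity groups
    all_pairs = sorted({p for clones in per_sample_clones.values() for p in clones})
    carrier_v: dict[tuple[str, str], str] = {}
    for mi, pm in enumerate(config.planted_motifs):
        gene = config.v_gene_pool[mi % len(config.v_gene_pool)]
        for pair in motif_carriers[pm.motif]:
            carrier_v[pair] = gene
    vj: dict[tuple[str, str], tuple[str, str, str, str]] = {}
    for pair in all_pairs:
        if pair in carrier_v and rng.random() < config.carrier_v_bias:
            vb = carrier_v[pair]
        else:
            vb = str(rng.choice(config.v_gene_pool))
        vj[pair] = (
            str(rng.choice(_DEFAULT_TRAV)), str(rng.choice(_DEFAULT_TRAJ)),
            vb, str(rng.choice(config.j_gene_pool)))

    # --- cells and contigs ----------------------------------------------
    condition_map = config.condition_map
    contig_rows: list[dict] = []
    cell_rows: list[dict] = []
    bc_counter = 0
    retained_per_clone: dict[tuple[str, tuple[str, str]], int] = {}
    for sample, cond in samples:
        sizes = _zipf_sizes(rng, config.clones_per_sample,
                            config.clone_size_alpha, config.clone_size_max)
        for pair, size in zip(per_sample_clones[sample], sizes):
            a, b = pair
            va, ja, vb, jb = vj[pair]
            retained = 0
            for _ in range(int(size)):
                bc_counter += 1
                barcode = f"BC{bc_counter:07d}-1"
                is_decoy = rng.random() < config.decoy_fraction
                umi_a, umi_b = rng.integers(1, 30, size=2)
                contig_rows.append({
                    "sample_id": sample, "barcode": barcode, "chain": "TRA",
                    "v_gene": va, "j_gene": ja, "cdr3": a,
                    "cdr3_nt": _back_translate(a), "full_length": True,
                    "productive": True, "umis": int(umi_a)})
                if is_decoy:
                    continue
                retained += 1
                contig_rows.append({
                    "sample_id": sample, "barcode": barcode, "chain": "TRB",
                    "v_gene": vb, "j_gene": jb, "cdr3": b,
                    "cdr3_nt": _back_translate(b), "full_length": True,
                    "productive": True, "umis": int(umi_b)})
                cell_rows.append({
                    "sample_id": sample, "barcode": barcode, "condition": cond,
                    "cdr3a": a, "cdr3b": b})
            retained_per_clone[(sample, pair)] = retained

    cells = pd.DataFrame(
        cell_rows, columns=["sample_id", "barcode", "condition", "cdr3a", "cdr3b"])
    # clone size = retained cells over ALL samples sharing the pair
    if len(cells):
        sizes_by_pair = cells.groupby(["cdr3a", "cdr3b"]).size()
        cells["clone_size"] = sizes_by_pair.loc[
            pd.MultiIndex.from_frame(cells[["cdr3a", "cdr3b"]])].to_numpy()
    else:
        cells["clone_size"] = pd.Series(dtype=int)

    corr, shifted = _gene_truth(config)
    gt = GroundTruth(
        motif_carriers=motif_carriers,
        motif_bias=motif_bias,
        motif_peptide=_motif_peptides(config),
        public_clonotypes=public,
        cells=cells,
        condition_map=condition_map,
        size_correlated_genes=corr,
        condition_shifted_genes=shifted,
        peptide_placements={},
    )
    contigs = pd.DataFrame(contig_rows, columns=[
        "sample_id", "barcode", "chain", "v_gene", "j_gene", "cdr3",
        "cdr3_nt", "full_length", "productive", "umis"])
    return contigs, gt


def check_ground_truth(gt: GroundTruth) -> None:
    """Verify that every planted motif spans >=4 clonotypes and >=3 samples."""
    cells = gt.cells
    for motif, carriers in gt.motif_carriers.items():
        carriers = [c for c in carriers
                    if ((cells.cdr3a == c[0]) & (cells.cdr3b == c[1])).any()]
        if len(carriers) < 4:
            raise AssertionError(f"motif {motif}: only {len(carriers)} carrier clonotypes")
        carrier_cells = cells[
            cells.set_index(["cdr3a", "cdr3b"]).index.isin(carriers)]
        n_samples = carrier_cells["sample_id"].nunique()
        if n_samples < 3:
            raise AssertionError(f"motif {motif}: carriers span only {n_samples} samples")


def generate_expression(
    cells: pd.DataFrame, config: SynthConfig
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Negative-binomial counts with planted clone-size and condition effects.

    Returns ``(counts, obs, genes)``: counts is cells x genes; obs carries
    barcode, sample_id, condition, cluster and clone_size. For each planted
    size-correlated gene the log-mean is ``base + sign * effect *
    log(clone_size)``; condition-shifted genes gain ``effect`` in the AUTO
    condition; all other genes are independent of both.
    """
    if config.n_size_correlated_genes > config.n_genes:
        raise ValueError("n_size_correlated_genes exceeds n_genes")
    rng = _rng(config, _S_EXPR)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    corr, shifted = _gene_truth(config)
    n_cells = len(cells)
    base = rng.normal(np.log(0.5), 0.4, size=config.n_genes)
    log_mu = np.tile(base, (n_cells, 1))
    log_size = np.log(cells["clone_size"].to_numpy(float))
    is_auto = (cells["condition"].to_numpy() == "AUTO").astype(float)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, (sign, eff) in corr.items():
        log_mu[:, gene_index[g]] += sign * eff * log_size
    for g, (sign, eff) in shifted.items():
        log_mu[:, gene_index[g]] += sign * eff * is_auto
    mu = np.exp(log_mu)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    obs = cells[["barcode", "sample_id", "condition", "clone_size"]].copy()
    obs["cluster"] = rng.choice(_CLUSTERS, size=n_cells)
    obs["clonotype_key"] = cells["cdr3a"] + "|" + cells["cdr3b"]
    return counts.astype(np.int64), obs.reset_index(drop=True), genes


def generate_reference_db(config: SynthConfig,
                          ground_truth: GroundTruth | None = None) -> pd.DataFrame:
    """Annotated CDR3beta reference table carrying the planted motifs.

    Emulates a harmonized union of public TCR-antigen databases. Each
    planted motif contributes ``refdb_entries_per_motif`` entries annotated
    to its ground-truth peptide; background entries carry random CDR3s and
    peptides. When ``ground_truth`` is supplied, the carrier clonotypes'
    own CDR3betas are also entered (annotated to the motif's peptide) so
    exact-match annotation has true positives. Deliberate exact-duplicate
    rows and rows with non-IUPAC characters are appended so database
    cleaning is exercised.
    """
    rng = _rng(config, _S_REFDB)
    peptides = _motif_peptides(config)
    lo, hi = config.cdr3_length_range
    rows = []
    diseases = [("influenza", "virus"), ("CMV", "virus"), ("M.tuberculosis", "bacteria"),
                ("T1D", "autoimmune"), ("melanoma", "cancer")]
    for i in range(config.refdb_background_entries):
        cdr3 = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        disease, dclass = diseases[int(rng.integers(len(diseases)))]
        rows.append({
            "cdr3b": cdr3,
            "peptide": "".join(rng.choice(list(AA), size=9)),
            "antigen": f"BGAG{i % 40:02d}",
            "disease": disease, "disease_class": dclass,
            "species": "HomoSapiens",
            "v_gene": str(rng.choice(config.v_gene_pool)),
            "j_gene": str(rng.choice(config.j_gene_pool)),
            "source": "synthdb-A" if i % 2 == 0 else "synthdb-B",
        })
    for m, pm in enumerate(config.planted_motifs):
        pep = peptides[pm.motif]
        for i in range(config.refdb_entries_per_motif):
            cdr3 = _insert_motif(
                rng, _random_cdr3(rng, int(rng.integers(max(lo, 11), hi + 1))),
                pm.motif)
            rows.append({
                "cdr3b": cdr3, "peptide": pep, "antigen": f"AG{m + 1:02d}",
                "disease": "autoimmunity", "disease_class": "autoimmune",
                "species": "MusMusculus",
                "v_gene": str(rng.choice(config.v_gene_pool)),
                "j_gene": str(rng.choice(config.j_gene_pool)),
                "source": "synthdb-A",
            })
    if ground_truth is not None:
        for m, pm in enumerate(config.planted_motifs):
            pep = peptides[pm.motif]
            for _a, b in ground_truth.motif_carriers.get(pm.motif, []):
                rows.append({
                    "cdr3b": b, "peptide": pep, "antigen": f"AG{m + 1:02d}",
                    "disease": "autoimmunity", "disease_class": "autoimmune",
                    "species": "MusMusculus",
                    "v_gene": str(rng.choice(config.v_gene_pool)),
                    "j_gene": str(rng.choice(config.j_gene_pool)),
                    "source": "synthdb-C",
                })
    df = pd.DataFrame(rows, columns=[
        "cdr3b", "peptide", "antigen", "disease", "disease_class",
        "species", "v_gene", "j_gene", "source"])
    if len(df):
        dup_idx = rng.choice(len(df), size=min(config.refdb_n_duplicates, len(df)),
                             replace=False)
        dups = df.iloc[dup_idx]
        bad = []
        for i in range(config.refdb_n_invalid):
            bad.append({**df.iloc[int(rng.integers(len(df)))].to_dict(),
                        "cdr3b": "CASS*_" + ("X" * (i % 3))})
        df = pd.concat([df, dups, pd.DataFrame(bad)], ignore_index=True)
    return df


def generate_reference_repertoire(config: SynthConfig) -> pd.DataFrame:
    """Motif-free background CDR3beta repertoire for enrichment testing."""
    rng = _rng(config, _S_REFREP)
    lo, hi = config.cdr3_length_range
    seen: set[str] = set()
    rows = []
    while len(rows) < config.reference_repertoire_size:
        cdr3 = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        rows.append({"cdr3b": cdr3, "v_gene": str(rng.choice(config.v_gene_pool))})
    return pd.DataFrame(rows, columns=["cdr3b", "v_gene"])


def generate_proteome(config: SynthConfig) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]]]:
    """Random-composition proteins with planted 9-mer target peptides.

    Returns ``(proteins, placements)`` where placements maps each planted
    peptide to its (protein_id, 0-based start) positions. The first
    ``n_target_peptides`` planted peptides are the motif-associated 9-mers
    (so PWMs trained on reference-database annotations have true targets);
    extra random 9-mers are planted if more targets than motifs are asked.
    """
    rng = _rng(config, _S_PROTEOME)
    peptides = list(_motif_peptides(config).values())
    while len(peptides) < config.n_target_peptides:
        peptides.append("".join(rng.choice(list(AA), size=9)))
    peptides = peptides[: config.n_target_peptides]

    proteins: dict[str, str] = {}
    for i in range(config.proteome_n_proteins):
        seq = "".join(rng.choice(list(AA), size=config.protein_length))
        proteins[f"SYNP{i + 1:04d}"] = seq
    placements: dict[str, list[tuple[str, int]]] = {p: [] for p in peptides}
    if config.protein_length >= 9 and config.proteome_n_proteins:
        ids = list(proteins)
        for pep in peptides:
            pid = ids[int(rng.integers(len(ids)))]
            pos = int(rng.integers(0, config.protein_length - 9 + 1))
            seq = proteins[pid]
            proteins[pid] = seq[:pos] + pep + seq[pos + 9:]
            placements[pep].append((pid, pos))
    return proteins, placements


# ---------------------------------------------------------------------------
# writers

def write_contigs_csv(contigs: pd.DataFrame, path: str | Path) -> None:
    contigs.to_csv(path, index=False)


def write_expression_mtx(counts: np.ndarray, obs: pd.DataFrame,
                         genes: list[str], outdir: str | Path) -> None:
    """MTX triplet (matrix.mtx genes x cells, 10x orientation) + metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.T))
    (outdir / "barcodes.tsv").write_text("\n".join(obs["barcode"]) + "\n")
    (outdir / "features.tsv").write_text("\n".join(genes) + "\n")
    obs.to_csv(outdir / "metadata.csv", index=False)


def write_proteome_fasta(proteins: dict[str, str], path: str | Path,
                         width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "motif_carriers": {m: [list(p) for p in v] for m, v in gt.motif_carriers.items()},
        "motif_bias": gt.motif_bias,
        "motif_peptide": gt.motif_peptide,
        "public_clonotypes": [list(p) for p in gt.public_clonotypes],
        "condition_map": gt.condition_map,
        "size_correlated_genes": {g: list(v) for g, v in gt.size_correlated_genes.items()},
        "condition_shifted_genes": {g: list(v) for g, v in gt.condition_shifted_genes.items()},
        "peptide_placements": {p: [list(x) for x in v]
                               for p, v in gt.peptide_placements.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_synthetic_inputs(config: SynthConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write every pipeline input under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, gt = generate_repertoire(config)
    write_contigs_csv(contigs, outdir / "contigs.csv")
    counts, obs, genes = generate_expression(gt.cells, config)
    write_expression_mtx(counts, obs, genes, outdir / "expression")
    generate_reference_db(config, gt).to_csv(
        outdir / "reference_db.tsv", sep="\t", index=False)
    generate_reference_repertoire(config).to_csv(
        outdir / "reference_repertoire.tsv", sep="\t", index=False)
    proteins, placements = generate_proteome(config)
    gt.peptide_placements = placements
    write_proteome_fasta(proteins, outdir / "proteome.fasta")
    pd.DataFrame(
        [{"sample_id": s, "condition": c} for s, c in config.samples]
    ).to_csv(outdir / "conditions.tsv", sep="\t", index=False)
    write_ground_truth_json(gt, outdir / "ground_truth.json")
    return gt
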