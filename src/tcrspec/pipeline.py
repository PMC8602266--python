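"""End-to-end orchestration: contigs -> clonotypes -> repertoire statistics
-> specificity groups -> database annotation -> PWM proteome scan ->
expression linkage, from a single validated config, with a manifest of
checksummed artifacts. Identical config + inputs give byte-identical
outputs."""

from __future__ import annotations

import dataclasses
import glob as globlib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gex_link, pwm_scan, reference_db, repertoire_stats, specificity_grouping
from . import synthetic_data, tcr_io


@dataclass
class Thresholds:
    """Expansion/filter thresholds, defaulting to the study's published values."""

    clonotype_log2fc: float = 3.0
    clonotype_size_floor: int = 10
    group_log2fc: float = 2.5
    group_size_floor: int = 10
    expansion_pseudocount: float = 1.0
    group_min_clonotypes: int = 4
    group_min_samples: int = 3
    group_vgene_p: float = 0.05
    group_final_score: float = 1e-5
    motif_p: float = 1e-3
    de_adj_p: float = 0.01
    de_log2fc: float = 0.2
    pwm_min_clone_size: int = 3
    network_min_size: int = 10


@dataclass
class PipelineConfig:
    contigs: str = ""  # path or glob
    dialect: str = "tenx_csv"
    conditions: str = ""  # TSV: sample_id, condition
    expression: str = ""  # MTX triplet directory
    reference_repertoire: str = ""
    reference_db: str = ""
    proteome: str = ""
    outdir: str = "tcrspec_out"
    seed: int = 0
    nmds_restarts: int = 20
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(**raw, thresholds=th)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema, file-existence and threshold sanity checks."""
    errors: list[str] = []
    th = config.thresholds
    for name in ("group_vgene_p", "group_final_score", "motif_p", "de_adj_p"):
        v = getattr(th, name)
        if not (0 < v <= 1):
            errors.append(f"threshold {name}={v} not in (0, 1]")
    for name in ("clonotype_size_floor", "group_size_floor", "group_min_clonotypes",
                 "group_min_samples", "pwm_min_clone_size", "network_min_size"):
        if getattr(th, name) < 0:
            errors.append(f"threshold {name} is negative")
    if th.expansion_pseudocount <= 0:
        errors.append("expansion_pseudocount must be positive")
    if config.dialect not in ("tenx_csv", "airr_tsv"):
        errors.append(f"unknown contig dialect {config.dialect!r}")
    if config.contigs and not globlib.glob(config.contigs):
        errors.append(f"no contig file matches {config.contigs!r}")
    for name in ("conditions", "reference_repertoire", "reference_db", "proteome"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            errors.append(f"{name} file {p!r} does not exist")
    if config.expression and not (Path(config.expression) / "matrix.mtx").exists():
        errors.append(f"expression directory {config.expression!r} lacks matrix.mtx")
    if not config.contigs:
        errors.append("contigs input is required")
    if not config.conditions:
        errors.append("conditions map is required")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _expansion_table(clonotypes, cond_a: str, cond_b: str, th: Thresholds) -> pd.DataFrame:
    counts = pd.DataFrame({
        cond_a: [ct.per_condition_counts.get(cond_a, 0) for ct in clonotypes],
        cond_b: [ct.per_condition_counts.get(cond_b, 0) for ct in clonotypes],
    }, index=[ct.clonotype_id for ct in clonotypes])
    labels = repertoire_stats.expansion_labels(
        counts, th.clonotype_log2fc, th.clonotype_size_floor,
        th.expansion_pseudocount)
    return pd.DataFrame({
        "clonotype_id": [l.entity_id for l in labels],
        "count_A": [l.count_A for l in labels],
        "count_B": [l.count_B for l in labels],
        "size": [l.count_A + l.count_B for l in labels],
        "log2fc": [l.log2fc for l in labels],
        "label": [l.label for l in labels],
    }).set_index("clonotype_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle of paths and key numbers."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    bundle: dict = {"outdir": str(out), "numbers": {}}
    num = bundle["numbers"]

    # ---- stage: tcr_io --------------------------------------------------
    cond_df = pd.read_csv(config.conditions, sep="\t")
    condition_map = dict(zip(cond_df["sample_id"], cond_df["condition"]))
    conditions = sorted(set(condition_map.values()))
    cond_a, cond_b = conditions[0], conditions[-1]
    records = []
    for path in sorted(globlib.glob(config.contigs)):
        records.extend(tcr_io.read_contigs(path, config.dialect))
    cells = tcr_io.filter_productive_paired(records)
    clonotypes = tcr_io.call_clonotypes(cells, condition_map)
    tcr_io.write_clonotypes(clonotypes, out / "clonotypes.tsv")
    n_barcodes = len({(r.sample_id, r.barcode) for r in records})
    num["n_contigs"] = len(records)
    num["n_barcodes"] = n_barcodes
    num["n_paired_cells"] = len(cells)
    num["pairing_rate"] = len(cells) / n_barcodes if n_barcodes else 0.0
    num["n_clonotypes"] = len(clonotypes)

    # ---- stage: repertoire_stats ---------------------------------------
    matrix = tcr_io.repertoire_matrix(clonotypes, axis="sample")
    div_rows = []
    for sample in matrix.columns:
        counts = matrix[sample][matrix[sample] > 0]
        div_rows.append({
            "sample_id": sample, "condition": condition_map[sample],
            "n_cells": int(counts.sum()), "n_clonotypes": int((counts > 0).sum()),
            "shannon": repertoire_stats.shannon_diversity(counts.tolist()),
            "geometric_mean_clone_size":
                repertoire_stats.geometric_mean_clone_size(counts.tolist()),
        })
    diversity = pd.DataFrame(div_rows)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    num["mean_shannon"] = float(diversity["shannon"].mean())

    pub = repertoire_stats.public_clonotypes(matrix, condition_map)
    pub.to_csv(out / "public_clonotypes.tsv", sep="\t", index=False)
    num["n_public_clonotypes"] = len(pub)
    num["n_condition_shared_public"] = int(pub["condition_shared"].sum()) if len(pub) else 0

    # NMDS of samples over public-clonotype counts (Bray-Curtis)
    if len(pub) >= 2:
        pub_matrix = matrix.loc[pub["clonotype_id"]].T  # samples x public clonotypes
        diss = repertoire_stats.bray_curtis(pub_matrix.to_numpy(float))
        ord_res = repertoire_stats.nmds(diss, k=2, seed=config.seed,
                                        n_restarts=config.nmds_restarts)
        coords = pd.DataFrame(ord_res.coordinates, index=pub_matrix.index,
                              columns=["NMDS1", "NMDS2"])
        coords.round(10).to_csv(out / "nmds.tsv", sep="\t")
        num["nmds_stress"] = ord_res.stress
    graph = repertoire_stats.sample_clonotype_network(clonotypes, th.network_min_size)
    pd.DataFrame(sorted(graph.edges), columns=["source", "target"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False)
    expansion = _expansion_table(clonotypes, cond_a, cond_b, th)
    expansion.to_csv(out / "clonotype_expansion.tsv", sep="\t")
    num["n_expanded_clonotypes"] = int((expansion["label"] != "shared").sum())

    # ---- stage: specificity_grouping -----------------------------------
    ref_rep = specificity_grouping.ReferenceRepertoire.from_table(
        pd.read_csv(config.reference_repertoire, sep="\t"))
    groups, _hits = specificity_grouping.run_gliph(
        clonotypes, ref_rep, p_motif=th.motif_p,
        min_clonotypes=th.group_min_clonotypes, min_samples=th.group_min_samples,
        vgene_p=th.group_vgene_p, final=th.group_final_score)
    for g in groups:  # group-level expansion labels on cell counts
        ga = g.per_condition_cell_counts.get(cond_a, 0)
        gb = g.per_condition_cell_counts.get(cond_b, 0)
        fc = float(np.log2((gb + th.expansion_pseudocount)
                           / (ga + th.expansion_pseudocount)))
        g.enrichment_log2fc = fc
        if abs(fc) > th.group_log2fc and ga + gb > th.group_size_floor:
            g.enrichment_label = "B_enriched" if fc > 0 else "A_enriched"
    passing = [g for g in groups if g.passes_filter]
    num["n_specificity_groups"] = len(groups)
    num["n_passing_groups"] = len(passing)
    num["n_clonotypes_in_passing_groups"] = len(
        {cid for g in passing for cid in g.member_clonotype_ids})

    # ---- stage: reference_db -------------------------------------------
    raw_db = pd.read_csv(config.reference_db, sep="\t", dtype=str,
                         keep_default_na=False)
    db = reference_db.compile_reference(
        [(raw_db, {c: c for c in raw_db.columns})])
    db.to_csv(out / "reference_db_compiled.tsv", sep="\t", index=False)
    annotations, matched_frac = reference_db.exact_match(clonotypes, db)
    annotations.to_csv(out / "exact_match_annotations.tsv", sep="\t", index=False)
    num["exact_match_fraction"] = matched_frac
    db_groups = reference_db.reference_motif_groups(db)
    num["n_groups_annotated"] = reference_db.motif_transfer(passing, db_groups)
    specificity_grouping.groups_to_frame(groups).to_csv(
        out / "specificity_groups.tsv", sep="\t", index=False)

    # ---- stage: pwm_scan -------------------------------------------------
    proteins = pwm_scan.read_proteome_fasta(config.proteome)
    background = pwm_scan.proteome_composition(proteins)
    pwm_expansion = _expansion_table(clonotypes, cond_a, cond_b,
                                     dataclasses.replace(th, clonotype_log2fc=0.0,
                                                         clonotype_size_floor=0))
    for label, cond in (("A", cond_a), ("B", cond_b)):
        peptides = pwm_scan.select_weighted_peptides(
            annotations, pwm_expansion, label, th.pwm_min_clone_size)
        num[f"n_pwm_peptides_{cond}"] = len(peptides)
        if not peptides:
            continue
        pwm = pwm_scan.build_pwm(peptides, background, condition=cond)
        hits, n_windows = pwm_scan.scan_proteome(pwm, proteins, top_n=100)
        pwm_scan.hits_to_frame(hits).to_csv(
            out / f"pwm_hits_{cond}.tsv", sep="\t", index=False)
        num[f"pwm_n_windows_{cond}"] = n_windows
        if hits:
            num[f"pwm_top_peptide_{cond}"] = hits[0].peptide
            num[f"pwm_best_p_{cond}"] = hits[0].p

    # ---- stage: gex_link --------------------------------------------------
    adata = gex_link.load_expression_mtx(config.expression)
    matched = gex_link.attach_clonotypes(adata, clonotypes)
    num["expression_matched_fraction"] = float(matched.mean())
    gex_link.normalize_lognorm(adata)
    corr = gex_link.clone_size_correlation(adata)
    corr.to_csv(out / "clone_size_correlation.tsv", sep="\t", index=False)
    cond_obs = adata.obs["condition"].to_numpy()
    de = gex_link.differential_expression(
        adata, cond_obs == cond_a, cond_obs == cond_b)
    de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    num["n_de_genes"] = int(((de["p_adjusted"] < th.de_adj_p)
                             & (de["log2fc"].abs() > th.de_log2fc)).sum())
    avg = gex_link.average_expression_by(adata, "clonotype_id")
    avg.to_csv(out / "average_expression_by_clonotype.tsv", sep="\t")
    top_genes = de.head(20)["gene"].tolist()
    scores = gex_link.module_score(adata, top_genes, seed=config.seed)
    pd.DataFrame({"barcode": adata.obs_names, "score": scores}).to_csv(
        out / "module_scores.tsv", sep="\t", index=False)

    # ---- manifest --------------------------------------------------------
    artifacts = sorted(p for p in out.iterdir() if p.is_file()
                       and p.name != "run_manifest.json")
    manifest = {
        "config": config.to_dict(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "numbers": {k: (round(v, 10) if isinstance(v, float) else v)
                    for k, v in sorted(num.items())},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    bundle["clonotypes"] = clonotypes
    bundle["groups"] = groups
    return bundle


DEMO_MOTIFS = [
    synthetic_data.PlantedMotif("QETQ", "shared", 0.05),
    synthetic_data.PlantedMotif("LGGR", "AUTO", 0.05),
    synthetic_data.PlantedMotif("WSNE", "AUTO", 0.05),
    synthetic_data.PlantedMotif("RDYT", "WT", 0.05),
    synthetic_data.PlantedMotif("PHSN", "shared", 0.05),
]


def demo_config(outdir: str | Path, seed: int = 0,
                scale: float = 1.0) -> tuple[PipelineConfig, synthetic_data.SynthConfig]:
    """Build the synthetic demo: generated inputs plus a matching config."""
    outdir = Path(outdir)
    synth = synthetic_data.SynthConfig(
        clones_per_sample=max(40, int(150 * scale)),
        planted_motifs=list(DEMO_MOTIFS),
        n_genes=max(50, int(200 * scale)),
        proteome_n_proteins=max(20, int(100 * scale)),
        seed=seed)
    data_dir = outdir / "synthetic_inputs"
    synthetic_data.write_synthetic_inputs(synth, data_dir)
    config = PipelineConfig(
        contigs=str(data_dir / "contigs.csv"),
        conditions=str(data_dir / "conditions.tsv"),
        expression=str(data_dir / "expression"),
        reference_repertoire=str(data_dir / "reference_repertoire.tsv"),
        reference_db=str(data_dir / "reference_db.tsv"),
        proteome=str(data_dir / "proteome.fasta"),
        outdir=str(outdir / "results"),
        seed=seed)
    return config, synth


def run_demo(outdir: str | Path, seed: int = 0, scale: float = 1.0) -> dict:
    """Generate synthetic inputs and run the full pipeline on them."""
    config, _synth = demo_config(outdir, seed, scale)
    return run_pipeline(config)
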