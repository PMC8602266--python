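"""Harmonized CDR3beta -> antigen reference database.

Compiles raw public-database exports (each with its own column names)
into one schema, drops CDR3s with non-amino-acid characters and exact
duplicate rows, annotates clonotypes by exact CDR3beta match, and
transfers annotations to specificity groups through shared local motifs.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .specificity_grouping import SpecificityGroup, interior_kmers
from .tcr_io import Clonotype

_VALID_CDR3 = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

DISEASE_CLASSES = ("virus", "bacteria", "parasite", "autoimmune", "cancer",
                   "transplant", "immunodeficiency", "allergy", "other")

SCHEMA = ["cdr3b", "peptide", "antigen", "disease", "disease_class",
          "species", "v_gene", "j_gene", "source"]

#: default disease -> class lookup; shipped editable as TSV by the CLI
DEFAULT_DISEASE_CLASS = {
    "influenza": "virus", "cmv": "virus", "ebv": "virus", "hiv": "virus",
    "sars-cov-2": "virus", "hcv": "virus",
    "m.tuberculosis": "bacteria", "tuberculosis": "bacteria",
    "malaria": "parasite", "toxoplasma": "parasite",
    "t1d": "autoimmune", "diabetes": "autoimmune", "ms": "autoimmune",
    "autoimmunity": "autoimmune", "celiac": "autoimmune", "sle": "autoimmune",
    "melanoma": "cancer", "neoantigen": "cancer",
    "gvhd": "transplant", "allograft": "transplant",
    "scid": "immunodeficiency", "allergy": "allergy",
}


@dataclass(frozen=True)
class ReferenceEntry:
    cdr3b: str
    peptide: str
    antigen: str
    disease: str
    disease_class: str
    species: str = ""
    v_gene: str = ""
    j_gene: str = ""
    source: str = ""


def compile_reference(
    raw_tables: Sequence[tuple[pd.DataFrame, Mapping[str, str]]],
    disease_class_map: Mapping[str, str] | None = None,
    species: str | None = None,
) -> pd.DataFrame:
    """Harmonize raw source tables into the unified reference schema.

    Each raw table arrives with a mapping {raw column -> schema column};
    ``cdr3b`` and ``peptide`` are mandatory. Rows whose CDR3 contains
    characters outside the 20 amino-acid letters are dropped, then exact
    duplicate rows are removed. ``disease_class`` is filled from the
    lookup (case-insensitive, fallback "other") wherever the source did
    not already provide a recognized class. Idempotent: compiling the
    compiled output returns it unchanged.
    """
    lookup = {k.lower(): v for k, v in
              (disease_class_map or DEFAULT_DISEASE_CLASS).items()}
    frames = []
    for i, (raw, mapping) in enumerate(raw_tables):
        inv = dict(mapping)
        for col in ("cdr3b", "peptide"):
            if col not in inv.values():
                missing = [k for k, v in inv.items() if v == col]
                raise ValueError(
                    f"source {i}: no column mapped to mandatory field {col!r}"
                    + (f" (missing raw column {missing})" if missing else ""))
        absent = [src for src in inv if src not in raw.columns]
        if absent:
            raise ValueError(f"source {i}: mapped column(s) {absent} not in table")
        df = raw[list(inv)].rename(columns=inv).astype(str)
        for col in SCHEMA:
            if col not in df.columns:
                df[col] = ""
        frames.append(df[SCHEMA])
    if not frames:
        return pd.DataFrame(columns=SCHEMA)
    db = pd.concat(frames, ignore_index=True)
    db = db[db["cdr3b"].str.match(_VALID_CDR3)]
    if species is not None:
        db = db[db["species"] == species]
    db = db.drop_duplicates(ignore_index=True)

    def classify(row):
        dc = row["disease_class"].lower()
        if dc in DISEASE_CLASSES:
            return dc
        return lookup.get(row["disease"].lower(), "other")

    db["disease_class"] = db.apply(classify, axis=1) if len(db) else db["disease_class"]
    return db.reset_index(drop=True)


def exact_match(clonotypes: Sequence[Clonotype],
                db: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Annotate clonotypes whose CDR3beta occurs verbatim in the database.

    Returns ``(annotations, matched_fraction)``; every (peptide, antigen,
    disease_class) of a matching database CDR3 is attached, and the
    fraction is over unique query CDR3beta sequences.
    """
    by_cdr3 = defaultdict(list)
    for row in db.itertuples(index=False):
        by_cdr3[row.cdr3b].append(row)
    rows = []
    unique_query = {ct.cdr3b_aa for ct in clonotypes}
    matched = {s for s in unique_query if s in by_cdr3}
    for ct in clonotypes:
        for hit in by_cdr3.get(ct.cdr3b_aa, []):
            rows.append({
                "clonotype_id": ct.clonotype_id, "cdr3b": ct.cdr3b_aa,
                "peptide": hit.peptide, "antigen": hit.antigen,
                "disease_class": hit.disease_class, "source": hit.source})
    ann = pd.DataFrame(rows, columns=["clonotype_id", "cdr3b", "peptide",
                                      "antigen", "disease_class", "source"])
    frac = len(matched) / len(unique_query) if unique_query else 0.0
    return ann, frac


def reference_motif_groups(db: pd.DataFrame,
                           k_values: Sequence[int] = (3, 4),
                           trim: tuple[int, int] = (3, 2),
                           min_entries: int = 3) -> dict[str, pd.DataFrame]:
    """Local-motif groups of the reference database itself.

    Groups database entries by shared interior CDR3beta k-mers (the same
    trimming convention as the query-side grouping), keeping motifs with
    at least ``min_entries`` distinct CDR3s — the database-side structures
    that annotation transfer matches query group seeds against.
    """
    members: dict[str, set[int]] = defaultdict(set)
    cdr3s = db["cdr3b"].tolist()
    for i, s in enumerate(cdr3s):
        for m in set(interior_kmers(s, k_values, trim)):
            members[m].add(i)
    out = {}
    for motif, idx in members.items():
        sub = db.iloc[sorted(idx)]
        if sub["cdr3b"].nunique() >= min_entries:
            out[motif] = sub
    return out


def motif_transfer(query_groups: Sequence[SpecificityGroup],
                   db_groups: Mapping[str, pd.DataFrame]) -> int:
    """Inherit database annotations into query groups with the same seed motif.

    The majority (peptide, antigen, disease_class) by unique database
    CDR3beta count wins; exact ties attach every tied annotation and set
    the ambiguous flag. Returns the number of groups annotated.
    """
    n_annotated = 0
    for g in query_groups:
        if g.kind != "local" or g.seed not in db_groups:
            continue
        sub = db_groups[g.seed]
        votes = (sub.groupby(["peptide", "antigen", "disease_class"])["cdr3b"]
                 .nunique().sort_values(ascending=False))
        if votes.empty:
            continue
        top = votes.max()
        winners = votes[votes == top]
        g.annotations = [
            {"peptide": p, "antigen": a, "disease_class": d, "n_support": int(top)}
            for (p, a, d) in winners.index]
        g.annotation_ambiguous = len(winners) > 1
        n_annotated += 1
    return n_annotated
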