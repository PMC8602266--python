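"""Contig-table reading, productivity/pairing filtering, and clonotype calling.

Clonotypes are defined by the exact paired CDR3alpha + CDR3beta amino-acid
sequences; clone size is the number of unique cell barcodes carrying that
pair. Contigs are accepted only when full length and productive; a cell is
retained only when it has both a surviving TRA and TRB contig.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_TRUE_TOKENS = {"True", "true", "TRUE", "T"}
_FALSE_TOKENS = {"False", "false", "FALSE", "F", "None", "none"}

#: column mapping for the 10x `filtered_contig_annotations.csv` dialect
TENX_COLUMNS = {
    "barcode": "barcode",
    "chain": "chain",
    "v_gene": "v_gene",
    "j_gene": "j_gene",
    "cdr3": "cdr3_aa",
    "cdr3_nt": "cdr3_nt",
    "full_length": "full_length",
    "productive": "productive",
    "umis": "umis",
}

#: column mapping for the AIRR Rearrangement TSV dialect
AIRR_COLUMNS = {
    "cell_id": "barcode",
    "locus": "chain",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "junction_aa": "cdr3_aa",
    "junction": "cdr3_nt",
    "complete_vdj": "full_length",
    "productive": "productive",
    "duplicate_count": "umis",
}

_MANDATORY = ["barcode", "chain", "cdr3_aa", "v_gene", "j_gene",
              "full_length", "productive", "umis"]


@dataclass(frozen=True)
class ContigRecord:
    """One TCR contig call for one cell barcode in one sample."""

    sample_id: str
    barcode: str
    chain: str  # "TRA", "TRB", or "other"
    cdr3_aa: str
    v_gene: str
    j_gene: str
    full_length: bool
    productive: bool
    umis: int
    cdr3_nt: str | None = None


@dataclass(frozen=True)
class CellTcr:
    """A paired cell: exactly one TRA and one TRB tuple (cdr3_aa, v, j)."""

    sample_id: str
    barcode: str
    tra: tuple[str, str, str]
    trb: tuple[str, str, str]


@dataclass
class Clonotype:
    """An identity class of cells sharing paired CDR3alpha/beta sequences."""

    clonotype_id: str
    cdr3a_aa: str
    cdr3b_aa: str
    va_gene: str
    ja_gene: str
    vb_gene: str
    jb_gene: str
    members: list[tuple[str, str]] = field(default_factory=list)
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    per_condition_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def _parse_bool(value: object, row: int, column: str) -> bool:
    s = str(value)
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(
        f"unparseable boolean {value!r} in column {column!r} at row {row}"
    )


def _normalize_chain(raw: str) -> str:
    c = raw.strip().upper()
    return c if c in ("TRA", "TRB") else "other"


def read_contigs(
    path: str | Path,
    dialect: Literal["tenx_csv", "airr_tsv"] = "tenx_csv",
    sample_id: str | None = None,
) -> list[ContigRecord]:
    """Read a contig annotation table into :class:`ContigRecord` rows.

    Parameters
    ----------
    path
        CSV (10x dialect) or TSV (AIRR Rearrangement dialect).
    dialect
        ``tenx_csv`` expects the ``filtered_contig_annotations.csv`` columns;
        ``airr_tsv`` expects AIRR names (``junction_aa``, ``v_call``, ...).
    sample_id
        Sample label; when omitted a ``sample_id`` column must be present.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        mapping = TENX_COLUMNS
    elif dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        mapping = AIRR_COLUMNS
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [src for src, dst in mapping.items()
               if dst in _MANDATORY and src not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing} for dialect {dialect}"
        )
    df = df.rename(columns=mapping)
    if sample_id is None:
        if "sample_id" not in df.columns:
            raise ValueError(
                f"{path}: no sample_id column and no sample_id argument given"
            )
    else:
        df = df.assign(sample_id=sample_id)

    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[ContigRecord]:
    """Build :class:`ContigRecord` rows from an already-harmonized table.

    Expects the unified column names (``cdr3_aa``, ``v_gene``, ...) or the
    10x generator dialect (``cdr3``/``cdr3_nt``).
    """
    if "cdr3_aa" not in df.columns and "cdr3" in df.columns:
        df = df.rename(columns={"cdr3": "cdr3_aa"})
    records: list[ContigRecord] = []
    has_nt = "cdr3_nt" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        records.append(
            ContigRecord(
                sample_id=d["sample_id"],
                barcode=d["barcode"],
                chain=_normalize_chain(str(d["chain"])),
                cdr3_aa=d["cdr3_aa"],
                v_gene=d["v_gene"],
                j_gene=d["j_gene"],
                full_length=_parse_bool(d["full_length"], i, "full_length"),
                productive=_parse_bool(d["productive"], i, "productive"),
                umis=int(d["umis"]) if str(d["umis"]) != "" else 0,
                cdr3_nt=(str(d["cdr3_nt"]) or None) if has_nt else None,
            )
        )
    return records


def normalize_gene(name: str) -> str:
    """Trim allele suffixes like ``*01`` from a V/J gene name."""
    return re.sub(r"\*\d+$", "", name)


def filter_productive_paired(
    records: Iterable[ContigRecord],
    multichain: Literal["top_umi", "drop"] = "top_umi",
) -> list[CellTcr]:
    """Apply the full-length/productive filter and retain paired cells.

    Per (sample, barcode, chain) the highest-UMI surviving contig is kept
    (ties broken by lexicographically smallest CDR3); cells need both a TRA
    and a TRB survivor. With ``multichain="drop"`` cells carrying more than
    one surviving contig for a chain are discarded instead.
    """
    by_cell_chain: dict[tuple[str, str, str], list[ContigRecord]] = defaultdict(list)
    for rec in records:
        if rec.full_length and rec.productive and rec.chain in ("TRA", "TRB"):
            by_cell_chain[(rec.sample_id, rec.barcode, rec.chain)].append(rec)

    cells: dict[tuple[str, str], dict[str, ContigRecord]] = defaultdict(dict)
    dropped_cells: set[tuple[str, str]] = set()
    for (sample, barcode, chain), contigs in by_cell_chain.items():
        if len(contigs) > 1 and multichain == "drop":
            dropped_cells.add((sample, barcode))
            continue
        best = min(contigs, key=lambda r: (-r.umis, r.cdr3_aa))
        cells[(sample, barcode)][chain] = best

    out: list[CellTcr] = []
    for (sample, barcode), chains in sorted(cells.items()):
        if (sample, barcode) in dropped_cells:
            continue
        if "TRA" in chains and "TRB" in chains:
            a, b = chains["TRA"], chains["TRB"]
            out.append(
                CellTcr(
                    sample_id=sample,
                    barcode=barcode,
                    tra=(a.cdr3_aa, a.v_gene, a.j_gene),
                    trb=(b.cdr3_aa, b.v_gene, b.j_gene),
                )
            )
    return out


def _modal(values: Sequence[str]) -> str:
    # deterministic mode: most common, ties to lexicographically smallest
    counts = Counter(values)
    return min(counts, key=lambda g: (-counts[g], g))


def call_clonotypes(
    cells: Sequence[CellTcr],
    condition_map: Mapping[str, str],
) -> list[Clonotype]:
    """Group cells into clonotypes by identical paired CDR3 aa sequences.

    Ordering is deterministic: size descending, then CDR3beta, then
    CDR3alpha. V/J genes recorded per clonotype are the modal usage over
    member cells.
    """
    unmapped = {c.sample_id for c in cells} - set(condition_map)
    if unmapped:
        raise ValueError(f"sample_id(s) missing from condition map: {sorted(unmapped)}")

    groups: dict[tuple[str, str], list[CellTcr]] = defaultdict(list)
    for cell in cells:
        groups[(cell.tra[0], cell.trb[0])].append(cell)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0][1], kv[0][0]))
    clonotypes: list[Clonotype] = []
    for idx, ((cdr3a, cdr3b), members) in enumerate(ordered):
        per_sample: Counter = Counter(m.sample_id for m in members)
        per_condition: Counter = Counter(condition_map[m.sample_id] for m in members)
        clonotypes.append(
            Clonotype(
                clonotype_id=f"CT{idx + 1:06d}",
                cdr3a_aa=cdr3a,
                cdr3b_aa=cdr3b,
                va_gene=_modal([m.tra[1] for m in members]),
                ja_gene=_modal([m.tra[2] for m in members]),
                vb_gene=_modal([m.trb[1] for m in members]),
                jb_gene=_modal([m.trb[2] for m in members]),
                members=sorted((m.sample_id, m.barcode) for m in members),
                per_sample_counts=dict(sorted(per_sample.items())),
                per_condition_counts=dict(sorted(per_condition.items())),
            )
        )
    return clonotypes


def repertoire_matrix(
    clonotypes: Sequence[Clonotype],
    axis: Literal["sample", "condition"] = "sample",
) -> pd.DataFrame:
    """Clonotype x sample (or x condition) cell-count matrix.

    Row sums equal clone sizes; column sums equal per-sample retained-cell
    counts.
    """
    key = "per_sample_counts" if axis == "sample" else "per_condition_counts"
    columns = sorted({c for ct in clonotypes for c in getattr(ct, key)})
    data = {
        ct.clonotype_id: [getattr(ct, key).get(col, 0) for col in columns]
        for ct in clonotypes
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=columns).astype(int)


_CLONOTYPE_COLUMNS = [
    "clonotype_id", "cdr3a_aa", "cdr3b_aa", "va_gene", "ja_gene",
    "vb_gene", "jb_gene", "size", "samples", "sample_counts",
    "conditions", "condition_counts", "barcodes",
]


def clonotypes_to_frame(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    """Flatten clonotypes into a table (list fields are ';'-joined)."""
    rows = []
    for ct in clonotypes:
        rows.append({
            "clonotype_id": ct.clonotype_id,
            "cdr3a_aa": ct.cdr3a_aa,
            "cdr3b_aa": ct.cdr3b_aa,
            "va_gene": ct.va_gene,
            "ja_gene": ct.ja_gene,
            "vb_gene": ct.vb_gene,
            "jb_gene": ct.jb_gene,
            "size": ct.size,
            "samples": ";".join(ct.per_sample_counts),
            "sample_counts": ";".join(str(v) for v in ct.per_sample_counts.values()),
            "conditions": ";".join(ct.per_condition_counts),
            "condition_counts": ";".join(
                str(v) for v in ct.per_condition_counts.values()),
            "barcodes": ";".join(f"{s}:{b}" for s, b in ct.members),
        })
    return pd.DataFrame(rows, columns=_CLONOTYPE_COLUMNS)


def write_clonotypes(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    clonotypes_to_frame(clonotypes).to_csv(path, sep="\t", index=False)


def read_clonotypes(path: str | Path) -> list[Clonotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[Clonotype] = []
    for row in df.itertuples(index=False):
        samples = row.samples.split(";") if row.samples else []
        s_counts = [int(x) for x in row.sample_counts.split(";")] if row.sample_counts else []
        conditions = row.conditions.split(";") if row.conditions else []
        c_counts = [int(x) for x in row.condition_counts.split(";")] if row.condition_counts else []
        members = []
        if row.barcodes:
            for tok in row.barcodes.split(";"):
                s, b = tok.split(":", 1)
                members.append((s, b))
        out.append(Clonotype(
            clonotype_id=row.clonotype_id,
            cdr3a_aa=row.cdr3a_aa,
            cdr3b_aa=row.cdr3b_aa,
            va_gene=row.va_gene,
            ja_gene=row.ja_gene,
            vb_gene=row.vb_gene,
            jb_gene=row.jb_gene,
            members=members,
            per_sample_counts=dict(zip(samples, s_counts)),
            per_condition_counts=dict(zip(conditions, c_counts)),
        ))
    return out
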