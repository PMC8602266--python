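import pandas as pd
import pytest

from tcrspec import tcr_io


def make_contig_row(barcode="BC1", chain="TRB", cdr3="CASSQETQYF",
                    v="TRBV5", j="TRBJ1", full_length=True, productive=True,
                    umis=5, sample="S1"):
    return {
        "sample_id": sample, "barcode": barcode, "chain": chain,
        "v_gene": v, "j_gene": j, "cdr3": cdr3, "cdr3_nt": "",
        "full_length": full_length, "productive": productive, "umis": umis,
    }


def contig_record(**kw):
    row = make_contig_row(**kw)
    return tcr_io.ContigRecord(
        sample_id=row["sample_id"], barcode=row["barcode"], chain=row["chain"],
        cdr3_aa=row["cdr3"], v_gene=row["v_gene"], j_gene=row["j_gene"],
        full_length=row["full_length"], productive=row["productive"],
        umis=row["umis"])


@pytest.fixture
def paired_cells():
    """8 cells over 3 distinct CDR3 pairs in 2 samples -> sizes {4, 3, 1}."""
    cells = []
    spec = [("CAVA", "CASSA", "S1", 3), ("CAVA", "CASSA", "S2", 1),
            ("CAVB", "CASSB", "S1", 3), ("CAVC", "CASSC", "S2", 1)]
    i = 0
    for cdr3a, cdr3b, sample, n in spec:
        for _ in range(n):
            i += 1
            cells.append(tcr_io.CellTcr(
                sample_id=sample, barcode=f"BC{i}",
                tra=(cdr3a, "TRAV1", "TRAJ1"), trb=(cdr3b, "TRBV1", "TRBJ1")))
    return cells


@pytest.fixture
def condition_map():
    return {"S1": "WT", "S2": "AUTO"}


def write_tenx_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
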