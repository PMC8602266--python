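from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrspec import specificity_grouping as sg
from tcrspec import tcr_io


def hypergeom_tail_oracle(a: int, n_query: int, c: int, n_ref: int) -> float:
    """Exact P(X >= a) by rational enumeration of the hypergeometric pmf."""
    N, K, n = n_query + n_ref, a + c, n_query
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def make_clonotype(ct_id, cdr3b, vb="TRBV5", samples=("S1",), cdr3a="CAVSNF"):
    ct = tcr_io.Clonotype(ct_id, cdr3a, cdr3b, "TRAV1", "TRAJ1", vb, "TRBJ1")
    ct.members = [(s, f"{ct_id}:{s}") for s in samples]
    ct.per_sample_counts = {s: 1 for s in samples}
    ct.per_condition_counts = {"WT": len(samples)}
    return ct


class TestExtractMotifs:
    def test_interior_trimming_enumeration(self):
        # "CASSQETQYF" -> interior "SQETQ" -> 3-mers {SQE, QET, ETQ}
        df = sg.extract_motifs([("CASSQETQYF", "S1")], k_values=(3,))
        assert set(df.index) == {"SQE", "QET", "ETQ"}
        assert (df["n_unique_cdr3"] == 1).all()

    def test_short_cdr3_contributes_nothing(self):
        df = sg.extract_motifs([("CASSQF", "S1")], k_values=(2, 3, 4))
        assert len(df) == 0

    def test_duplicates_inflate_raw_not_unique(self):
        df = sg.extract_motifs([("CASSQETQYF", "S1"), ("CASSQETQYF", "S2")],
                               k_values=(3,))
        assert (df["n_total"] == 2).all()
        assert (df["n_unique_cdr3"] == 1).all()
        assert (df["n_samples"] == 2).all()


class TestFisher:
    def test_spec_worked_table(self):
        # query: 3 of 4 carry motif; reference: 2 of 6
        assert sg.fisher_greater(3, 4, 2, 6) == pytest.approx(
            hypergeom_tail_oracle(3, 4, 2, 6), abs=1e-12)

    def test_absent_motif_p_one(self):
        assert sg.fisher_greater(0, 10, 5, 100) == 1.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(1, 25), st.integers(1, 25),
           st.data())
    def test_matches_enumeration_oracle(self, nq, nr, data):
        a = data.draw(st.integers(0, nq))
        c = data.draw(st.integers(0, nr))
        assert sg.fisher_greater(a, nq, c, nr) == pytest.approx(
            hypergeom_tail_oracle(a, nq, c, nr), abs=1e-12)


class TestMotifEnrichment:
    def test_api_wires_counts_into_fisher_table(self):
        query = sg.extract_motifs(
            [("CASSQETQYF", "S1"), ("CASTQETQYF", "S2"), ("CAWWQETQYF", "S3"),
             ("CASSLDRGYF", "S1")], k_values=(4,))
        ref = sg.ReferenceRepertoire.from_sequences(
            ["CASSQETQYF", "CATTQETQWF", "CASSLLLGYF", "CASSRRRGYF",
             "CASSYYYGYF", "CASSHHHGYF"], k_values=(4,))
        hits = {h.motif: h for h in sg.motif_enrichment(query, ref, 4, k_test=(4,))}
        hit = hits["QETQ"]
        assert hit.unique_cdr3_count_in_query == 3
        assert hit.count_in_reference == 2
        assert hit.fisher_p == pytest.approx(
            hypergeom_tail_oracle(3, 4, 2, 6), abs=1e-12)

    def test_null_pvalues_uniform(self):
        # query and reference drawn from the same generator: KS test on the
        # mid-p-adjusted empirical distribution should not reject uniformity
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        def seqs(n):
            return ["CAS" + "".join(rng.choice(aa, size=9)) + "YF" for _ in range(n)]
        query = seqs(300)
        ref = sg.ReferenceRepertoire.from_sequences(seqs(1000))
        obs = sg.extract_motifs([(s, "S1") for s in query], k_values=(3,))
        hits = sg.motif_enrichment(obs, ref, len(set(query)), k_test=(3,))
        p = np.array([h.fisher_p for h in hits])
        # discrete conservative p-values: check super-uniformity instead of
        # exact uniformity -- P(p <= t) must not exceed t by a wide margin
        for t in (0.01, 0.05, 0.2):
            assert (p <= t).mean() <= t * 1.5 + 0.01


class TestNonTemplated:
    def test_positions_outside_germline_flagged(self):
        v, j = "TGTGCCAGC", "TTTGGC"  # germline V prefix / J suffix
        nt = v + "CAGGAA" + j  # 2 inserted codons
        pos = sg.non_templated_positions(nt, v, j)
        assert pos == {3, 4}


class TestGlobalClusters:
    def test_conservative_substitution_joins(self):
        # L<->I scores +2 in BLOSUM62
        clusters = sg.global_clusters(["CASSLG", "CASSIG"])
        assert clusters == [["CASSIG", "CASSLG"]]

    def test_nonconservative_substitution_rejected(self):
        # L<->P scores -3 in BLOSUM62
        assert sg.global_clusters(["CASSLG", "CASSPG"]) == []

    def test_duplicates_form_cluster(self):
        assert sg.global_clusters(["CASSLG", "CASSLG"]) == [["CASSLG"]]

    def test_different_lengths_never_join(self):
        assert sg.global_clusters(["CASSLG", "CASSLLG"]) == []


class TestAssembleAndScore:
    def _fixture(self):
        carriers = [make_clonotype(f"c{i}", f"CAS{'SQETQ' if i < 5 else 'LDRGY'}W{chr(65 + i)}F",
                                   vb="TRBV5" if i < 5 else "TRBV1",
                                   samples=(f"S{i % 4 + 1}",))
                    for i in range(10)]
        return carriers

    def test_motif_group_membership(self):
        cts = self._fixture()
        hits = [sg.MotifHit("QETQ", 4, 5, 0, 1e-6)]
        groups = sg.assemble_groups(hits, [], cts, p_motif=1e-3)
        (g,) = groups
        assert g.n_unique_clonotypes == 5
        assert g.n_samples == 4

    def test_clonotype_in_multiple_groups(self):
        cts = [make_clonotype("c1", "CASSQETQLDRF")]
        hits = [sg.MotifHit("QETQ", 1, 1, 0, 1e-6),
                sg.MotifHit("ETQL", 1, 1, 0, 1e-6)]
        groups = sg.assemble_groups(hits, [], cts, p_motif=1e-3)
        assert all(g.member_clonotype_ids == ["c1"] for g in groups)
        assert len(groups) == 2

    def test_no_hits_no_clusters_empty(self):
        assert sg.assemble_groups([], [], self._fixture()) == []

    def test_vgene_bias_matches_oracle(self):
        # 6-member group all TRBV5; repertoire 60 of 600 carry TRBV5
        cts = {f"m{i}": make_clonotype(f"m{i}", "CASSQETQW" + "AVLIMFWYGSTCNQ"[i] + "F", vb="TRBV5")
               for i in range(6)}
        background = {f"b{i}": make_clonotype(f"b{i}", "CASSLDRG" + "".join("AVLIMFWYGSTDEKR"[d] for d in map(int, str(i))) + "WF",
                                              vb="TRBV5" if i < 54 else f"TRBV{i % 9 + 10}")
                      for i in range(594)}
        group = sg.SpecificityGroup(
            "g1", "QETQ", "local", list(cts), 6, 3, {})
        p = sg.vgene_bias(group, {**cts, **background})
        assert p == pytest.approx(hypergeom_tail_oracle(6, 6, 54, 594), abs=1e-12)

    def test_no_bias_p_at_least_half(self):
        cts = {f"c{i}": make_clonotype(f"c{i}", "CASSQETQW" + "AVLIMFWYGSTCNQ"[i] + "F", vb=f"TRBV{i % 5}")
               for i in range(10)}
        group = sg.SpecificityGroup("g1", "QETQ", "local", list(cts), 10, 3, {})
        assert sg.vgene_bias(group, cts) >= 0.5

    def test_single_member_group_boundary(self):
        cts = {"c0": make_clonotype("c0", "CASSQETQWAF", vb="TRBV5")}
        background = {f"b{i}": make_clonotype(f"b{i}", "CASSLDRG" + "".join("AVLIMFWYGSTDEKR"[d] for d in map(int, str(i))) + "WF", vb="TRBV1")
                      for i in range(9)}
        group = sg.SpecificityGroup("g1", "QETQ", "local", ["c0"], 1, 1, {})
        p = sg.vgene_bias(group, {**cts, **background})
        assert p == pytest.approx(hypergeom_tail_oracle(1, 1, 0, 9), abs=1e-12)

    def test_final_score_product(self):
        g = sg.SpecificityGroup("g1", "QETQ", "local", [], 0, 0, {},
                                motif_p=1e-4, vgene_bias_p=0.03, length_p=0.5)
        assert sg.final_score(g) == pytest.approx(1.5e-6)
        g2 = sg.SpecificityGroup("g1", "QETQ", "local", [], 0, 0, {},
                                 motif_p=0.5, vgene_bias_p=1e-4, length_p=0.03)
        assert sg.final_score(g2) == pytest.approx(sg.final_score(g))

    def test_all_components_one(self):
        g = sg.SpecificityGroup("g1", "QETQ", "local", [], 0, 0, {})
        assert sg.final_score(g) == 1.0


class TestFilterGroups:
    def _group(self, **kw):
        base = dict(group_id="g", seed="QETQ", kind="local",
                    member_clonotype_ids=list("abcd"), n_unique_clonotypes=4,
                    n_samples=3, per_condition_cell_counts={},
                    vgene_bias_p=0.01, motif_p=1e-7, length_p=0.01)
        base.update(kw)
        g = sg.SpecificityGroup(**base)
        g.final_score = sg.final_score(g)
        return g

    def test_too_few_clonotypes_fails(self):
        g = self._group(n_unique_clonotypes=3)
        assert sg.filter_groups([g]) == []

    def test_defaults_pass_strong_group(self):
        g = self._group()
        assert sg.filter_groups([g]) == [g]
        assert g.passes_filter

    def test_vacuous_thresholds_pass_everything(self):
        weak = self._group(n_unique_clonotypes=1, n_samples=1,
                           vgene_bias_p=0.9, motif_p=0.9, length_p=0.9)
        assert sg.filter_groups([weak], min_clonotypes=1, min_samples=1,
                                vgene_p=1.0, final=1.0) == [weak]

    def test_methods_variant_min_samples(self):
        g = self._group(n_samples=3)
        assert sg.filter_groups([g], min_samples=4) == []


def test_membership_monotone_under_added_clonotype():
    """Adding an unrelated clonotype never removes an existing group."""
    cts = [make_clonotype(f"c{i}", "CASSQETQW" + "AVLIMFWYGSTCNQ"[i] + "F", samples=(f"S{i % 3 + 1}",))
           for i in range(5)]
    ref = sg.ReferenceRepertoire.from_sequences(
        ["CASSLDR" + a + "".join("AVLIMFWYGS"[d] for d in map(int, str(i))) + "WF" for i in range(50) for a in "GAV"])
    groups_before, _ = sg.run_gliph(cts, ref, p_motif=0.05,
                                    min_clonotypes=1, min_samples=1,
                                    vgene_p=1.0, final=1.0)
    extra = make_clonotype("z1", "CAWWHHKKPPF", vb="TRBV9")
    groups_after, _ = sg.run_gliph(cts + [extra], ref, p_motif=0.05,
                                   min_clonotypes=1, min_samples=1,
                                   vgene_p=1.0, final=1.0)
    seeds_before = {g.seed for g in groups_before}
    seeds_after = {g.seed for g in groups_after}
    assert seeds_before <= seeds_after
    for g_after in groups_after:
        match = [g for g in groups_before if g.seed == g_after.seed]
        if match:
            assert set(match[0].member_clonotype_ids) <= set(
                g_after.member_clonotype_ids)
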