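"""Gene-set perturbation tests: one-on-group fold changes, the set-vs-all
t-test, Stouffer combination, null calibration and essential genes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybherit.enrichment import (
    GeneSet,
    assign_primary_function,
    combine_comparisons,
    essential_genes,
    estimate_column_correlation,
    gage_set_test,
    one_on_group_foldchanges,
    read_gmt,
    run_enrichment,
    write_gmt,
    _combine_dependent,
)

from conftest import make_matrix


def _null_matrix(rng, n_genes, sd=0.3, replicates=6):
    return make_matrix(rng.normal(0, sd, (n_genes, 4 * replicates)), replicates)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

class TestOneOnGroup:
    def test_subtraction(self):
        values = np.zeros((1, 24))
        values[0, :6] = 2.0     # WW block
        values[0, 18:] = 3.0    # DD block
        fc = one_on_group_foldchanges(make_matrix(values))
        assert (fc.to_numpy() == 1.0).all()

    def test_test_replicate_at_control_mean_gives_zero_column(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (50, 24))
        values[:, 18] = values[:, :6].mean(axis=1)   # first DD replicate
        fc = one_on_group_foldchanges(make_matrix(values))
        np.testing.assert_allclose(fc.iloc[:, 0], 0.0, atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (100, 24))
        matrix = make_matrix(values)
        fc = one_on_group_foldchanges(matrix)
        ww_cols = matrix.arrays_for("WW")
        for j, col in enumerate(matrix.arrays_for("DD")):
            expected = matrix.values[col] - matrix.values[ww_cols].mean(axis=1)
            np.testing.assert_allclose(fc[col], expected, atol=1e-14)


# ---------------------------------------------------------------------------
# set test
# ---------------------------------------------------------------------------

class TestGageSetTest:
    def test_null_set_p_near_half(self):
        rng = np.random.default_rng(2)
        fc = pd.Series(rng.normal(0, 0.3, 5000), index=[f"g{i}" for i in range(5000)])
        ps = [
            gage_set_test(fc, GeneSet(f"s{k}", frozenset(fc.index[k * 50:(k + 1) * 50])), "up")
            for k in range(40)
        ]
        assert 0.3 < np.mean(ps) < 0.7

    def test_shifted_set_detected_up(self):
        rng = np.random.default_rng(3)
        fc = pd.Series(rng.normal(0, 0.3, 5000), index=[f"g{i}" for i in range(5000)])
        members = list(fc.index[:50])
        fc[members] += 1.0
        gs = GeneSet("s", frozenset(members))
        assert gage_set_test(fc, gs, "up") < 1e-10
        assert gage_set_test(fc, gs, "down") > 0.5

    def test_bidirectional_set_two_way_only(self):
        """Half up, half down: invisible one-directionally, glaring in 2d."""
        rng = np.random.default_rng(4)
        fc = pd.Series(rng.normal(0, 0.3, 5000), index=[f"g{i}" for i in range(5000)])
        members = list(fc.index[:50])
        fc[members[::2]] += 1.0
        fc[members[1::2]] -= 1.0
        gs = GeneSet("s", frozenset(members))
        assert gage_set_test(fc, gs, "up") > 0.01
        assert gage_set_test(fc, gs, "down") > 0.01
        assert gage_set_test(fc, gs, "two_way") < 1e-6

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(5)
        fc = pd.Series(rng.normal(0.2, 0.5, 2000), index=[f"g{i}" for i in range(2000)])
        gs = GeneSet("s", frozenset(fc.index[100:150]))
        p_up = gage_set_test(fc, gs, "up")
        p_down_flipped = gage_set_test(-fc, gs, "down")
        assert p_up == pytest.approx(p_down_flipped, abs=1e-12)

    def test_two_way_invariant_to_sign_flips(self):
        rng = np.random.default_rng(6)
        fc = pd.Series(rng.normal(0, 0.5, 2000), index=[f"g{i}" for i in range(2000)])
        gs = GeneSet("s", frozenset(fc.index[:40]))
        p1 = gage_set_test(fc, gs, "two_way")
        flip = fc.copy()
        flip.iloc[::3] *= -1
        assert gage_set_test(flip, gs, "two_way") == pytest.approx(p1, abs=1e-12)

    def test_degenerate_variance_p_one(self):
        fc = pd.Series(1.0, index=[f"g{i}" for i in range(100)])
        assert gage_set_test(fc, GeneSet("s", frozenset(fc.index[:20])), "up") == 1.0


class TestCombine:
    def test_stouffer_fixed_point(self):
        assert combine_comparisons([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_evidence_accumulates(self):
        assert combine_comparisons([0.01] * 6) < 0.01

    def test_hand_computed_value(self):
        p = [0.2, 0.04, 0.6]
        z = stats.norm.isf(p)
        expected = stats.norm.sf(z.sum() / np.sqrt(3))
        assert combine_comparisons(p) == pytest.approx(expected, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_comparisons([])

    def test_dependent_version_reduces_to_stouffer_at_rho_zero(self):
        p = [0.2, 0.04, 0.6]
        assert _combine_dependent(p, 0.0) == pytest.approx(combine_comparisons(p), abs=1e-12)


# ---------------------------------------------------------------------------
# calibration and the full scan
# ---------------------------------------------------------------------------

def _combined_null_pvalues(rng, n_sets=500, n_genes=5000, direction="up"):
    matrix = _null_matrix(rng, n_genes, sd=0.3)
    fc = one_on_group_foldchanges(matrix)
    which = fc.abs() if direction == "two_way" else fc
    rho = estimate_column_correlation(which)
    genes = np.array(fc.index)
    out = []
    for _ in range(n_sets):
        members = frozenset(rng.choice(genes, size=30, replace=False))
        gs = GeneSet("s", members)
        ps = [gage_set_test(fc[c], gs, direction) for c in fc.columns]
        out.append(_combine_dependent(ps, rho))
    return np.array(out)


class TestCalibration:
    def test_null_combined_p_uniform(self):
        """500 null sets: combined p passes a KS uniformity test at 1 %."""
        rng = np.random.default_rng(17)
        pvals = _combined_null_pvalues(rng)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_shared_control_mean_induces_column_correlation(self):
        # the estimated inter-comparison correlation is near 1/(n_control+1)
        rng = np.random.default_rng(18)
        fc = one_on_group_foldchanges(_null_matrix(rng, 8000, sd=0.3))
        rho = estimate_column_correlation(fc)
        assert abs(rho - 1 / 7) < 0.05


class TestRunEnrichment:
    def _planted(self, rng, n_genes=3000):
        values = rng.normal(0, 0.25, (n_genes, 24))
        genes = [f"g{i}" for i in range(n_genes)]
        up = genes[:50]
        two = genes[50:100]
        dd = slice(18, 24)
        values[:50, dd] += 1.0
        values[50:100:2, dd] += 1.0
        values[51:100:2, dd] -= 1.0
        matrix = make_matrix(values, row_ids=genes)
        sets = [GeneSet("planted_up", frozenset(up), "Planted"),
                GeneSet("planted_2d", frozenset(two), "Planted")]
        for k in range(50):
            members = rng.choice(genes[100:], size=30, replace=False)
            sets.append(GeneSet(f"null_{k:02d}", frozenset(members), "Metabolism"))
        return matrix, sets

    def test_planted_sets_exactly_significant(self):
        rng = np.random.default_rng(19)
        matrix, sets = self._planted(rng)
        res = run_enrichment(matrix, sets)
        sig_ids = set(res.loc[res["significant"], "set_id"])
        assert sig_ids == {"planted_up", "planted_2d"}
        up_hit = res[(res.set_id == "planted_up") & (res.direction == "up")]
        assert bool(up_hit["significant"].iloc[0])
        two_hit = res[(res.set_id == "planted_2d") & (res.direction == "two_way")]
        assert bool(two_hit["significant"].iloc[0]) and bool(two_hit["focus_2d"].iloc[0])
        # the bidirectional set stays invisible one-directionally
        for d in ("up", "down"):
            assert not res[(res.set_id == "planted_2d") & (res.direction == d)][
                "significant"
            ].iloc[0]

    def test_zero_q_threshold_empty(self):
        rng = np.random.default_rng(20)
        matrix, sets = self._planted(rng)
        res = run_enrichment(matrix, sets, q_threshold=0.0)
        assert not res["significant"].any()

    def test_excluded_group_absent(self):
        rng = np.random.default_rng(21)
        matrix, sets = self._planted(rng)
        res = run_enrichment(matrix, sets, exclude_groups={"Planted"})
        assert "planted_up" not in set(res["set_id"])

    def test_results_invariant_to_set_and_gene_order(self):
        rng = np.random.default_rng(22)
        matrix, sets = self._planted(rng, n_genes=800)
        res1 = run_enrichment(matrix, sets[:10])
        perm = matrix.subset_rows(list(rng.permutation(matrix.values.index)))
        res2 = run_enrichment(perm, sets[:10][::-1])
        merged = res1.merge(res2, on=["set_id", "direction"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["p_raw_1"], merged["p_raw_2"], atol=1e-12)


class TestEssentialGenes:
    def test_strong_and_significant_included(self):
        rng = np.random.default_rng(23)
        values = rng.normal(0, 0.25, (2000, 24))
        values[0, 18:] += 3.0     # strong, significant member
        matrix = make_matrix(values)
        gs = GeneSet("s", frozenset(["g0", "g1"]))
        ess = essential_genes(matrix, gs)
        assert "g0" in ess and "g1" not in ess

    def test_strong_but_nonsignificant_excluded(self):
        rng = np.random.default_rng(24)
        values = rng.normal(0, 0.05, (2000, 24))
        # g0: large mean difference but huge within-group scatter -> p > 0.05
        values[0, :6] = [-4, 4, -4, 4, -4, 4.001]
        values[0, 18:] = [-1, 9, -1, 9, -1, 9.0]
        matrix = make_matrix(values)
        from hybherit.diffexpr import welch_t

        _, p = welch_t(values[0, 18:], values[0, :6])
        assert p > 0.05
        assert essential_genes(matrix, GeneSet("s", frozenset(["g0"]))) == []

    def test_null_inclusion_rate_calibrated(self):
        # at n=6/6 and SD 0.25 the t-test cut (~2.2 SE) is stricter than the
        # 1-SD magnitude cut, so the joint null rate sits at ~0.05; check it
        # is calibrated rather than inflated
        rng = np.random.default_rng(25)
        values = rng.normal(0, 0.25, (4000, 24))
        matrix = make_matrix(values)
        gs = GeneSet("s", frozenset(f"g{i}" for i in range(1000)))
        frac = len(essential_genes(matrix, gs)) / 1000
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert frac <= 0.05 + 3 * se


class TestAssignAndGmt:
    def test_largest_candidate_wins(self):
        analysed = [f"g{i}" for i in range(60)]
        big = GeneSet("big", frozenset(analysed[:40]))
        small = GeneSet("small", frozenset(analysed[:12]))
        assert assign_primary_function("g3", [big, small], analysed) == "big"

    def test_single_candidate(self):
        gs = GeneSet("only", frozenset(["g1"]))
        assert assign_primary_function("g1", [gs], ["g1"]) == "only"

    def test_tie_breaks_lexicographically(self):
        a = GeneSet("alpha", frozenset(["g1", "g2"]))
        b = GeneSet("beta", frozenset(["g1", "g3"]))
        assert assign_primary_function("g1", [b, a], ["g1", "g2", "g3"]) == "alpha"

    def test_gmt_round_trip(self, tmp_path):
        sets = [GeneSet("s1", frozenset(["a", "b"]), "Metabolism"),
                GeneSet("s2", frozenset(["c"]), "Human Diseases")]
        write_gmt(sets, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert {(g.set_id, g.functional_group, g.member_genes) for g in back} == {
            (g.set_id, g.functional_group, g.member_genes) for g in sets
        }
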