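import numpy as np
import pandas as pd
import pytest
from scipy import stats

from concorddeg import (
    OrthologMap,
    binom_two_sided_logspace,
    binom_upper_tail_logspace,
    concordance_test,
    conserved_signature,
    logistic_match_curve,
    map_orthologs,
    null_match_probability,
    overlap_significant,
    remove_exclusion_genes,
    top_n,
)
from concorddeg.io_core import DataError
from conftest import make_deg_table


def minlike_enumeration(k, n, p0):
    """Independent oracle: direct pmf summation, no log-space tricks."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()


class TestOrthologMapping:
    def test_symbol_translation(self):
        t = make_deg_table(["Ms4a1"], [1.2], [0.01])
        out, frac = map_orthologs(t, OrthologMap([("MS4A1", "Ms4a1")]))
        assert out["gene"].tolist() == ["MS4A1"]
        assert out["log2fc"].iloc[0] == 1.2
        assert frac == 0.0

    def test_unmapped_fraction_one_percent(self):
        genes = [f"Gene{i}" for i in range(100)]
        t = make_deg_table(genes, np.ones(100), np.full(100, 0.01))
        omap = OrthologMap([(g.upper(), g) for g in genes[:99]])
        out, frac = map_orthologs(t, omap)
        assert len(out) == 99
        assert frac == pytest.approx(0.01)

    def test_identity_map_is_noop(self):
        t = make_deg_table(["A", "B"], [1, -1], [0.1, 0.2])
        out, _ = map_orthologs(t, OrthologMap([("A", "A"), ("B", "B")]))
        assert out["gene"].tolist() == ["A", "B"]

    def test_empty_intersection_error(self):
        t = make_deg_table(["X"], [1.0], [0.5])
        with pytest.raises(DataError):
            map_orthologs(t, OrthologMap([("A", "a")]))


class TestOverlap:
    def test_worked_example(self, toy_deg_trio):
        joined = overlap_significant(toy_deg_trio, alpha=0.05)
        assert sorted(joined["gene"]) == ["g1", "g2", "g3"]
        matched = set(joined.loc[joined["matched"], "gene"])
        assert matched == {"g1", "g3"}

    def test_alpha_one_gives_symbol_intersection(self, toy_deg_trio):
        joined = overlap_significant(toy_deg_trio, alpha=1.0)
        assert sorted(joined["gene"]) == ["g1", "g2", "g3", "g4"]

    def test_zero_lfc_never_matched(self):
        t1 = make_deg_table(["g"], [0.0], [0.01], "a")
        t2 = make_deg_table(["g"], [1.0], [0.01], "b")
        joined = overlap_significant([t1, t2])
        assert not joined["matched"].iloc[0]

    def test_needs_two_tables(self):
        with pytest.raises(DataError):
            overlap_significant([make_deg_table(["g"], [1.0], [0.01])])


class TestNullMatchProbability:
    @pytest.mark.parametrize("D,expected", [(1, 1.0), (2, 0.5), (3, 0.25), (4, 0.125)])
    def test_values(self, D, expected):
        assert null_match_probability(D) == expected

    def test_invalid_D(self):
        with pytest.raises(DataError):
            null_match_probability(0)


class TestBinomialTails:
    def test_small_example_enumerated(self):
        # pmf(3) + pmf(4) for Binomial(4, 0.25)
        p, _ = binom_two_sided_logspace(3, 4, 0.25)
        assert p == pytest.approx(0.046875 + 0.00390625, rel=1e-12)

    def test_single_trial_symmetric(self):
        p, _ = binom_two_sided_logspace(1, 1, 0.5)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_exhaustively(self):
        for p0 in (0.1, 0.25, 0.5):
            for n in range(1, 61):
                expected = [minlike_enumeration(k, n, p0) for k in range(n + 1)]
                got = [binom_two_sided_logspace(k, n, p0)[0] for k in range(n + 1)]
                np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_upper_tail_conventions(self):
        # strict vs inclusive tails against direct summation
        pmf = stats.binom.pmf(np.arange(11), 10, 0.3)
        p_strict, _ = binom_upper_tail_logspace(6, 10, 0.3, strict=True)
        p_incl, _ = binom_upper_tail_logspace(6, 10, 0.3, strict=False)
        assert p_strict == pytest.approx(pmf[7:].sum(), rel=1e-12)
        assert p_incl == pytest.approx(pmf[6:].sum(), rel=1e-12)

    def test_log10_accurate_beyond_underflow(self):
        p, log10_p = binom_two_sided_logspace(5000, 5000, 0.25)
        assert p == 0.0  # underflows double precision
        np.testing.assert_allclose(log10_p, 5000 * np.log10(0.25), rtol=1e-10)

    def test_log10_matches_log_p_when_representable(self):
        p, log10_p = binom_two_sided_logspace(703, 1713, 0.25)
        np.testing.assert_allclose(log10_p, np.log10(p), rtol=1e-12)

    def test_monotone_in_k_above_null(self):
        ps = [binom_two_sided_logspace(k, 100, 0.25)[1] for k in range(30, 101)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(DataError):
            binom_two_sided_logspace(5, 4, 0.25)
        with pytest.raises(DataError):
            binom_two_sided_logspace(1, 4, 1.0)


class TestConcordanceTest:
    def _joined(self, n, k, D=3):
        signs = np.ones((n, D))
        signs[k:, 1] = -1  # unmatched rows disagree in dataset 1
        cols = {"gene": [f"g{i}" for i in range(n)]}
        for d in range(D):
            cols[f"log2fc_ds{d}"] = signs[:, d]
            cols[f"p_ds{d}"] = np.full(n, 0.01)
        df = pd.DataFrame(cols)
        df["matched"] = np.arange(n) < k
        df.attrs["dataset_ids"] = [f"ds{d}" for d in range(D)]
        return df

    def test_counts_and_probabilities(self):
        res = concordance_test(self._joined(1713, 703))
        assert (res.n_overlap, res.n_matched, res.p0) == (1713, 703, 0.25)
        assert res.p_binomial == pytest.approx(minlike_enumeration(703, 1713, 0.25), rel=1e-9)

    def test_all_matched_small_n_enumeration(self):
        res = concordance_test(self._joined(10, 10))
        assert res.p_binomial == pytest.approx(minlike_enumeration(10, 10, 0.25), rel=1e-10)

    def test_null_centred_data_give_large_p(self):
        res = concordance_test(self._joined(1000, 250))
        assert res.p_binomial > 0.9

    def test_invariant_to_dataset_order(self, toy_deg_trio):
        a = concordance_test(overlap_significant(toy_deg_trio))
        b = concordance_test(overlap_significant(toy_deg_trio[::-1]))
        assert a.n_matched == b.n_matched
        assert a.p_binomial == pytest.approx(b.p_binomial, rel=1e-12)

    def test_fixed_p0_override(self):
        res = concordance_test(self._joined(100, 50), p0_mode="fixed", p0_fixed=0.5)
        assert res.p0 == 0.5


class TestLogisticCurve:
    def test_two_level_closed_form(self):
        # match rates 4/8 at x=0 and 6/8 at x=1: log-odds 0 and log 3
        x = np.array([0] * 8 + [1] * 8, dtype=float)
        y = np.array([1] * 4 + [0] * 4 + [1] * 6 + [0] * 2, dtype=float)
        fit = logistic_match_curve(x, y)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.slope == pytest.approx(np.log(3), rel=1e-5)
        assert not fit.separation

    def test_all_matched_flags_separation(self):
        fit = logistic_match_curve(np.linspace(0, 1, 20), np.ones(20))
        assert fit.separation

    def test_complete_separation_flagged_not_divergent(self):
        x = np.linspace(0, 1, 40)
        y = (x > 0.5).astype(float)
        fit = logistic_match_curve(x, y)
        assert fit.separation and np.isnan(fit.slope)

    def test_constant_covariate_error(self):
        with pytest.raises(DataError, match="constant"):
            logistic_match_curve(np.ones(20), np.r_[np.ones(10), np.zeros(10)])

    def test_monte_carlo_recovery_within_3se(self):
        rng = np.random.default_rng(42)
        beta0, beta1 = 1.0, -2.0
        x = rng.uniform(0, 1, 5000)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.uniform(size=5000) < p).astype(float)
        fit = logistic_match_curve(x, y)
        assert abs(fit.slope - beta1) < 3 * fit.slope_se
        assert fit.slope_p < 0.05


class TestSignature:
    def test_only_matched_genes(self, toy_deg_trio):
        sig = conserved_signature(overlap_significant(toy_deg_trio))
        assert sorted(sig["gene"]) == ["g1", "g3"]

    def test_aggregate_rank_arithmetic(self):
        df = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "log2fc_d1": [1, 1], "p_d1": [0.01, 0.02],
                "log2fc_d2": [1, 1], "p_d2": [0.03, 0.02],
                "log2fc_d3": [1, 1], "p_d3": [0.01, 0.02],
                "matched": [True, True],
            }
        )
        df.attrs["dataset_ids"] = ["d1", "d2", "d3"]
        sig = conserved_signature(df).set_index("gene")
        # gene a ranks (1, 2, 1) -> 4/3
        assert sig.loc["a", "aggregate_rank"] == pytest.approx(4 / 3)

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame(
            {
                "gene": ["zzz", "aaa"],
                "log2fc_d1": [1, 1], "p_d1": [0.01, 0.01],
                "log2fc_d2": [1, 1], "p_d2": [0.01, 0.01],
                "matched": [True, True],
            }
        )
        df.attrs["dataset_ids"] = ["d1", "d2"]
        sig = conserved_signature(df)
        assert sig["gene"].tolist() == ["aaa", "zzz"]

    def test_no_matched_genes_empty_with_warning(self, caplog):
        df = pd.DataFrame(
            {"gene": ["g"], "log2fc_d1": [1.0], "p_d1": [0.01],
             "log2fc_d2": [-1.0], "p_d2": [0.01], "matched": [False]}
        )
        df.attrs["dataset_ids"] = ["d1", "d2"]
        with caplog.at_level("WARNING", logger="concorddeg"):
            sig = conserved_signature(df)
        assert sig.empty

    def test_top_n_truncation(self, toy_deg_trio):
        sig = conserved_signature(overlap_significant(toy_deg_trio))
        assert len(top_n(sig, 1)) == 1
        assert top_n(sig, 100) == sig["gene"].tolist()
        with pytest.raises(DataError):
            top_n(sig, 0)

    def test_exclusion_list(self):
        assert remove_exclusion_genes(["A", "B", "C"], {"B"}) == ["A", "C"]
        assert remove_exclusion_genes(["A", "B"], set()) == ["A", "B"]
        assert remove_exclusion_genes(["A"], {"A", "B"}) == []
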