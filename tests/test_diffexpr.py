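import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncwhiten.diffexpr import (
    bh_adjust,
    call_status,
    del_union,
    de_test,
    estimate_dispersion,
    nb_wald,
    pairwise_comparisons,
    size_factors,
)
from lncwhiten.model import DEResult, PositionalCategory, ValidationError
from oracles import bh_stepup


def _counts(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = _counts({"f1": [10, 10], "f2": [3, 3]})
        np.testing.assert_allclose(size_factors(df), [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # geomeans: f1 sqrt(2*8)=4 -> ratios (0.5, 2); f2 = 2 -> (1, 1)
        df = _counts({"f1": [2, 8], "f2": [2, 2]})
        np.testing.assert_allclose(size_factors(df), [0.75, 1.5])

    def test_doubling_a_column_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.poisson(50, size=(100, 4)) + 1, columns=list("abcd")
        )
        base = size_factors(df)
        df2 = df.copy()
        df2["c"] = df2["c"] * 2
        doubled = size_factors(df2)
        # factors are defined up to overall scale: the doubled sample's
        # factor doubles relative to every untouched sample
        assert doubled["c"] / doubled["a"] == pytest.approx(
            2 * base["c"] / base["a"]
        )

    def test_no_all_positive_feature_is_an_error(self):
        df = _counts({"f1": [0, 5], "f2": [5, 0]})
        with pytest.raises(ValidationError, match="pseudo-reference"):
            size_factors(df)


class TestDispersion:
    def _groups(self, n):
        return [f"a{i}" for i in range(n)], [f"b{i}" for i in range(n)]

    def test_constant_counts_have_zero_dispersion(self):
        ga, gb = self._groups(3)
        df = pd.DataFrame(
            [[7] * 6], index=["f1"], columns=ga + gb, dtype=float
        )
        assert estimate_dispersion(df, ga, gb)["f1"] == 0.0

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(1)
        ga, gb = self._groups(50)
        mu = rng.uniform(50, 500, 1000)
        df = pd.DataFrame(
            rng.poisson(mu[:, None], size=(1000, 100)).astype(float),
            columns=ga + gb,
        )
        est = estimate_dispersion(df, ga, gb)
        assert est.mean() < 0.01

    def test_nb_dispersion_recovered_within_20_percent(self):
        rng = np.random.default_rng(2)
        ga, gb = self._groups(50)
        alpha, r = 0.2, 5.0
        mu = rng.uniform(100, 500, 1000)
        counts = rng.negative_binomial(
            r, (r / (r + mu))[:, None], size=(1000, 100)
        ).astype(float)
        df = pd.DataFrame(counts, columns=ga + gb)
        est = estimate_dispersion(df, ga, gb)
        assert abs(est.mean() - alpha) / alpha < 0.2

    def test_single_replicate_group_rejected(self):
        df = _counts({"f1": [1, 2, 3]}, samples=["a1", "a2", "b1"])
        with pytest.raises(ValidationError):
            estimate_dispersion(df, ["a1", "a2"], ["b1"])


class TestNbWald:
    def test_identical_groups_null_result(self):
        df = _counts({"f1": [10, 20, 30, 10, 20, 30],
                      "f2": [5, 5, 5, 5, 5, 5]})
        res = nb_wald(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-12)

    def test_swapping_groups_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.poisson(100, size=(50, 6)), columns=[f"s{i}" for i in range(6)]
        )
        ga, gb = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = nb_wald(df, ga, gb)
        rev = nb_wald(df, gb, ga)
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"], atol=1e-10)
        np.testing.assert_allclose(rev["p"], fwd["p"], atol=1e-10)

    def test_overlapping_groups_rejected(self):
        df = _counts({"f1": [1, 2, 3]}, samples=["s0", "s1", "s2"])
        with pytest.raises(ValidationError):
            nb_wald(df, ["s0", "s1"], ["s1", "s2"])

    def test_type_one_error_near_nominal_on_null(self):
        """Null NB counts (alpha=0.1, n=3/group, 2,000 features): the
        fraction of p < 0.05 stays within 3 binomial SDs of 0.05."""
        rng = np.random.default_rng(7)
        n_feat, r = 2000, 10.0
        mu = rng.uniform(50, 500, n_feat)
        counts = rng.negative_binomial(
            r, (r / (r + mu))[:, None], size=(n_feat, 6)
        )
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(6)])
        res = nb_wald(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        frac = (res["p"] < 0.05).mean()
        sd = math.sqrt(0.05 * 0.95 / n_feat)
        assert abs(frac - 0.05) < 3 * sd

    def test_planted_fold_changes_recovered(self):
        """|log2FC|=2.5 planted at low dispersion on a mostly-null background:
        sensitivity > 0.9 with the planted direction, n=3 per group."""
        rng = np.random.default_rng(11)
        n, n_up, n_down = 2000, 100, 100
        alpha = 0.01
        r = 1 / alpha
        mu_a = rng.uniform(100, 400, n)
        mu_b = mu_a.copy()
        mu_b[:n_up] *= 2**2.5
        mu_b[n_up : n_up + n_down] /= 2**2.5
        ca = rng.negative_binomial(r, (r / (r + mu_a))[:, None], size=(n, 3))
        cb = rng.negative_binomial(r, (r / (r + mu_b))[:, None], size=(n, 3))
        df = pd.DataFrame(
            np.hstack([ca, cb]), columns=[f"s{i}" for i in range(6)]
        )
        res = nb_wald(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        fdr = bh_adjust(res["p"].to_numpy())
        up = (res["log2fc"].to_numpy() > 1.5) & (fdr < 0.01)
        down = (res["log2fc"].to_numpy() < -1.5) & (fdr < 0.01)
        recovered = up[:n_up].sum() + down[n_up : n_up + n_down].sum()
        assert recovered / (n_up + n_down) > 0.9
        # direction never inverted among planted calls
        assert not down[:n_up].any()
        assert not up[n_up : n_up + n_down].any()
        # median effect estimate close to truth
        assert abs(np.median(res["log2fc"][:n_up]) - 2.5) < 0.25


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=4)
    )
    def test_matches_hand_stepup_on_short_vectors(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_stepup(ps), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_adjusted_dominates_raw_and_is_bounded(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDELCalling:
    @pytest.mark.parametrize(
        "log2fc,fdr,status",
        [
            (1.6, 0.005, "up"),
            (1.5, 0.001, "ns"),  # strict >
            (-2.0, 0.5, "ns"),
            (-1.6, 0.009, "down"),
            (2.0, 0.01, "ns"),  # strict <
        ],
    )
    def test_strict_thresholds(self, log2fc, fdr, status):
        assert call_status(log2fc, fdr) == status

    def test_six_pairwise_comparisons_for_four_stages(self):
        comps = pairwise_comparisons(["D0", "D15", "D85", "Y2"])
        assert len(comps) == 6
        assert ("D0", "D15") in comps and ("D85", "Y2") in comps

    def test_union_and_breakdown(self):
        def res(fid, comp, status):
            return DEResult(fid, comp, 2.0 if status == "up" else 0.0,
                            0.001, 0.001 if status != "ns" else 0.9, status)

        per_comp = {
            "c1": [res("a", "c1", "up"), res("b", "c1", "ns")],
            "c2": [res("a", "c2", "down"), res("c", "c2", "up")],
        }
        cats = {"a": PositionalCategory.LINCRNA,
                "c": PositionalCategory.ANTISENSE}
        union, breakdown = del_union(per_comp, cats)
        assert union == {"a", "c"}
        assert breakdown["union_total"] == 2
        assert sum(v for k, v in breakdown.items() if k != "union_total") == 2

    def test_de_test_end_to_end_statuses(self, default_bundle):
        b = default_bundle
        lnc = sorted(b.ledger.expected_retained_novel())
        results = de_test(b.counts, "D0", "D15", feature_ids=lnc)
        assert {r.comparison for r in results} == {"D15_vs_D0"}
        for r in results:
            assert r.fdr >= r.p - 1e-12
            assert r.status == call_status(r.log2fc, r.fdr)
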