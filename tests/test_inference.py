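import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ciberdyn.inference import (
    InferenceConfig,
    aggregate_weighted,
    apply_barcode_filter,
    barcode_log_ratio,
    estimate_variance_inflation,
    growth_log2fc,
    infer_phenotypes,
    normalize_to_controls,
    wald_fdr,
)
from ciberdyn.library import ParameterError


class TestBarcodeLogRatio:
    @pytest.mark.parametrize(
        "cp,cu,expected",
        [
            (15, 15, 0.0),
            (0, 0, 0.0),  # pseudocount symmetry
            (32, 8, math.log2(32.5 / 8.5)),
        ],
    )
    def test_values(self, cp, cu, expected):
        ratio, var = barcode_log_ratio(cp, cu, 0.5)
        assert ratio == pytest.approx(expected, abs=1e-12)
        assert var == pytest.approx(
            (1 / math.log(2)) ** 2 * (1 / (cp + 0.5) + 1 / (cu + 0.5))
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            barcode_log_ratio(-1, 5, 0.5)
        with pytest.raises(ParameterError):
            barcode_log_ratio(5, 5, 0.0)


class TestAggregation:
    def test_equal_variances_arithmetic_mean(self):
        est, se, n = aggregate_weighted([1.0, 3.0, 5.0], [0.2, 0.2, 0.2])
        assert est == pytest.approx(3.0)
        assert n == 3

    def test_single_barcode_passthrough(self):
        est, se, n = aggregate_weighted([1.7], [0.09])
        assert (est, se, n) == (pytest.approx(1.7), pytest.approx(0.3), 1)

    def test_weighted_mean_closed_form(self):
        # (1/0.25 + 2/0.75) / (1/0.25 + 1/0.75); se = sqrt(1/(4 + 4/3))
        est, se, n = aggregate_weighted([1.0, 2.0], [0.25, 0.75])
        assert est == pytest.approx((1 / 0.25 + 2 / 0.75) / (1 / 0.25 + 1 / 0.75))
        assert est == pytest.approx(1.25)
        assert se == pytest.approx(math.sqrt(1 / (4 + 4 / 3)))
        assert se == pytest.approx(0.4330127, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_weighted([1.0], [0.0])


class TestGrowth:
    def test_identical_shares_zero(self):
        val, _ = growth_log2fc([50], [50], 1000.0, 1000.0, 0.5)
        assert val[0] == pytest.approx(0.0)

    def test_share_doubling_is_one(self):
        val, _ = growth_log2fc([100 - 0.5], [50 - 0.5], 1000.0, 1000.0, 0.5)
        assert val[0] == pytest.approx(1.0)

    def test_bad_totals_rejected(self):
        with pytest.raises(ParameterError):
            growth_log2fc([1], [1], 0.0, 10.0)


class TestNormalization:
    def _table(self, values, perts=None):
        n = len(values)
        perts = perts or [f"p{i}" for i in range(n)]
        return pd.DataFrame(
            {"perturbation": perts, "sample_id": "s1", "isr_log2fc": values}
        )

    def test_zero_median_controls_leave_estimates_unchanged(self):
        t = self._table([-0.1, 0.0, 0.1, 2.0])
        out = normalize_to_controls(t, ["p0", "p1", "p2"])
        np.testing.assert_allclose(out.isr_log2fc, t.isr_log2fc)

    def test_median_shift(self):
        t = self._table([0.2, 0.4, 0.9, 2.0])
        out = normalize_to_controls(t, ["p0", "p1", "p2"])
        np.testing.assert_allclose(out.isr_log2fc, t.isr_log2fc - 0.4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shift=st.floats(-100, 100))
    def test_location_equivariance(self, shift):
        base = [0.2, 0.4, 0.9, 2.0, -1.0]
        out0 = normalize_to_controls(self._table(base), ["p0", "p1", "p2"])
        out1 = normalize_to_controls(
            self._table([v + shift for v in base]), ["p0", "p1", "p2"]
        )
        np.testing.assert_allclose(out0.isr_log2fc, out1.isr_log2fc, atol=1e-9)

    def test_no_controls_errors(self):
        with pytest.raises(ParameterError):
            normalize_to_controls(self._table([1.0]), ["absent"])


class TestFilterAndFdr:
    def test_barcode_filter(self):
        t = pd.DataFrame({"n_barcodes": [1, 2, 3, 1]})
        kept, removed = apply_barcode_filter(t, 2)
        assert removed == 2 and len(kept) == 2
        kept1, removed1 = apply_barcode_filter(t, 1)
        assert removed1 == 0 and len(kept1) == 4

    def test_wald_trivials(self):
        z, p, q = wald_fdr([0.0], [1.0])
        assert z[0] == 0.0 and p[0] == 1.0 and q[0] == 1.0
        z, p, q = wald_fdr([0.3], [0.1])
        assert q[0] == p[0]  # single test: q = p

    def test_bh_by_hand(self):
        # p = (0.01, 0.02, 0.03), m = 3 -> q = (0.03, 0.03, 0.03)
        from scipy import stats

        ps = np.array([0.01, 0.02, 0.03])
        est = stats.norm.isf(ps / 2)
        z, p, q = wald_fdr(est, np.ones(3))
        np.testing.assert_allclose(p, ps, atol=1e-12)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    def test_q_at_least_p(self, rng):
        p_in = rng.uniform(0, 1, 100)
        est = 1.0 * np.sign(rng.normal(size=100))
        from scipy import stats

        z, p, q = wald_fdr(stats.norm.isf(p_in / 2) * est, np.ones(100))
        assert (q >= p - 1e-12).all()

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ParameterError):
            wald_fdr([1.0], [0.0])


class TestVarianceInflation:
    def test_calibrated_data_near_unity(self, rng):
        n_groups, k = 400, 4
        var = 0.04
        vals = rng.normal(0, np.sqrt(var), size=(n_groups, k))
        df = pd.DataFrame(
            {
                "value": vals.ravel(),
                "var": var,
                "group": np.repeat(np.arange(n_groups), k),
            }
        )
        infl = estimate_variance_inflation(df, "value", "var", "group")
        assert infl == pytest.approx(1.0, abs=0.15)

    def test_overdispersion_detected(self, rng):
        n_groups, k = 400, 4
        vals = rng.normal(0, 0.4, size=(n_groups, k))
        df = pd.DataFrame(
            {
                "value": vals.ravel(),
                "var": 0.04,
                "group": np.repeat(np.arange(n_groups), k),
            }
        )
        infl = estimate_variance_inflation(df, "value", "var", "group")
        assert infl == pytest.approx(4.0, rel=0.2)


def _toy_counts(scale=1):
    # two perturbations x two barcodes, one control pair with two barcodes
    rows = []
    data = {
        ("C1", "UBC6"): (1000, 900), ("C1", "PCL5"): (2000, 3600),
        ("C2", "UBC6"): (800, 700), ("C2", "PCL5"): (1600, 2900),
        ("C3", "UBC6"): (1200, 1100), ("C3", "PCL5"): (1200, 1150),
        ("C4", "UBC6"): (900, 1000), ("C4", "PCL5"): (950, 1030),
        ("C5", "UBC6"): (1000, 1000), ("C5", "PCL5"): (990, 1005),
        ("C6", "UBC6"): (1010, 995), ("C6", "PCL5"): (1000, 1001),
    }
    for (cid, rep), (pre, post) in data.items():
        rows.append(
            {"construct_id": cid, "reporter": rep, "pre": pre * scale, "post": post * scale}
        )
    return pd.DataFrame(rows)


def _toy_map():
    return pd.DataFrame(
        {
            "construct_id": [f"C{i}" for i in range(1, 7)],
            "perturbation": ["gA+gB", "gA+gB", "gC+gD", "gC+gD", "HO_01+HO_02", "HO_01+HO_02"],
            "guide_first": ["gA", "gA", "gC", "gC", "HO_01", "HO_01"],
            "guide_second": ["gB", "gB", "gD", "gD", "HO_02", "HO_02"],
            "is_control_pair": [False, False, False, False, True, True],
        }
    )


class TestInferPhenotypes:
    def test_scale_invariance_at_deep_counts(self):
        cfg = InferenceConfig(variance_inflation=False)
        p1 = infer_phenotypes(_toy_counts(1), _toy_map(), cfg)
        p10 = infer_phenotypes(_toy_counts(10), _toy_map(), cfg)
        m = p1.merge(p10, on=["perturbation", "sample_id"], suffixes=("_1", "_10"))
        assert len(m) == len(p1)
        np.testing.assert_allclose(m.isr_log2fc_1, m.isr_log2fc_10, atol=1e-3)

    def test_control_rows_retained_and_centered(self):
        pheno = infer_phenotypes(_toy_counts(), _toy_map())
        ctrl = pheno[pheno.is_control]
        assert not ctrl.empty
        for s, grp in pheno.groupby("sample_id"):
            assert np.median(grp.loc[grp.is_control, "isr_log2fc"]) == 0.0

    def test_missing_pre_sample_errors(self):
        counts = _toy_counts().rename(columns={"pre": "other"})
        with pytest.raises(ParameterError):
            infer_phenotypes(counts, _toy_map())
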