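import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_long
from ictaxis import axis as axis_mod
from ictaxis import preprocess
from ictaxis.axis import (
    BANDS,
    BandRule,
    axis_consistency,
    axis_descriptives,
    band_frequency_table,
    classify_band,
    compute_axis,
)
from ictaxis.errors import ValidationError
from ictaxis.instruments import AXIS_COLUMNS, OCDUS_SUBSCALES, UPPS_SUBSCALES


def _z_table(upps=None, ocdus=None, n=None):
    cols = {}
    for s in UPPS_SUBSCALES:
        cols[f"UPPS_{s}"] = upps
    for s in OCDUS_SUBSCALES:
        cols[f"OCDUS_{s}"] = ocdus
    return pd.DataFrame(cols)


class TestComputeAxis:
    def test_equal_components_give_zero(self):
        z = _z_table(upps=[1.3], ocdus=[1.3])
        assert compute_axis(z)["axis"].iloc[0] == pytest.approx(0.0)

    def test_unit_impulsive_component_gives_plus_ten(self):
        z = _z_table(upps=[1.0], ocdus=[0.0])
        res = compute_axis(z)
        assert res["axis"].iloc[0] == pytest.approx(10.0)
        assert res["impulsive_component"].iloc[0] == pytest.approx(1.0)

    def test_cohort_mean_zero_on_standardization_cohort(self, cohort_axis):
        assert abs(cohort_axis["axis"]["axis"].mean()) < 1e-8

    def test_missing_subscale_rejected(self):
        z = _z_table(upps=[1.0], ocdus=[0.0]).drop(columns=["OCDUS_resistance"])
        with pytest.raises(ValidationError):
            compute_axis(z)

    def test_commutes_with_subject_reordering(self, cohort_axis):
        z = cohort_axis["z"]
        shuffled = z.sample(frac=1.0, random_state=5)
        a = compute_axis(z).sort_index()
        b = compute_axis(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestClassifyBand:
    @pytest.mark.parametrize(
        "value,band",
        [
            (25, "high_impulsivity"),
            (20, "moderate_impulsivity"),
            (15, "moderate_impulsivity"),
            (10, "balance"),
            (0, "balance"),
            (-10, "balance"),
            (-15, "moderate_compulsivity"),
            (-20, "moderate_compulsivity"),
            (-25, "high_compulsivity"),
        ],
    )
    def test_thresholds_and_tie_rule(self, value, band):
        assert classify_band(value) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            classify_band(float("nan"))

    @given(
        st.floats(min_value=-50, max_value=50, allow_nan=False),
        st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_axis_value(self, a, b):
        order = {b_: i for i, b_ in enumerate(BANDS)}  # impulsive pole first
        lo, hi = sorted((a, b))
        assert order[classify_band(hi)] <= order[classify_band(lo)]

    def test_custom_rule_moves_boundaries(self):
        rule = BandRule(inner=5.0, outer=15.0)
        assert classify_band(7, rule) == "moderate_impulsivity"
        assert classify_band(-16, rule) == "high_compulsivity"


class TestDescriptives:
    def test_symmetric_sample_has_zero_skewness(self):
        x = [-3, -2, -1, 0, 1, 2, 3]
        d = axis_descriptives(x)
        assert d["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert d["q1"] <= d["median"] <= d["q3"]

    def test_standard_normal_shape_moments(self):
        rng = np.random.default_rng(10)
        d = axis_descriptives(rng.normal(size=10000))
        assert abs(d["skewness"]) <= 0.1
        assert abs(d["excess_kurtosis"]) <= 0.1

    def test_small_sample_moments_undefined(self):
        d = axis_descriptives([1.0, 2.0, 3.0])
        assert d["skewness"] is None and d["excess_kurtosis"] is None


class TestConsistency:
    def test_constant_compulsive_component_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        n = 50
        df = pd.DataFrame(
            {
                **{f"UPPS_{s}": rng.normal(size=n) for s in UPPS_SUBSCALES},
                **{f"OCDUS_{s}": np.zeros(n) for s in OCDUS_SUBSCALES},
            }
        )
        res = axis_consistency(compute_axis(df))
        assert res["impulsive_component"]["r"] == pytest.approx(1.0)
        assert "error" in res["compulsive_component"]

    def test_independent_components_match_empirical_oracle(self):
        # with independent standard-normal subscales the axis-component
        # correlation is verified against direct np.corrcoef computation
        rng = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame({c: rng.normal(size=n) for c in AXIS_COLUMNS})
        ax = compute_axis(df)
        res = axis_consistency(ax)
        for comp in ("impulsive_component", "compulsive_component"):
            oracle = np.corrcoef(ax["axis"], ax[comp])[0, 1]
            assert res[comp]["r"] == pytest.approx(oracle, abs=1e-12)
        # population value sqrt((1/5) / (1/5 + 1/3)) = sqrt(3/8) ~ 0.612
        assert res["impulsive_component"]["r"] == pytest.approx(np.sqrt(3 / 8), abs=0.05)
        assert res["compulsive_component"]["r"] == pytest.approx(-np.sqrt(5 / 8), abs=0.05)

    def test_signs_on_synthetic_cohort(self, cohort_axis):
        res = axis_consistency(cohort_axis["axis"])
        assert res["impulsive_component"]["r"] > 0
        assert res["compulsive_component"]["r"] < 0
        assert res["impulsive_component"]["sign_ok"]
        assert res["compulsive_component"]["sign_ok"]


class TestBandFrequencyTable:
    def _flags(self, index, flagged_scales):
        df = pd.DataFrame(index=index)
        from ictaxis.instruments import MULTICAGE_SCALES

        for s in MULTICAGE_SCALES:
            df[f"MULTICAGE_{s}_flag"] = s in flagged_scales
        return df

    def test_columns_sum_to_hundred(self, cohort_axis, cohort_scores):
        ax = cohort_axis["axis"]
        table = band_frequency_table(ax["band"], cohort_scores.loc[ax.index])
        sums = table.sum(axis=0)
        for scale, total in sums.items():
            assert total == pytest.approx(100.0, abs=0.05)

    def test_all_flagged_compulsive_gives_hundred(self):
        idx = pd.Index([f"s{i}" for i in range(6)])
        bands = pd.Series(["high_compulsivity"] * 6, index=idx)
        table = band_frequency_table(bands, self._flags(idx, {"internet"}))
        assert table.loc["high_compulsivity", "internet"] == pytest.approx(100.0)

    def test_compulsive_mass_dominates_on_linked_cohort(self, cohort_axis, cohort_scores):
        # MULTICAGE endorsement loads more on the compulsivity latent, so
        # flagged subpopulations must lean compulsive in every column
        ax = cohort_axis["axis"]
        table = band_frequency_table(ax["band"], cohort_scores.loc[ax.index])
        comp = table.loc[["moderate_compulsivity", "high_compulsivity"]].sum()
        imp = table.loc[["high_impulsivity", "moderate_impulsivity"]].sum()
        assert (comp > imp).all()

    def test_empty_scale_reported_undefined(self):
        idx = pd.Index(["a", "b"])
        bands = pd.Series(["balance", "balance"], index=idx)
        warnings: list = []
        table = band_frequency_table(bands, self._flags(idx, set()), warnings_out=warnings)
        assert table.isna().all().all()
        assert len(warnings) == 5


def test_axis_invariant_under_affine_subscale_rescaling(cohort, cohort_axis):
    """End-to-end: rescaling constants of any raw subscale cannot move the axis."""
    retained = cohort_axis["retained"]
    covs = preprocess.encode_covariates(cohort.demographics.loc[retained.index])
    scrambled = retained.copy()
    scrambled["UPPS_sensation_seeking"] = scrambled["UPPS_sensation_seeking"] * 7.0 + 13.0
    scrambled["OCDUS_resistance"] = scrambled["OCDUS_resistance"] * 0.2 - 4.0
    ax_ref = compute_axis(preprocess.residualize_z(retained, covs))
    ax_new = compute_axis(preprocess.residualize_z(scrambled, covs))
    np.testing.assert_allclose(ax_new["axis"], ax_ref["axis"], atol=1e-9)
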