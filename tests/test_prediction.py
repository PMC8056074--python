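import numpy as np
import pandas as pd
import pytest

from ictaxis import prediction
from ictaxis.errors import ValidationError
from ictaxis.prediction import (
    FAMILIES,
    CharacterModel,
    classify_subject,
    decision_region,
    distill_quadratic_rule,
    feature_table,
    fit_character_model,
    model_tournament,
    select_labeled,
    split_train_test,
)


def _blobs(n=200, centers=((20, 20), (80, 80)), sd=5.0, seed=0):
    """Two well-separated Gaussian blobs labeled impulsive/compulsive."""
    rng = np.random.default_rng(seed)
    half = n // 2
    pts = np.vstack(
        [
            rng.normal(centers[0], sd, size=(half, 2)),
            rng.normal(centers[1], sd, size=(n - half, 2)),
        ]
    ).clip(0, 100)
    labels = ["impulsive"] * half + ["compulsive"] * (n - half)
    df = pd.DataFrame(pts, columns=["UPPS_total_pct", "OCDUS_total_pct"])
    df["label"] = labels
    df.attrs["feature_pair"] = ("UPPS_total_pct", "OCDUS_total_pct")
    return df


@pytest.fixture(scope="module")
def labeled_cohort(cohort_axis, cohort_scores):
    ax = cohort_axis["axis"]
    features = feature_table(cohort_scores).loc[ax.index]
    return select_labeled(ax, features)


class TestSelectLabeled:
    def test_threshold_rule_on_small_cohort(self):
        ax = pd.DataFrame(
            {"axis": [-15.0, -5.0, 0.0, 12.0, 25.0]},
            index=[f"s{i}" for i in range(5)],
        )
        feats = pd.DataFrame(
            {"UPPS_total_pct": [50.0] * 5, "OCDUS_total_pct": [50.0] * 5}, index=ax.index
        )
        out = select_labeled(ax, feats)
        assert list(out.index) == ["s0", "s3", "s4"]
        assert list(out["label"]) == ["compulsive", "impulsive", "impulsive"]
        assert out.attrs["retained_fraction"] == pytest.approx(0.6)

    def test_all_balance_cohort_rejected(self):
        ax = pd.DataFrame({"axis": [0.0, 3.0, -7.0]}, index=["a", "b", "c"])
        feats = pd.DataFrame(
            {"UPPS_total_pct": [1.0] * 3, "OCDUS_total_pct": [1.0] * 3}, index=ax.index
        )
        with pytest.raises(ValidationError):
            select_labeled(ax, feats)

    def test_default_cohort_retained_fraction(self, labeled_cohort):
        # the reference study retained ~25% outside the balance band
        assert 0.15 <= labeled_cohort.attrs["retained_fraction"] <= 0.35


class TestSplit:
    def _labeled(self, n, n_comp):
        df = pd.DataFrame(
            {
                "UPPS_total_pct": np.linspace(0, 100, n),
                "OCDUS_total_pct": np.linspace(100, 0, n),
                "label": ["compulsive"] * n_comp + ["impulsive"] * (n - n_comp),
            },
            index=[f"s{i}" for i in range(n)],
        )
        df.attrs["feature_pair"] = ("UPPS_total_pct", "OCDUS_total_pct")
        return df

    def test_201_splits_161_40(self):
        train, test = split_train_test(self._labeled(201, 90), seed=0)
        assert len(train) == 161 and len(test) == 40

    def test_ten_splits_eight_two(self):
        train, test = split_train_test(self._labeled(10, 4), seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_partition_is_disjoint_exhaustive_and_stratified(self):
        labeled = self._labeled(201, 90)
        train, test = split_train_test(labeled, seed=5)
        assert len(train.intersection(test)) == 0
        assert set(train) | set(test) == set(labeled.index)
        assert set(labeled.loc[train, "label"]) == {"impulsive", "compulsive"}
        assert set(labeled.loc[test, "label"]) == {"impulsive", "compulsive"}

    def test_seed_determinism(self):
        labeled = self._labeled(100, 40)
        a1, _ = split_train_test(labeled, seed=7)
        a2, _ = split_train_test(labeled, seed=7)
        b, _ = split_train_test(labeled, seed=8)
        assert list(a1) == list(a2)
        assert list(a1) != list(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            split_train_test(self._labeled(20, 0))


class TestFitAndTournament:
    def test_gpc_separates_clean_blobs(self):
        labeled = _blobs(200, seed=1)
        train, test = split_train_test(labeled, seed=1)
        model = fit_character_model(labeled, train, family="gpc", seed=1)
        acc = prediction.evaluate_model(model, labeled, test)
        assert acc >= 95.0

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(2)
        accs = []
        for seed in range(50):
            labeled = _blobs(200, seed=seed)
            labeled["label"] = rng.permutation(labeled["label"].to_numpy())
            train, test = split_train_test(labeled, seed=seed)
            model = fit_character_model(labeled, train, family="gpc", seed=seed)
            accs.append(prediction.evaluate_model(model, labeled, test))
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_duplicated_training_points_change_nothing(self):
        labeled = _blobs(80, seed=3)
        train, test = split_train_test(labeled, seed=3)
        model = fit_character_model(labeled, train, family="gpc", seed=3)
        doubled = pd.concat([labeled.loc[train], labeled.loc[train]])
        doubled.index = [f"d{i}" for i in range(len(doubled))]
        doubled.attrs["feature_pair"] = labeled.attrs["feature_pair"]
        model2 = fit_character_model(doubled, doubled.index, family="gpc", seed=3)
        grid = np.column_stack(
            [np.linspace(0, 100, 25), np.linspace(0, 100, 25)]
        )
        # duplication doubles each point's likelihood weight, nudging the
        # approximate posterior slightly; hard decisions are unchanged
        assert (model.predict_label(grid) == model2.predict_label(grid)).all()
        np.testing.assert_allclose(
            model.predict_proba_compulsive(grid),
            model2.predict_proba_compulsive(grid),
            atol=0.05,
        )

    def test_training_row_order_invariance(self):
        labeled = _blobs(120, seed=4)
        train, test = split_train_test(labeled, seed=4)
        model = fit_character_model(labeled, train, family="gpc", seed=4)
        shuffled = labeled.loc[np.random.default_rng(0).permutation(labeled.index)]
        shuffled.attrs["feature_pair"] = labeled.attrs["feature_pair"]
        model2 = fit_character_model(shuffled, train, family="gpc", seed=4)
        grid = np.column_stack([np.linspace(0, 100, 20), np.full(20, 50.0)])
        np.testing.assert_allclose(
            model.predict_proba_compulsive(grid),
            model2.predict_proba_compulsive(grid),
            atol=1e-8,
        )

    def test_tournament_on_separable_data(self):
        labeled = _blobs(200, seed=5)
        result = model_tournament(labeled, seed=5)
        assert set(result["accuracies"]) == set(FAMILIES)
        assert all(a >= 95.0 for a in result["accuracies"].values())
        assert all(0 <= a <= 100 for a in result["accuracies"].values())
        # deterministic alphabetical tie-break among perfect scorers
        best = max(result["accuracies"].values())
        expected = min(f for f, a in result["accuracies"].items() if a == best)
        assert result["winner"] == expected

    def test_gpc_beats_logistic_on_curved_boundary(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            u = rng.uniform(0, 100, 300)
            o = rng.uniform(0, 100, 300)
            boundary = 20 + 0.015 * (u - 50) ** 2  # quadratic class edge
            labels = np.where(o > boundary, "compulsive", "impulsive")
            df = pd.DataFrame(
                {"UPPS_total_pct": u, "OCDUS_total_pct": o, "label": labels},
                index=[f"s{i}" for i in range(300)],
            )
            df.attrs["feature_pair"] = ("UPPS_total_pct", "OCDUS_total_pct")
            res = model_tournament(df, families=("gpc", "logistic_regression"), seed=seed)
            wins += res["accuracies"]["gpc"] >= res["accuracies"]["logistic_regression"]
        assert wins >= 11  # majority over seeds

    def test_unknown_family_recorded_not_fatal(self):
        labeled = _blobs(60, seed=6)
        res = model_tournament(labeled, families=("gpc", "bogus"), seed=6)
        assert "bogus" in res["failures"]
        assert "gpc" in res["accuracies"]


@pytest.fixture(scope="module")
def fitted():
    labeled = _blobs(200, centers=((30, 20), (60, 75)), sd=9.0, seed=7)
    train, _ = split_train_test(labeled, seed=7)
    model = fit_character_model(labeled, train, family="gpc", seed=7)
    return model, labeled


class TestDecisionRegion:

    def test_probabilities_valid(self, fitted):
        model, _ = fitted
        grid = decision_region(model, resolution=41)
        assert ((grid.p_compulsive >= 0) & (grid.p_compulsive <= 1)).all()

    def test_zero_delta_empties_uncertain_zone(self, fitted):
        model, _ = fitted
        grid = decision_region(model, resolution=31, delta=0.0)
        assert (grid.zones() != "uncertain").all()

    def test_grid_frame_round_trip(self, fitted):
        model, _ = fitted
        grid = decision_region(model, resolution=21)
        frame = grid.to_frame()
        assert len(frame) == 21 * 21
        assert set(frame["zone"]) <= {"impulsive", "compulsive", "uncertain"}


class TestDistillation:
    def test_linear_boundary_yields_negligible_curvature(self):
        # an analytically linear probability field: logistic in (u + o)
        class LinearField:
            feature_names = ("UPPS_total_pct", "OCDUS_total_pct")
            family = "synthetic"

            def predict_proba_compulsive(self, X):
                X = np.asarray(X)
                return 1.0 / (1.0 + np.exp(-(X[:, 0] + X[:, 1] - 100.0) / 8.0))

            def predict_label(self, X):
                return np.where(
                    self.predict_proba_compulsive(X) >= 0.5, "compulsive", "impulsive"
                )

        grid = decision_region(LinearField(), resolution=101, delta=0.1)
        labeled = _blobs(100, seed=8)
        rule = distill_quadratic_rule(grid, labeled, LinearField())
        for coeffs in (rule.f1, rule.f2):
            assert abs(coeffs[0]) <= 1e-3  # quadratic term, per unit of the 0-100 scale

    def test_agreement_on_calibrated_cohort(self, labeled_cohort):
        train, _ = split_train_test(labeled_cohort, seed=0)
        model = fit_character_model(labeled_cohort, train, family="gpc", seed=0)
        grid = decision_region(model, resolution=101, delta=0.1)
        rule = distill_quadratic_rule(grid, labeled_cohort, model)
        assert rule.agreement_pct >= 75.0
        assert rule.agreement_pct <= 100.0
        # lower curve sits below the upper curve across the plane
        u = np.linspace(0, 100, 101)
        assert (np.polyval(rule.f1, u) <= np.polyval(rule.f2, u) + 1e-9).all()

    def test_high_ocdus_never_impulsive_on_calibrated_fit(self, labeled_cohort):
        train, _ = split_train_test(labeled_cohort, seed=0)
        model = fit_character_model(labeled_cohort, train, family="gpc", seed=0)
        grid = decision_region(model, resolution=101, delta=0.1)
        zones = grid.zones()
        high = grid.y > 70
        assert (zones[high, :] != "impulsive").all()

    def test_rule_at_zero_ocdus_is_impulsive(self, labeled_cohort):
        train, _ = split_train_test(labeled_cohort, seed=0)
        model = fit_character_model(labeled_cohort, train, family="gpc", seed=0)
        grid = decision_region(model, resolution=101, delta=0.1)
        rule = distill_quadratic_rule(grid, labeled_cohort, model)
        assert rule.classify(50.0, 0.0) == "impulsive"


@pytest.fixture(scope="module")
def model():
    labeled = _blobs(150, centers=((25, 25), (75, 75)), sd=6.0, seed=9)
    train, _ = split_train_test(labeled, seed=9)
    return fit_character_model(labeled, train, family="gpc", seed=9)


class TestClassifySubject:

    def test_deep_zone_confident(self, model):
        rec = classify_subject(model, (80.0, 80.0))[0]
        assert rec["label"] == "compulsive"
        assert rec["p_compulsive"] > 0.9
        assert rec["zone"] == "compulsive"

    def test_batch_order_preserved(self, model):
        X = np.array([[20.0, 20.0], [80.0, 80.0], [20.0, 20.0]])
        recs = classify_subject(model, X)
        assert [r["label"] for r in recs] == ["impulsive", "compulsive", "impulsive"]

    def test_out_of_range_features_rejected(self, model):
        with pytest.raises(ValidationError):
            classify_subject(model, (120.0, 50.0))


def test_feature_table_percent_scaling(cohort_scores):
    feats = feature_table(cohort_scores)
    for col in feats.columns:
        assert feats[col].between(0, 100).all()
    # UPPS raw total 20 -> 0%, 80 -> 100%
    raw = pd.DataFrame(
        {
            "UPPS_total": [20, 80],
            "OCDUS_total": [12, 84],
            "PSI_total": [0, 80],
            "MULTICAGE_total": [0, 20],
        }
    )
    out = feature_table(raw)
    assert out.iloc[0].tolist() == [0.0, 0.0, 0.0, 0.0]
    assert out.iloc[1].tolist() == [100.0, 100.0, 100.0, 100.0]
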