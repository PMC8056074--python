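"""Two-feature character classifiers and boundary distillation.

After balance-band subjects are excluded, each remaining subject carries a
binary character label from the axis sign (impulsive: axis > +10,
compulsive: axis < -10) and a feature pair on 0-100 percent-of-maximum
scales — either (PSI total %, MULTICAGE total %) or (UPPS total %,
OCDUS total %). A tournament of standard supervised families is run on a
stratified 8:2 split; the Gaussian-process classifier (RBF kernel with
initial length scale 1.0, L-BFGS-B hyperparameter optimization, 100
maximum prediction iterations, no warm start) provides the probability
surface whose decision regions are mapped over the feature plane and
distilled into two quadratic threshold curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError
from .instruments import TOTAL_RANGES

__all__ = [
    "FAMILIES",
    "feature_table",
    "select_labeled",
    "split_train_test",
    "CharacterModel",
    "fit_character_model",
    "evaluate_model",
    "model_tournament",
    "DecisionRegionGrid",
    "decision_region",
    "QuadraticBoundary",
    "distill_quadratic_rule",
    "classify_subject",
]

FAMILIES = (
    "decision_tree",
    "gpc",
    "knn",
    "linear_regression",
    "logistic_regression",
    "svm",
)

#: Class encoding used throughout: 0 = impulsive, 1 = compulsive.
CLASS_NAMES = {0: "impulsive", 1: "compulsive"}


def feature_table(raw_scores: pd.DataFrame) -> pd.DataFrame:
    """Instrument totals as percent of their theoretical maximum.

    Adds ``{UPPS,OCDUS,PSI,MULTICAGE}_total_pct`` columns computed from the
    raw totals over their theoretical ranges (UPPS [20,80], OCDUS [12,84],
    PSI [0,80], MULTICAGE yes-count over 20).
    """
    out = pd.DataFrame(index=raw_scores.index)
    for col, (lo, hi) in TOTAL_RANGES.items():
        if col not in raw_scores.columns:
            raise ValidationError(f"raw score table lacks {col}")
        out[f"{col}_pct"] = (raw_scores[col].astype(float) - lo) / (hi - lo) * 100.0
    return out


def select_labeled(
    axis_result: pd.DataFrame,
    features: pd.DataFrame,
    feature_pair: tuple[str, str] = ("UPPS_total_pct", "OCDUS_total_pct"),
    inner: float = 10.0,
) -> pd.DataFrame:
    """Drop balance-band subjects and attach binary character labels.

    Keeps subjects with |axis| > ``inner``; the label is 'impulsive' for
    positive axis, 'compulsive' for negative. Returns a frame with the
    two feature columns, ``label`` and ``axis``; its ``attrs`` record the
    retained count and fraction.
    """
    for col in feature_pair:
        if col not in features.columns:
            raise ValidationError(f"feature table lacks column {col!r}")
    joined = axis_result[["axis"]].join(features[list(feature_pair)], how="inner")
    if len(joined) != len(axis_result):
        raise ValidationError("axis and feature tables cover different subjects")
    kept = joined[joined["axis"].abs() > inner].copy()
    if kept.empty:
        raise ValidationError("no subjects outside the balance band")
    kept["label"] = np.where(kept["axis"] > 0, "impulsive", "compulsive")
    kept.attrs["n_total"] = len(joined)
    kept.attrs["n_retained"] = len(kept)
    kept.attrs["retained_fraction"] = len(kept) / len(joined)
    kept.attrs["feature_pair"] = feature_pair
    return kept


def split_train_test(
    labeled: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Stratified random train/test partition with |train| = round(ratio * n).

    Train sizes are allocated per class proportionally (largest-remainder
    rounding), so both classes appear on both sides whenever possible.
    """
    if len(labeled) < 10:
        raise ValidationError("need at least 10 labeled subjects to split")
    classes = labeled["label"].unique()
    if len(classes) < 2:
        raise ValidationError("both character classes must be present")
    n = len(labeled)
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    quotas = {}
    fracs = {}
    for cls in sorted(classes):
        ideal = ratio * (labeled["label"] == cls).sum()
        quotas[cls] = int(np.floor(ideal))
        fracs[cls] = ideal - np.floor(ideal)
    while sum(quotas.values()) < n_train:
        cls = max(fracs, key=lambda c: (fracs[c], c))
        quotas[cls] += 1
        fracs[cls] = -1.0
    train_ids: list = []
    for cls in sorted(classes):
        ids = labeled.index[labeled["label"] == cls].to_numpy()
        picked = rng.choice(ids, size=quotas[cls], replace=False)
        train_ids.extend(picked)
    train_idx = pd.Index(train_ids)
    test_idx = labeled.index.difference(train_idx)
    return labeled.index.intersection(train_idx), test_idx


def _make_estimator(family: str, hyperparameters: dict, seed: int):
    hp = dict(hyperparameters or {})
    if family == "gpc":
        length_scale = hp.pop("length_scale", 1.0)
        return GaussianProcessClassifier(
            kernel=RBF(length_scale=length_scale),
            optimizer=hp.pop("optimizer", "fmin_l_bfgs_b"),
            max_iter_predict=hp.pop("max_iter_predict", 100),
            warm_start=hp.pop("warm_start", False),
            random_state=seed,
            **hp,
        )
    if family == "logistic_regression":
        return LogisticRegression(random_state=seed, **hp)
    if family == "knn":
        return KNeighborsClassifier(**hp)
    if family == "svm":
        return SVC(probability=True, random_state=seed, **hp)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if family == "linear_regression":
        return LinearRegression(**hp)
    raise ValidationError(f"unknown model family {family!r}")


@dataclass
class CharacterModel:
    """A fitted two-feature binary character classifier."""

    family: str
    estimator: object
    feature_names: tuple[str, str]
    hyperparameters: dict = field(default_factory=dict)
    train_index: pd.Index | None = None
    test_index: pd.Index | None = None
    test_accuracy: float | None = None  # percent

    def predict_proba_compulsive(self, X) -> np.ndarray:
        """P(compulsive) for each row of X (shape (n, 2))."""
        X = np.asarray(X, dtype=float)
        if self.family == "linear_regression":
            return np.clip(self.estimator.predict(X), 0.0, 1.0)
        proba = self.estimator.predict_proba(X)
        idx = list(self.estimator.classes_).index(1)
        return proba[:, idx]

    def predict_label(self, X) -> np.ndarray:
        p = self.predict_proba_compulsive(X)
        return np.where(p >= 0.5, "compulsive", "impulsive")


def fit_character_model(
    labeled: pd.DataFrame,
    train_index: pd.Index,
    family: str = "gpc",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> CharacterModel:
    """Fit one family on the training rows of a labeled subject table."""
    pair = labeled.attrs.get("feature_pair") or tuple(
        c for c in labeled.columns if c not in ("label", "axis")
    )
    train = labeled.loc[train_index]
    y = (train["label"] == "compulsive").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    X = train[list(pair)].to_numpy(dtype=float)
    est = _make_estimator(family, hyperparameters or {}, seed)
    est.fit(X, y)
    return CharacterModel(
        family=family,
        estimator=est,
        feature_names=tuple(pair),
        hyperparameters=dict(hyperparameters or {}),
        train_index=train_index,
    )


def evaluate_model(model: CharacterModel, labeled: pd.DataFrame, test_index: pd.Index) -> float:
    """Test-set prediction efficiency (accuracy, percent); stored on the model."""
    test = labeled.loc[test_index]
    pred = model.predict_label(test[list(model.feature_names)].to_numpy(dtype=float))
    acc = float((pred == test["label"].to_numpy()).mean() * 100.0)
    model.test_index = test_index
    model.test_accuracy = acc
    return acc


def model_tournament(
    labeled: pd.DataFrame,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> dict:
    """Fit every family on one shared split and rank by test accuracy.

    Returns ``{"split": (train, test), "accuracies": {family: pct},
    "failures": {family: message}, "winner": family, "models": {...}}``.
    Ties break deterministically by family name.
    """
    train_idx, test_idx = split_train_test(labeled, seed=seed)
    accuracies: dict[str, float] = {}
    failures: dict[str, str] = {}
    models: dict[str, CharacterModel] = {}
    for family in families:
        hp = (hyperparameters or {}).get(family, {})
        try:
            model = fit_character_model(labeled, train_idx, family, hp, seed=seed)
            accuracies[family] = evaluate_model(model, labeled, test_idx)
            models[family] = model
        except Exception as exc:  # a failed family is recorded, not fatal
            failures[family] = f"{type(exc).__name__}: {exc}"
    if not accuracies:
        raise ValidationError("every model family failed to fit")
    winner = min(accuracies, key=lambda f: (-accuracies[f], f))
    return {
        "split": (train_idx, test_idx),
        "accuracies": accuracies,
        "failures": failures,
        "winner": winner,
        "models": models,
    }


@dataclass
class DecisionRegionGrid:
    """Class-probability surface over the 0-100 x 0-100 feature plane."""

    feature_names: tuple[str, str]
    x: np.ndarray          # grid over feature 1 (plotted horizontally)
    y: np.ndarray          # grid over feature 2
    p_compulsive: np.ndarray  # shape (len(y), len(x))
    delta: float

    def zones(self) -> np.ndarray:
        """'impulsive' if p < 0.5 - delta, 'compulsive' if p > 0.5 + delta, else 'uncertain'."""
        return np.where(
            self.p_compulsive < 0.5 - self.delta,
            "impulsive",
            np.where(self.p_compulsive > 0.5 + self.delta, "compulsive", "uncertain"),
        )

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                self.feature_names[0]: xx.ravel(),
                self.feature_names[1]: yy.ravel(),
                "p_compulsive": self.p_compulsive.ravel(),
                "zone": self.zones().ravel(),
            }
        )

    def unconditional_compulsive_level(self) -> float | None:
        """Lowest feature-2 level above which every cell is non-impulsive.

        For the UPPS/OCDUS model this is the OCDUS percent beyond which the
        prediction is compulsive (or uncertain) regardless of UPPS.
        """
        zones = self.zones()
        ok = (zones != "impulsive").all(axis=1)
        for i in range(len(self.y)):
            if ok[i:].all():
                return float(self.y[i])
        return None


def decision_region(
    model: CharacterModel, resolution: int = 101, delta: float = 0.1
) -> DecisionRegionGrid:
    """Evaluate the model's compulsive-class probability on a regular grid."""
    x = np.linspace(0.0, 100.0, resolution)
    y = np.linspace(0.0, 100.0, resolution)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    p = model.predict_proba_compulsive(pts).reshape(len(y), len(x))
    return DecisionRegionGrid(
        feature_names=model.feature_names, x=x, y=y, p_compulsive=p, delta=delta
    )


@dataclass
class QuadraticBoundary:
    """Distilled decision rule: two quadratics f1 <= f2 over feature 1.

    With u the first feature (UPPS %) and o the second (OCDUS %):
    o > f2(u) -> compulsive; o < f1(u) -> impulsive; otherwise abstain
    (uncertain). ``f1``/``f2`` are numpy polynomial coefficient triples
    (highest degree first).
    """

    f1: np.ndarray
    f2: np.ndarray
    delta: float
    feature_names: tuple[str, str]
    agreement_pct: float | None = None

    def classify(self, u, o) -> np.ndarray | str:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        o = np.atleast_1d(np.asarray(o, dtype=float))
        lo = np.polyval(self.f1, u)
        hi = np.polyval(self.f2, u)
        out = np.where(o > hi, "compulsive", np.where(o < lo, "impulsive", "uncertain"))
        return out if out.size > 1 else str(out[0])


def _contour_points(grid: DecisionRegionGrid, level: float) -> tuple[np.ndarray, np.ndarray]:
    """First upward crossing of ``level`` along each grid column, interpolated."""
    us, os_ = [], []
    for j, u in enumerate(grid.x):
        col = grid.p_compulsive[:, j]
        above = col >= level
        if not above.any() or above.all():
            continue
        i = int(np.argmax(above))
        if i == 0:
            continue
        p0, p1 = col[i - 1], col[i]
        frac = (level - p0) / (p1 - p0) if p1 != p0 else 0.0
        us.append(u)
        os_.append(grid.y[i - 1] + frac * (grid.y[i] - grid.y[i - 1]))
    return np.asarray(us), np.asarray(os_)


def distill_quadratic_rule(
    grid: DecisionRegionGrid, labeled: pd.DataFrame, model: CharacterModel
) -> QuadraticBoundary:
    """Fit quadratics to the p = 0.5 -+ delta contours and score agreement.

    The contours are extracted column-wise from the probability grid (the
    second feature as a function of the first) and fitted by least
    squares. Agreement is the percent of labeled subjects where the
    distilled rule's hard label matches the model's; abstentions count as
    disagreement.
    """
    curves = []
    for level in (0.5 - grid.delta, 0.5 + grid.delta):
        us, os_ = _contour_points(grid, level)
        if us.size < 3:
            raise ValidationError(
                f"p={level:.2f} contour absent or degenerate; cannot distill"
            )
        curves.append(np.polyfit(us, os_, deg=2))
    rule = QuadraticBoundary(
        f1=curves[0], f2=curves[1], delta=grid.delta, feature_names=grid.feature_names
    )
    X = labeled[list(grid.feature_names)].to_numpy(dtype=float)
    gpc_labels = model.predict_label(X)
    rule_labels = rule.classify(X[:, 0], X[:, 1])
    rule.agreement_pct = float((rule_labels == gpc_labels).mean() * 100.0)
    return rule


def classify_subject(artifact, features, delta: float = 0.1) -> list[dict]:
    """Classify one or more feature pairs with a fitted model or distilled rule.

    ``features`` is a (2,) pair or an (n, 2) array on the 0-100 scales.
    Returns one record per input row with label, compulsive-class
    probability (None for a distilled rule) and zone.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != 2:
        raise ValidationError("expected feature pairs of length 2")
    if (X < 0).any() or (X > 100).any():
        raise ValidationError("features must lie in [0, 100]")
    records = []
    if isinstance(artifact, QuadraticBoundary):
        zones = artifact.classify(X[:, 0], X[:, 1])
        zones = np.atleast_1d(zones)
        for z in zones:
            label = z if z != "uncertain" else "uncertain"
            records.append({"label": label, "p_compulsive": None, "zone": z})
        return records
    p = artifact.predict_proba_compulsive(X)
    for pi in p:
        zone = (
            "impulsive"
            if pi < 0.5 - delta
            else "compulsive"
            if pi > 0.5 + delta
            else "uncertain"
        )
        records.append(
            {
                "label": "compulsive" if pi >= 0.5 else "impulsive",
                "p_compulsive": float(pi),
                "zone": zone,
            }
        )
    return records
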