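"""Score conditioning between raw subscale scores and the axis.

Stages, in pipeline order: 0-100 linear rescaling of every subscale to its
theoretical range; multivariate outlier exclusion on the eight UPPS/OCDUS
subscale scores via the squared Mahalanobis distance against the
chi-square p < 0.001 criterion; removal of weak age/education trends by
ordinary least squares; and Z-standardization of the residuals so each of
the eight contributions enters the axis on an exactly mean-0 / SD-1 scale.

Age and education are ordinal band codes (age 1..6 over <18, 18-25, 26-30,
31-45, 46-60, >60; education 1..5 over primary, secondary, high school,
university student, university degree). Any monotone coding of the bands
is admissible; the integer coding is the package default and is isolated
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, ValidationError
from .instruments import AXIS_COLUMNS, InstrumentSpec, default_specs

__all__ = [
    "AGE_BANDS",
    "EDUCATION_BANDS",
    "encode_covariates",
    "subscale_ranges",
    "rescale_0_100",
    "mahalanobis_filter",
    "OutlierReport",
    "residualize_z",
]

AGE_BANDS = ("<18", "18-25", "26-30", "31-45", "46-60", ">60")
EDUCATION_BANDS = (
    "primary",
    "secondary",
    "high_school",
    "university_student",
    "university_degree",
)


def encode_covariates(demographics: pd.DataFrame) -> pd.DataFrame:
    """Map age/education band labels to ordinal codes (1-based).

    Expects columns ``age_band`` and ``education_band`` with values from
    :data:`AGE_BANDS` / :data:`EDUCATION_BANDS`; index = subject_id.
    """
    out = pd.DataFrame(index=demographics.index)
    for col, bands, name in (
        ("age_band", AGE_BANDS, "age_code"),
        ("education_band", EDUCATION_BANDS, "education_code"),
    ):
        if col not in demographics.columns:
            raise ValidationError(f"demographics table lacks column {col!r}")
        mapping = {b: i + 1 for i, b in enumerate(bands)}
        codes = demographics[col].map(mapping)
        if codes.isna().any():
            bad = demographics.loc[codes.isna(), col].iloc[0]
            raise ValidationError(f"unknown {col} label {bad!r}")
        out[name] = codes.astype(int)
    return out


def subscale_ranges(specs: dict[str, InstrumentSpec] | None = None) -> dict[str, tuple[int, int]]:
    """Theoretical (min, max) for every scored column, keyed like the score table."""
    if specs is None:
        specs = default_specs()
    ranges: dict[str, tuple[int, int]] = {}
    for spec in specs.values():
        real = [s for s in spec.subscales if s != "total"]
        for name in real:
            ranges[f"{spec.name}_{name}"] = spec.subscale_range(name)
        lo, hi = spec.response_range
        n_items = len(spec.items)
        ranges[f"{spec.name}_total"] = (n_items * lo, n_items * hi)
    return ranges


def rescale_0_100(
    scores: pd.DataFrame, ranges: dict[str, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Linearly rescale each score column to 0 (theoretical min) .. 100 (max)."""
    if ranges is None:
        ranges = subscale_ranges()
    out = scores.copy()
    for col in scores.columns:
        if col not in ranges:
            continue  # flags / pct columns pass through untouched
        lo, hi = ranges[col]
        if hi == lo:
            raise ValidationError(f"degenerate theoretical range for {col}: [{lo}, {hi}]")
        x = scores[col].astype(float)
        if (x < lo).any() or (x > hi).any():
            raise ValidationError(f"{col}: raw score outside theoretical range [{lo}, {hi}]")
        out[col] = (x - lo) / (hi - lo) * 100.0
    out.attrs["stage"] = "normalized"
    return out


@dataclass
class OutlierReport:
    """Result of the Mahalanobis screening step."""

    distances_sq: pd.Series
    threshold: float
    df: int
    alpha: float
    excluded: list
    n_total: int

    @property
    def exclusion_fraction(self) -> float:
        return len(self.excluded) / self.n_total

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": len(self.excluded),
            "exclusion_fraction": self.exclusion_fraction,
            "chi2_df": self.df,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "excluded_subjects": [str(s) for s in self.excluded],
        }


def mahalanobis_filter(
    scores: pd.DataFrame,
    alpha: float = 0.001,
    columns: tuple[str, ...] = AXIS_COLUMNS,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Exclude multivariate outliers by squared Mahalanobis distance.

    d2(x) = (x - mu)' S^-1 (x - mu) with sample mean and (n-1) covariance;
    a subject is excluded when d2 exceeds the 1 - alpha chi-square
    quantile with df = number of columns (the p < alpha criterion).

    Returns (retained rows of ``scores``, :class:`OutlierReport`).
    """
    missing = [c for c in columns if c not in scores.columns]
    if missing:
        raise ValidationError(f"score table lacks columns {missing}")
    x = scores[list(columns)].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValidationError(f"need n > {p} subjects for a {p}-column covariance; got {n}")
    const = [c for c, v in zip(columns, x.var(axis=0)) if v == 0]
    if const:
        raise NumericalError(f"constant column(s) {const}: covariance singular")
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular covariance over columns {list(columns)}") from exc
    centred = x - mu
    d2 = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
    threshold = float(stats.chi2.ppf(1.0 - alpha, df=p))
    dist = pd.Series(d2, index=scores.index, name="mahalanobis_sq")
    excluded = list(scores.index[d2 > threshold])
    report = OutlierReport(
        distances_sq=dist,
        threshold=threshold,
        df=p,
        alpha=alpha,
        excluded=excluded,
        n_total=n,
    )
    retained = scores.loc[~scores.index.isin(excluded)].copy()
    retained.attrs = dict(scores.attrs)
    return retained, report


def residualize_z(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = AXIS_COLUMNS,
    warnings_out: list | None = None,
) -> pd.DataFrame:
    """Regress out age/education and standardize the residuals.

    For each score column an OLS fit ``score = b0 + b1*age_code +
    b2*education_code`` is solved by the normal equations; the raw
    residuals are divided by their (n-1) sample SD, yielding columns with
    mean exactly 0 and SD exactly 1.

    A constant covariate column is dropped with a warning (both constant:
    plain Z-scoring). Warning strings are appended to ``warnings_out``
    when given.
    """
    if len(scores) < 3:
        raise ValidationError("need at least 3 subjects to residualize")
    cov = covariates.reindex(scores.index)
    if cov[["age_code", "education_code"]].isna().any().any():
        raise ValidationError("covariates missing for some scored subjects")
    preds = []
    for c in ("age_code", "education_code"):
        if cov[c].nunique() > 1:
            preds.append(c)
        else:
            msg = f"covariate {c} is constant; dropped from residualization"
            if warnings_out is not None:
                warnings_out.append(msg)
    design = np.column_stack(
        [np.ones(len(scores))] + [cov[c].to_numpy(dtype=float) for c in preds]
    )
    out = scores.copy()
    for col in columns:
        y = scores[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise NumericalError(f"{col}: residuals have zero variance")
        out[col] = resid / sd
    out.attrs["stage"] = "residual_z"
    return out
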