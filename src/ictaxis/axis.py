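"""Construction of the Impulsivity-Compulsivity axis and its descriptives.

The axis locates each subject on the continuum between impulsive and
compulsive character: the impulsive component is the arithmetic mean of
the five standardized UPPS residual scores, the compulsive component the
mean of the three standardized OCDUS residual scores, and

    axis = 10 * (impulsive_component - compulsive_component)

so that positive values mark the impulsive pole. Because each residual-Z
column has sample mean 0, the axis averages exactly 0 over the cohort it
was standardized on. Five qualitative bands are cut at +-10 and +-20;
exact +-10 falls in the balance band ("both inclusive") and exact +-20 in
the moderate bands — the tie rule is overridable via :class:`BandRule`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedResultError, ValidationError
from .instruments import MULTICAGE_SCALES, OCDUS_SUBSCALES, UPPS_SUBSCALES
from . import stats as stats_battery

__all__ = [
    "BANDS",
    "BandRule",
    "compute_axis",
    "classify_band",
    "axis_descriptives",
    "axis_consistency",
    "band_frequency_table",
]

BANDS = (
    "high_impulsivity",
    "moderate_impulsivity",
    "balance",
    "moderate_compulsivity",
    "high_compulsivity",
)


@dataclass(frozen=True)
class BandRule:
    """Thresholds and tie handling for the five character bands.

    With the default rule the balance band is the closed interval
    [-inner, +inner] and the moderate bands are half-open on the inside,
    closed at +-outer.
    """

    inner: float = 10.0
    outer: float = 20.0

    def classify(self, axis) -> np.ndarray | str:
        x = np.asarray(axis, dtype=float)
        if not np.isfinite(x).all():
            raise ValidationError("non-finite axis value")
        out = np.where(
            x > self.outer,
            "high_impulsivity",
            np.where(
                x > self.inner,
                "moderate_impulsivity",
                np.where(
                    x >= -self.inner,
                    "balance",
                    np.where(x >= -self.outer, "moderate_compulsivity", "high_compulsivity"),
                ),
            ),
        )
        if np.isscalar(axis) or np.ndim(axis) == 0:
            return str(out)
        return out


def compute_axis(z: pd.DataFrame, band_rule: BandRule | None = None) -> pd.DataFrame:
    """Per-subject components, axis value and band from residual-Z scores.

    Parameters
    ----------
    z : DataFrame
        Stage ``residual_z`` score table containing the eight
        ``UPPS_*``/``OCDUS_*`` subscale columns.

    Returns
    -------
    DataFrame with columns impulsive_component, compulsive_component,
    axis, band (index = subject_id).
    """
    rule = band_rule or BandRule()
    upps_cols = [f"UPPS_{s}" for s in UPPS_SUBSCALES]
    ocdus_cols = [f"OCDUS_{s}" for s in OCDUS_SUBSCALES]
    missing = [c for c in upps_cols + ocdus_cols if c not in z.columns]
    if missing:
        raise ValidationError(f"residual-Z table lacks columns {missing}")
    imp = z[upps_cols].mean(axis=1)
    comp = z[ocdus_cols].mean(axis=1)
    axis = 10.0 * (imp - comp)
    out = pd.DataFrame(
        {
            "impulsive_component": imp,
            "compulsive_component": comp,
            "axis": axis,
            "band": rule.classify(axis.to_numpy()),
        },
        index=z.index,
    )
    return out


def classify_band(axis, band_rule: BandRule | None = None):
    """Band label(s) for one axis value or an array of values."""
    rule = band_rule or BandRule()
    return rule.classify(axis)


def axis_descriptives(axis_values) -> dict:
    """Distribution summary of the axis: n, mean, SD, quartiles, shape.

    Skewness is the adjusted Fisher-Pearson coefficient and kurtosis is
    excess kurtosis; quartiles interpolate linearly between order
    statistics. With n < 4 the shape moments are reported as None.
    """
    x = np.asarray(axis_values, dtype=float)
    if x.size < 1:
        raise ValidationError("empty axis sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    out = {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else None,
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }
    if x.size >= 4:
        out["skewness"] = float(sps.skew(x, bias=False))
        out["excess_kurtosis"] = float(sps.kurtosis(x, bias=False))
    else:
        out["skewness"] = None
        out["excess_kurtosis"] = None
    return out


def axis_consistency(axis_result: pd.DataFrame) -> dict:
    """Internal-consistency check: axis vs its own two components.

    Returns the Pearson correlation (with p and BF10) of the axis against
    the impulsive component (expected positive: higher UPPS, more
    impulsive) and against the compulsive component (expected negative).
    """
    axis = axis_result["axis"].to_numpy()
    if np.std(axis) == 0:
        raise UndefinedResultError("zero variance in axis")
    results = {}
    for comp, expected_sign in (("impulsive_component", 1), ("compulsive_component", -1)):
        y = axis_result[comp].to_numpy()
        if np.std(y) == 0:
            results[comp] = {"error": "zero variance: correlation undefined"}
            continue
        res = stats_battery.pearson_bf10(axis, y)
        results[comp] = {
            "r": res.r,
            "p": res.p,
            "bf10": res.bf10,
            "ci95": res.ci95,
            "evidence": res.evidence,
            "expected_sign": expected_sign,
            "sign_ok": bool(np.sign(res.r) == expected_sign),
        }
    return results


def band_frequency_table(
    bands: pd.Series,
    multicage_flags: pd.DataFrame,
    warnings_out: list | None = None,
) -> pd.DataFrame:
    """Percent of each axis band among subjects flagged on each ICT scale.

    For each of the five MULTICAGE scales, restricts to subjects whose
    scale percent reached the 50% screening threshold and tabulates the
    percent falling in each band; every column sums to 100 (columns with
    zero flagged subjects are reported as NaN with a warning).
    """
    table = pd.DataFrame(index=list(BANDS), columns=list(MULTICAGE_SCALES), dtype=float)
    for scale in MULTICAGE_SCALES:
        flag_col = f"MULTICAGE_{scale}_flag"
        if flag_col not in multicage_flags.columns:
            raise ValidationError(f"flag column {flag_col} missing")
        flagged = multicage_flags.index[multicage_flags[flag_col].astype(bool)]
        flagged = flagged.intersection(bands.index)
        if len(flagged) == 0:
            if warnings_out is not None:
                warnings_out.append(f"no subjects flagged on scale {scale}")
            continue
        counts = bands.loc[flagged].value_counts()
        for band in BANDS:
            table.loc[band, scale] = counts.get(band, 0) / len(flagged) * 100.0
    return table
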