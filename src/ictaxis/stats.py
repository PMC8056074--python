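"""Inferential toolkit: KS normality gate, Mann-Whitney U with the
Rosenthal effect size, Pearson correlation with a default Bayes factor,
and the band-proportion comparison.

The Bayes factor BF10 for a correlation is the Jeffreys-Zellner-Siow
default: the marginal likelihood of the observed sample correlation under
a uniform (stretched-beta, kappa = 1) prior on rho, divided by its
likelihood under rho = 0, computed by numerical integration of the exact
sampling density of Pearson's r. Evidence labels follow BF10 < 1 (none),
1 <= BF10 < 10 (weak-moderate), >= 10 (strong). Effect-size labels for
both Rosenthal's and Pearson's r follow r < 0.30 (small),
0.30 <= r < 0.50 (medium), r >= 0.50 (large).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .errors import UndefinedResultError, ValidationError

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "effect_size_label",
    "evidence_label",
    "ks_normality",
    "mann_whitney_rosenthal",
    "pearson_bf10",
    "compare_band_proportions",
]

IMPULSIVE_BANDS = ("high_impulsivity", "moderate_impulsivity")
COMPULSIVE_BANDS = ("moderate_compulsivity", "high_compulsivity")


def effect_size_label(r: float) -> str:
    r = abs(r)
    if r < 0.30:
        return "small"
    if r < 0.50:
        return "medium"
    return "large"


def evidence_label(bf10: float) -> str:
    if bf10 < 1:
        return "no evidence"
    if bf10 < 10:
        return "weak-moderate"
    return "strong"


@dataclass
class GroupTestResult:
    """Mann-Whitney U outcome with the Rosenthal nonparametric effect size."""

    u: float            # headline statistic: min(U_x, U_y)
    u_x: float
    u_y: float
    n1: int
    n2: int
    z: float            # tie- and continuity-corrected normal approximation
    p: float            # p under the requested sidedness
    alternative: str
    p_one_sided: float
    p_two_sided: float
    rosenthal_r: float  # |z| / sqrt(n1 + n2)
    effect_label: str = ""

    def __post_init__(self):
        if not self.effect_label:
            self.effect_label = effect_size_label(self.rosenthal_r)

    def to_dict(self) -> dict:
        return {
            "test": "mann-whitney-u",
            "U": self.u,
            "U_x": self.u_x,
            "U_y": self.u_y,
            "n1": self.n1,
            "n2": self.n2,
            "z": self.z,
            "p": self.p,
            "alternative": self.alternative,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "rosenthal_r": self.rosenthal_r,
            "effect_label": self.effect_label,
        }


@dataclass
class CorrelationResult:
    """Pearson correlation with two-sided p, default BF10 and credible interval."""

    r: float
    p: float
    n: int
    bf10: float
    ci95: tuple[float, float]
    evidence: str = ""
    effect_label: str = ""

    def __post_init__(self):
        if not self.evidence:
            self.evidence = evidence_label(self.bf10)
        if not self.effect_label:
            self.effect_label = effect_size_label(self.r)

    def to_dict(self) -> dict:
        return {
            "test": "pearson-bf10",
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "BF10": self.bf10,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "evidence": self.evidence,
            "effect_label": self.effect_label,
        }


def ks_normality(x, lilliefors: bool = False, warnings_out: list | None = None):
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and (n-1) SD. With estimated
    parameters the plain KS p-value is anti-conservative; pass
    ``lilliefors=True`` for the corrected p (statsmodels). Used only as a
    gate for preferring nonparametric tests. Zero variance returns a
    degenerate non-normal verdict (statistic 1, p 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValidationError(f"need at least 5 observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        if warnings_out is not None:
            warnings_out.append("zero variance: distribution degenerate, non-normal")
        return 1.0, 0.0
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def mann_whitney_rosenthal(x, y, alternative: str = "two-sided") -> GroupTestResult:
    """Mann-Whitney U test with tie/continuity-corrected z and Rosenthal r.

    U_x counts pairs where x exceeds y plus half-ties; the headline
    statistic is min(U_x, U_y). The z approximation is
    ``(U - n1 n2 / 2 + 0.5) / sigma`` with the tie-corrected sigma, and
    the effect size is r = |z| / sqrt(n1 + n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("two-sided", "one-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    # rank-based computation (equivalent to pair counting with half-ties)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u_x = r1 - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    u = min(u_x, u_y)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise UndefinedResultError("all observations tied: z undefined")
    sigma = np.sqrt(var)
    z = (u - mu + 0.5) / sigma  # continuity correction toward the mean; z <= 0
    p_one = float(stats.norm.cdf(z))
    p_two = float(min(1.0, 2.0 * p_one))
    p = p_two if alternative == "two-sided" else p_one
    return GroupTestResult(
        u=float(u),
        u_x=float(u_x),
        u_y=float(u_y),
        n1=n1,
        n2=n2,
        z=float(z),
        p=p,
        alternative=alternative,
        p_one_sided=p_one,
        p_two_sided=p_two,
        rosenthal_r=float(abs(z) / np.sqrt(n)),
    )


def _log_likelihood_ratio(rho, r: float, n: int):
    """log f(r | rho, n) - log f(r | 0, n) for the exact density of Pearson r."""
    num = (
        (n - 1) / 2.0 * np.log1p(-rho * rho)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2.0, (rho * r + 1) / 2.0))
    )
    den = np.log(special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2.0, (r * 0 + 1) / 2.0))
    return num - den


def pearson_bf10(
    x, y=None, r: float | None = None, n: int | None = None
) -> CorrelationResult:
    """Pearson r with two-sided p, JZS default BF10 and 95% credible interval.

    Either pass two samples, or a precomputed ``r`` and ``n`` (summary
    form). BF10 integrates the exact sampling density of r over the
    uniform prior on rho in (-1, 1); the credible interval comes from the
    quantiles of the resulting gridded posterior.
    """
    if x is not None and y is not None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValidationError("samples differ in length")
        n = x.size
        if n < 4:
            raise ValidationError(f"need at least 4 paired observations, got {n}")
        if x.std() == 0 or y.std() == 0:
            raise UndefinedResultError("zero variance: correlation undefined")
        r, p = stats.pearsonr(x, y)
        r, p = float(r), float(p)
    else:
        if r is None or n is None:
            raise ValidationError("pass samples, or both r and n")
        if n < 4 or not (-1 <= r <= 1):
            raise ValidationError("invalid summary input")
        # two-sided p from the t transform of r
        if abs(r) == 1:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))

    if abs(r) >= 1.0 - 1e-12:  # numerically perfect: the integral diverges
        return CorrelationResult(r=r, p=p, n=n, bf10=np.inf, ci95=(r, r))

    bf10, _err = integrate.quad(
        lambda rho: 0.5 * np.exp(_log_likelihood_ratio(rho, r, n)), -1, 1, limit=200
    )

    grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 4001)
    log_post = _log_likelihood_ratio(grid, r, n)  # hyp2f1 broadcasts over rho
    post = np.exp(log_post - log_post.max())
    cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(post, grid)])
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return CorrelationResult(r=r, p=p, n=n, bf10=float(bf10), ci95=(lo, hi))


def compare_band_proportions(table: pd.DataFrame) -> dict:
    """Compare impulsive vs compulsive band proportions among flagged subjects.

    ``table`` is the 5-band x 5-scale percent-frequency table (rows
    indexed by band label). The impulsive group pools the 10 values of
    the two impulsivity bands across the five ICT scales, the compulsive
    group the 10 values of the two compulsivity bands; the groups are
    compared by Mann-Whitney U and summarized by mean / median / (n-1) SD
    / interquartile range.
    """
    needed = set(IMPULSIVE_BANDS + COMPULSIVE_BANDS)
    if not needed.issubset(set(table.index)):
        raise ValidationError(f"table must have band rows {sorted(needed)}")
    if table.shape[1] != 5:
        raise ValidationError(f"expected 5 ICT scale columns, got {table.shape[1]}")
    imp = table.loc[list(IMPULSIVE_BANDS)].to_numpy(dtype=float).ravel()
    comp = table.loc[list(COMPULSIVE_BANDS)].to_numpy(dtype=float).ravel()
    if np.isnan(imp).any() or np.isnan(comp).any():
        raise ValidationError("band table contains undefined (NaN) cells")

    def _summary(v: np.ndarray) -> dict:
        q1, q3 = np.percentile(v, [25, 75])
        return {
            "n": int(v.size),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "sd": float(v.std(ddof=1)),
            "iqr": float(q3 - q1),
        }

    test = mann_whitney_rosenthal(imp, comp, alternative="two-sided")
    return {
        "test": test,
        "impulsive": _summary(imp),
        "compulsive": _summary(comp),
    }
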