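"""Synthetic questionnaire cohorts with the structure the analysis assumes.

The generator emulates an online-survey cohort of ~800 adults screened
for ICT use/abuse: demographics drawn from the study population's band
frequencies (women ~68%, mostly 31-60 years old, predominantly
university-educated Europeans); two correlated latent traits I
(impulsivity) and C (compulsivity); eight UPPS/OCDUS subscale scores
generated as linear functions of one latent plus weak negative age and
education effects; PSI factor scores loading positively on I; and
MULTICAGE endorsement probabilities rising with both latents but more
steeply with C, so that flagged (possible-addiction) subjects skew toward
the compulsive pole downstream. A configurable fraction of multivariate
outliers is planted by shifting score vectors along a random direction.

Continuous subscale targets are emitted as integer item responses by
spreading the target total equally across the subscale's items and
rounding with small independent per-item noise — the simplest mechanism
that preserves subscale-level structure. One named random stream per
component (demographics, latents, items, MULTICAGE, outliers) hangs off
the single global seed, so adding a component never perturbs another's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .instruments import (
    AXIS_COLUMNS,
    MULTICAGE_SCALES,
    OCDUS_SUBSCALES,
    UPPS_SUBSCALES,
    default_specs,
)

__all__ = [
    "SubscaleLoading",
    "MulticageLoading",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "recover_parameters",
]

# Band frequencies of the reference cohort (n=807): counts per band.
_SEX_COUNTS = {"woman": 546, "man": 261}
_AGE_COUNTS = {"<18": 13, "18-25": 128, "26-30": 107, "31-45": 213, "46-60": 261, ">60": 85}
_EDU_COUNTS = {
    "primary": 25,
    "secondary": 30,
    "high_school": 119,
    "university_student": 79,
    "university_degree": 554,
}
_NATIONALITY_COUNTS = {
    "Europe": 762,
    "South America": 37,
    "Central America": 6,
    "Asia": 1,
    "Africa": 1,
}
_RESIDENCE_COUNTS = {
    "Europe": 785,
    "North America": 1,
    "South America": 15,
    "Central America": 5,
    "Oceania": 1,
}


def _probs(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class SubscaleLoading:
    """Linear model for one subscale's continuous target on the 0-100 scale.

    target = mean + b_latent * L + b_age * (age_code - age_ref)
                  + b_education * (education_code - education_ref) + N(0, noise_sd)

    where L is the subject's latent I or C (standard normal marginally).
    """

    mean: float
    latent: str            # "I" or "C"
    b_latent: float
    b_age: float
    b_education: float
    noise_sd: float

    @classmethod
    def from_targets(
        cls,
        mean: float,
        sd: float,
        latent: str,
        latent_corr: float,
        age_r: float,
        education_r: float,
        age_sd: float,
        education_sd: float,
    ) -> "SubscaleLoading":
        """Build coefficients from target SD and target correlations."""
        resid_var = sd * sd * (1 - latent_corr**2 - age_r**2 - education_r**2)
        if resid_var < 0:
            raise ValidationError("target correlations imply negative noise variance")
        return cls(
            mean=mean,
            latent=latent,
            b_latent=latent_corr * sd,
            b_age=age_r * sd / age_sd,
            b_education=education_r * sd / education_sd,
            noise_sd=float(np.sqrt(resid_var)),
        )


@dataclass(frozen=True)
class MulticageLoading:
    """Per-item endorsement logit for one MULTICAGE scale:
    logit p = intercept + b_impulsivity * I + b_compulsivity * C."""

    intercept: float = -1.4
    b_impulsivity: float = 0.35
    b_compulsivity: float = 0.9


def _code_moments(probs: dict) -> tuple[float, float]:
    codes = np.arange(1, len(probs) + 1, dtype=float)
    p = np.array(list(probs.values()))
    mean = float((codes * p).sum())
    sd = float(np.sqrt((codes**2 * p).sum() - mean**2))
    return mean, sd


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 807
    seed: int = 0
    sex_probs: dict = field(default_factory=lambda: _probs(_SEX_COUNTS))
    age_probs: dict = field(default_factory=lambda: _probs(_AGE_COUNTS))
    education_probs: dict = field(default_factory=lambda: _probs(_EDU_COUNTS))
    nationality_probs: dict = field(default_factory=lambda: _probs(_NATIONALITY_COUNTS))
    residence_probs: dict = field(default_factory=lambda: _probs(_RESIDENCE_COUNTS))
    latent_rho: float = 0.4
    loadings: dict = None  # column name -> SubscaleLoading; filled by default_config
    multicage: dict = field(
        default_factory=lambda: {s: MulticageLoading() for s in MULTICAGE_SCALES}
    )
    item_noise_sd: float = 0.6
    outlier_fraction: float = 0.0
    outlier_shift: float = 8.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not -1.0 <= self.latent_rho <= 1.0:
            raise ValidationError("|latent_rho| must be <= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValidationError("outlier_fraction must be in [0, 1)")
        for name, probs in (
            ("sex", self.sex_probs),
            ("age", self.age_probs),
            ("education", self.education_probs),
            ("nationality", self.nationality_probs),
            ("residence", self.residence_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} probabilities must sum to 1")
        for col, ld in self.loadings.items():
            if not 0.0 <= ld.mean <= 100.0:
                raise ValidationError(f"{col}: target mean {ld.mean} outside [0, 100]")
            if ld.latent not in ("I", "C", "none"):
                raise ValidationError(f"{col}: latent must be 'I', 'C' or 'none'")


# Target normalized means/SDs and covariate correlations of the reference
# cohort's eight axis subscales (OCDUS converted from the raw scale), plus
# the three PSI factors.
_SUBSCALE_TARGETS = {
    "UPPS_negative_urgency": ("I", 47.41, 18.49, -0.07, -0.16),
    "UPPS_positive_urgency": ("I", 45.97, 15.27, -0.19, -0.17),
    "UPPS_lack_premeditation": ("I", 24.47, 16.39, -0.09, 0.04),
    "UPPS_lack_perseverance": ("I", 20.62, 16.83, -0.09, -0.11),
    "UPPS_sensation_seeking": ("I", 43.33, 19.60, -0.35, -0.09),
    "OCDUS_thought_interference": ("C", 22.39, 15.69, -0.28, -0.04),
    "OCDUS_desire_control": ("C", 31.08, 19.79, -0.28, 0.01),
    "OCDUS_resistance": ("C", 17.25, 19.08, -0.35, -0.01),
    "PSI_behavioral_control": ("I", 32.0, 17.0, -0.10, 0.0),
    "PSI_emotional_control": ("I", 32.0, 17.0, -0.10, 0.0),
    "PSI_social_behavior": ("I", 32.0, 17.0, -0.10, 0.0),
}

#: Shared latent correlation of every generated subscale with its trait.
_DEFAULT_LATENT_CORR = 0.65


def default_config(**overrides) -> CohortConfig:
    """The standard study-shaped cohort configuration (n=807).

    Keyword overrides replace any :class:`CohortConfig` field; pass
    ``latent_corr=`` to rebuild all loadings at a different trait loading.
    """
    latent_corr = overrides.pop("latent_corr", _DEFAULT_LATENT_CORR)
    base = CohortConfig(loadings={})
    age_mean, age_sd = _code_moments(base.age_probs)
    edu_mean, edu_sd = _code_moments(base.education_probs)
    loadings = {}
    for col, (latent, mean, sd, age_r, edu_r) in _SUBSCALE_TARGETS.items():
        lc = latent_corr if col in AXIS_COLUMNS else 0.30
        loadings[col] = SubscaleLoading.from_targets(
            mean, sd, latent, lc, age_r, edu_r, age_sd, edu_sd
        )
    cfg = replace(base, loadings=loadings, **overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticCohort:
    """A generated cohort: demographics, item responses and ground truth."""

    demographics: pd.DataFrame     # index subject_id; bands + continents
    responses: pd.DataFrame        # long format item response table
    ground_truth: pd.DataFrame     # I, C, age_code, education_code, planted_outlier
    config: CohortConfig

    def write(self, out_dir) -> None:
        """Write the long responses, demographics and ground truth as CSV."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.responses.to_csv(out / "responses.csv", index=False)
        self.demographics.to_csv(out / "demographics.csv", index_label="subject_id")
        self.ground_truth.to_csv(out / "ground_truth.csv", index_label="subject_id")


def _model_covariance(config: CohortConfig) -> np.ndarray:
    """Model-implied covariance of the eight emitted subscale scores (0-100).

    Includes the latent, covariate and target-noise structure plus the
    per-item rounding/emission noise propagated to the normalized scale.
    """
    _, age_sd = _code_moments(config.age_probs)
    _, edu_sd = _code_moments(config.education_probs)
    specs = default_specs()
    cols = list(AXIS_COLUMNS)
    p = len(cols)
    sigma = np.zeros((p, p))
    for j in range(p):
        lj = config.loadings[cols[j]]
        for k in range(p):
            lk = config.loadings[cols[k]]
            if lj.latent == "none" or lk.latent == "none":
                lat = 0.0
            else:
                lat = 1.0 if lj.latent == lk.latent else config.latent_rho
            sigma[j, k] = (
                lj.b_latent * lk.b_latent * lat
                + lj.b_age * lk.b_age * age_sd**2
                + lj.b_education * lk.b_education * edu_sd**2
            )
            if j == k:
                sigma[j, k] += lj.noise_sd**2
                inst, sub = cols[j].split("_", 1)
                spec = specs[inst]
                n_items = len(spec.subscales[sub])
                s_lo, s_hi = spec.subscale_range(sub)
                # rounding (+1/12) and per-item jitter, on the percent scale
                emission_var = n_items * (config.item_noise_sd**2 + 1.0 / 12.0)
                sigma[j, k] += emission_var * (100.0 / (s_hi - s_lo)) ** 2
    return sigma


def _sample_bands(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels])
    return rng.choice(labels, size=n, p=p)


def _emit_items(
    rng: np.random.Generator,
    raw_target: np.ndarray,
    n_items: int,
    lo: int,
    hi: int,
    noise_sd: float,
) -> np.ndarray:
    """Spread subscale totals over items; round and clamp to the item range."""
    base = raw_target[:, None] / n_items
    noisy = base + rng.normal(0.0, noise_sd, size=(raw_target.size, n_items))
    return np.clip(np.rint(noisy), lo, hi).astype(int)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort from ``config``.

    ``seed`` overrides ``config.seed``. Identical config + seed yields a
    byte-identical cohort.
    """
    if config is None:
        config = default_config()
    if config.loadings is None:
        config = replace(config, loadings=default_config().loadings)
    if seed is not None:
        config = replace(config, seed=int(seed))
    config.validate()
    n = config.n_subjects
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_demo, rng_lat, rng_items, rng_mc, rng_out = (np.random.default_rng(s) for s in streams)

    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    demo = pd.DataFrame(
        {
            "sex": _sample_bands(rng_demo, config.sex_probs, n),
            "age_band": _sample_bands(rng_demo, config.age_probs, n),
            "education_band": _sample_bands(rng_demo, config.education_probs, n),
            "nationality_continent": _sample_bands(rng_demo, config.nationality_probs, n),
            "residence_continent": _sample_bands(rng_demo, config.residence_probs, n),
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    age_order = list(config.age_probs)
    edu_order = list(config.education_probs)
    age_code = demo["age_band"].map({b: i + 1 for i, b in enumerate(age_order)}).to_numpy()
    edu_code = demo["education_band"].map({b: i + 1 for i, b in enumerate(edu_order)}).to_numpy()
    age_ref, _ = _code_moments(config.age_probs)
    edu_ref, _ = _code_moments(config.education_probs)

    cov = np.array([[1.0, config.latent_rho], [config.latent_rho, 1.0]])
    latents = rng_lat.multivariate_normal([0.0, 0.0], cov, size=n)
    latent_i, latent_c = latents[:, 0], latents[:, 1]

    # continuous subscale targets on the normalized 0-100 scale
    targets: dict[str, np.ndarray] = {}
    for col, ld in config.loadings.items():
        lat = {"I": latent_i, "C": latent_c, "none": np.zeros(n)}[ld.latent]
        targets[col] = (
            ld.mean
            + ld.b_latent * lat
            + ld.b_age * (age_code - age_ref)
            + ld.b_education * (edu_code - edu_ref)
            + rng_lat.normal(0.0, ld.noise_sd, size=n)
        )

    # plant multivariate outliers on the eight axis subscales; the shift is
    # measured in Mahalanobis SD units of the model-implied score
    # covariance, so a planted displacement of s has squared distance ~s^2
    # under the downstream filter regardless of direction
    n_out = int(round(n * config.outlier_fraction))
    planted = np.zeros(n, dtype=bool)
    if n_out > 0:
        idx = rng_out.choice(n, size=n_out, replace=False)
        planted[idx] = True
        sigma = _model_covariance(config)
        chol = np.linalg.cholesky(sigma)
        sigma_inv = np.linalg.inv(sigma)
        for i in idx:
            t = np.array([targets[col][i] for col in AXIS_COLUMNS])
            # the 0-100 scale truncates extreme targets, so directions that
            # cannot express the displacement are rejection-resampled; of
            # the two opposite displacements the one retaining more
            # Mahalanobis length after clipping is kept
            best = None
            for _attempt in range(20):
                u = rng_out.normal(size=len(AXIS_COLUMNS))
                u /= np.linalg.norm(u)
                v = config.outlier_shift * (chol @ u)
                for cand in (np.clip(t + v, 0.0, 100.0), np.clip(t - v, 0.0, 100.0)):
                    d = cand - t
                    d2 = float(d @ sigma_inv @ d)
                    if best is None or d2 > best[0]:
                        best = (d2, cand)
                if best[0] >= 0.75 * config.outlier_shift**2:
                    break
            for k, col in enumerate(AXIS_COLUMNS):
                targets[col][i] = best[1][k]

    # emit item responses
    specs = default_specs()
    records: list[pd.DataFrame] = []

    def _add(instrument: str, items: tuple[int, ...], values: np.ndarray) -> None:
        for j, item in enumerate(items):
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids,
                        "instrument": instrument,
                        "item": item,
                        "response": values[:, j],
                    }
                )
            )

    for inst_name in ("UPPS", "OCDUS", "PSI"):
        spec = specs[inst_name]
        lo, hi = spec.response_range
        for sub in spec.subscales:
            if sub == "total":
                continue
            col = f"{inst_name}_{sub}"
            s_lo, s_hi = spec.subscale_range(sub)
            raw = s_lo + targets[col] / 100.0 * (s_hi - s_lo)
            if sub in spec.inverted_subscales:
                raw = s_lo + s_hi - raw  # items carry the pre-inversion score
            raw = np.clip(raw, s_lo, s_hi)
            items = spec.subscales[sub]
            vals = _emit_items(rng_items, raw, len(items), lo, hi, config.item_noise_sd)
            # reverse-keyed items are stored in observed (pre-key) orientation
            for j, item in enumerate(items):
                if item in spec.reverse_keyed_items:
                    vals[:, j] = lo + hi - vals[:, j]
            _add(inst_name, items, vals)

    mc_spec = specs["MULTICAGE"]
    for scale in MULTICAGE_SCALES:
        ld = config.multicage[scale]
        logit = ld.intercept + ld.b_impulsivity * latent_i + ld.b_compulsivity * latent_c
        p = 1.0 / (1.0 + np.exp(-logit))
        items = mc_spec.subscales[scale]
        vals = (rng_mc.random(size=(n, len(items))) < p[:, None]).astype(int)
        _add("MULTICAGE", items, vals)

    responses = pd.concat(records, ignore_index=True)
    truth = pd.DataFrame(
        {
            "I": latent_i,
            "C": latent_c,
            "age_code": age_code,
            "education_code": edu_code,
            "planted_outlier": planted,
        },
        index=demo.index,
    )
    return SyntheticCohort(demographics=demo, responses=responses, ground_truth=truth, config=config)


def recover_parameters(cohort: SyntheticCohort) -> dict:
    """Parameter-recovery report for a generated cohort.

    Runs the standard pipeline (score -> rescale -> outlier filter ->
    residualize -> axis) and reports the correlation between each
    retained subject's ground-truth I - C contrast and the computed axis,
    plus sign agreement between configured covariate effects and the
    recovered score-covariate correlations.
    """
    from . import axis as axis_mod
    from . import preprocess
    from .instruments import score_battery

    truth = cohort.ground_truth
    scores = score_battery(cohort.responses)
    normalized = preprocess.rescale_0_100(scores)
    retained, report = preprocess.mahalanobis_filter(normalized)
    covs = preprocess.encode_covariates(cohort.demographics)
    z = preprocess.residualize_z(retained, covs)
    ax = axis_mod.compute_axis(z)

    contrast = (truth["I"] - truth["C"]).reindex(ax.index)
    if contrast.std() == 0 or ax["axis"].std() == 0:
        axis_truth_corr = 0.0
    else:
        axis_truth_corr = float(np.corrcoef(ax["axis"], contrast)[0, 1])

    sign_report = {}
    covs_ret = covs.reindex(retained.index)
    for col, ld in cohort.config.loadings.items():
        if col not in retained.columns:
            continue
        entry = {}
        for cov_name, b in (("age_code", ld.b_age), ("education_code", ld.b_education)):
            r = float(np.corrcoef(retained[col], covs_ret[cov_name])[0, 1])
            entry[cov_name] = {
                "configured_coefficient": b,
                "observed_r": r,
                "sign_agrees": bool(np.sign(r) == np.sign(b)) if b != 0 else None,
            }
        sign_report[col] = entry
    return {
        "axis_truth_corr": axis_truth_corr,
        "n_retained": len(ax),
        "n_excluded": len(report.excluded),
        "covariate_signs": sign_report,
    }


def config_from_yaml(path) -> CohortConfig:
    """Load a cohort configuration from YAML (missing keys keep defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    overrides = {}
    simple = {
        "n_subjects",
        "seed",
        "latent_rho",
        "item_noise_sd",
        "outlier_fraction",
        "outlier_shift",
        "sex_probs",
        "age_probs",
        "education_probs",
        "nationality_probs",
        "residence_probs",
    }
    for key in simple & set(raw):
        overrides[key] = raw[key]
    latent_corr = raw.get("latent_corr", _DEFAULT_LATENT_CORR)
    cfg = default_config(latent_corr=latent_corr, **overrides)
    if "multicage" in raw:
        mc = {
            s: MulticageLoading(**raw["multicage"].get(s, {}))
            for s in MULTICAGE_SCALES
        }
        cfg = replace(cfg, multicage=mc)
    if "loadings" in raw:
        loadings = dict(cfg.loadings)
        for col, kv in raw["loadings"].items():
            loadings[col] = SubscaleLoading(**kv)
        cfg = replace(cfg, loadings=loadings)
    cfg.validate()
    return cfg
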