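"""End-to-end orchestration: simulate/ingest -> score -> condition -> axis
-> stats battery -> character models -> report.

Every run is driven by a :class:`RunConfig`; all randomness flows from its
named seeds and every stage's artifacts are written under the output
directory together with a manifest (config, seeds, package version), so a
run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import axis as axis_mod
from . import prediction, preprocess, stats, synthetic
from .errors import ValidationError
from .instruments import default_specs, score_battery

__all__ = ["RunConfig", "check_sample_size", "run_pipeline", "demographics_summary"]

log = logging.getLogger("ictaxis")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    # input: either a synthetic cohort ...
    synthetic: bool = True
    n_subjects: int = 807
    cohort_seed: int = 0
    outlier_fraction: float = 0.006
    # ... or CSV paths (long-format responses + demographics)
    responses_csv: str | None = None
    demographics_csv: str | None = None

    outlier_alpha: float = 0.001
    band_inner: float = 10.0
    band_outer: float = 20.0
    split_ratio: float = 0.8
    split_seed: int = 0
    model_seed: int = 0
    families: tuple = prediction.FAMILIES
    delta: float = 0.1
    grid_resolution: int = 101
    out_dir: str = "ictaxis_run"
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown run-config keys {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        cfg = asdict(self)
        cfg["families"] = list(cfg["families"])
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "package": "ictaxis",
            "version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
        }


def check_sample_size(n_subjects: int, item_counts: dict[str, int] | None = None) -> dict:
    """The n/p sample-size rule for questionnaire studies: 10 subjects per item.

    p is the total number of items over the analyzed instruments (default
    battery: 20 + 12 + 20 + 20 = 72); the verdict passes iff n/p >= 10.
    """
    if item_counts is None:
        item_counts = {name: len(s.items) for name, s in default_specs().items()}
    p = sum(item_counts.values())
    ratio = round(n_subjects / p, 2)
    return {
        "n": n_subjects,
        "p": p,
        "ratio": ratio,
        "minimum_n": 10 * p,
        "verdict": "pass" if ratio >= 10 else "fail",
    }


def demographics_summary(demographics: pd.DataFrame) -> dict:
    """Counts and percents by sex within each age and education band."""
    n = len(demographics)
    out: dict = {"n": n, "by": {}}
    for col in ("age_band", "education_band", "nationality_continent", "residence_continent"):
        if col not in demographics.columns:
            continue
        table = {}
        for band, grp in demographics.groupby(col, sort=False):
            row = {"total": {"count": len(grp), "pct": round(len(grp) / n * 100, 1)}}
            if "sex" in demographics.columns:
                for sex, sgrp in grp.groupby("sex"):
                    row[sex] = {"count": len(sgrp), "pct": round(len(sgrp) / n * 100, 1)}
            table[str(band)] = row
        out["by"][col] = table
    if "sex" in demographics.columns:
        out["by"]["sex"] = {
            str(sex): {"count": len(g), "pct": round(len(g) / n * 100, 1)}
            for sex, g in demographics.groupby("sex")
        }
    return out


def _load_input(config: RunConfig):
    from .instruments import long_from_wide  # noqa: F401  (documented companion reader)

    if config.synthetic:
        cohort = synthetic.generate_cohort(
            synthetic.default_config(
                n_subjects=config.n_subjects,
                outlier_fraction=config.outlier_fraction,
            ),
            seed=config.cohort_seed,
        )
        return cohort.responses, cohort.demographics, cohort
    if not config.responses_csv or not config.demographics_csv:
        raise ValidationError("non-synthetic runs need responses_csv and demographics_csv")
    responses = pd.read_csv(config.responses_csv)
    demographics = pd.read_csv(config.demographics_csv).set_index("subject_id")
    return responses, demographics, None


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Returns the report dict (also serialized as ``report.json`` with CSV
    side tables and a Markdown summary).
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"manifest": config.manifest(), "stages": {}}
    stage = "input"
    try:
        responses, demographics, cohort = _load_input(config)
        n0 = demographics.shape[0]
        log.info("input: %d subjects", n0)
        report["stages"]["input"] = {"n_subjects": n0}
        report["sample_size_rule"] = check_sample_size(n0)
        report["demographics"] = demographics_summary(demographics)

        stage = "score"
        scores = score_battery(responses)
        scores.to_csv(out / "scores_raw.csv", index_label="subject_id")

        stage = "rescale"
        normalized = preprocess.rescale_0_100(scores)
        normalized.to_csv(out / "scores_normalized.csv", index_label="subject_id")
        summary_cols = list(preprocess.AXIS_COLUMNS)
        report["stages"]["normalized_summary"] = {
            c: {
                "mean": float(normalized[c].mean()),
                "sd": float(normalized[c].std(ddof=1)),
                "median": float(normalized[c].median()),
                "min": float(normalized[c].min()),
                "max": float(normalized[c].max()),
            }
            for c in summary_cols
        }

        stage = "outlier_filter"
        retained, outlier_report = preprocess.mahalanobis_filter(
            normalized, alpha=config.outlier_alpha
        )
        outlier_report.distances_sq.to_csv(out / "mahalanobis_distances.csv")
        (out / "outlier_report.json").write_text(json.dumps(outlier_report.summary(), indent=2))
        report["stages"]["outliers"] = outlier_report.summary()
        log.info(
            "outlier filter: %d excluded of %d", len(outlier_report.excluded), n0
        )

        stage = "residualize"
        warnings: list = []
        covariates = preprocess.encode_covariates(demographics.loc[retained.index])
        z = preprocess.residualize_z(retained, covariates, warnings_out=warnings)
        z.to_csv(out / "scores_residual_z.csv", index_label="subject_id")

        stage = "covariate_correlations"
        cov_table = {}
        for col in preprocess.AXIS_COLUMNS:
            cov_table[col] = {
                name: stats.pearson_bf10(retained[col], covariates[name]).to_dict()
                for name in ("age_code", "education_code")
            }
        report["covariate_correlations"] = cov_table

        stage = "axis"
        rule = axis_mod.BandRule(inner=config.band_inner, outer=config.band_outer)
        ax = axis_mod.compute_axis(z, band_rule=rule)
        ax.to_csv(out / "axis.csv", index_label="subject_id")
        report["axis_descriptives"] = axis_mod.axis_descriptives(ax["axis"])
        report["axis_consistency"] = axis_mod.axis_consistency(ax)
        report["band_counts"] = ax["band"].value_counts().to_dict()

        stage = "band_frequency"
        flags = scores.loc[ax.index]
        band_table = axis_mod.band_frequency_table(ax["band"], flags, warnings_out=warnings)
        band_table.to_csv(out / "band_frequency.csv", index_label="band")
        if not band_table.isna().any().any():
            cmp_res = stats.compare_band_proportions(band_table)
            report["band_comparison"] = {
                "test": cmp_res["test"].to_dict(),
                "impulsive": cmp_res["impulsive"],
                "compulsive": cmp_res["compulsive"],
            }

        stage = "labeled_selection"
        features = prediction.feature_table(scores).loc[ax.index]
        models_report = {}
        fitted = {}
        for model_name, pair in (
            ("gpc_psi_multicage", ("PSI_total_pct", "MULTICAGE_total_pct")),
            ("gpc_upps_ocdus", ("UPPS_total_pct", "OCDUS_total_pct")),
        ):
            try:
                labeled = prediction.select_labeled(
                    ax, features, feature_pair=pair, inner=config.band_inner
                )
                tournament = prediction.model_tournament(
                    labeled,
                    families=tuple(config.families),
                    seed=config.split_seed,
                )
            except ValidationError as exc:
                warnings.append(f"{model_name} skipped: sample too small ({exc})")
                models_report[model_name] = {"skipped": str(exc)}
                continue
            train_idx, test_idx = tournament["split"]
            gpc = tournament["models"].get("gpc")
            entry = {
                "feature_pair": list(pair),
                "n_labeled": labeled.attrs["n_retained"],
                "retained_fraction": labeled.attrs["retained_fraction"],
                "n_train": len(train_idx),
                "n_test": len(test_idx),
                "accuracies_pct": tournament["accuracies"],
                "failures": tournament["failures"],
                "winner": tournament["winner"],
            }
            if gpc is not None:
                grid = prediction.decision_region(
                    gpc, resolution=config.grid_resolution, delta=config.delta
                )
                grid.to_frame().to_csv(out / f"decision_region_{model_name}.csv", index=False)
                entry["gpc_accuracy_pct"] = gpc.test_accuracy
                entry["unconditional_compulsive_level"] = grid.unconditional_compulsive_level()
                fitted[model_name] = (gpc, labeled, grid)
            models_report[model_name] = entry
        report["models"] = models_report

        stage = "distillation"
        if "gpc_upps_ocdus" in fitted:
            gpc, labeled, grid = fitted["gpc_upps_ocdus"]
            try:
                boundary = prediction.distill_quadratic_rule(grid, labeled, gpc)
                report["quadratic_rule"] = {
                    "f1_coefficients": [float(c) for c in boundary.f1],
                    "f2_coefficients": [float(c) for c in boundary.f2],
                    "delta": boundary.delta,
                    "agreement_pct": boundary.agreement_pct,
                }
            except ValidationError as exc:
                warnings.append(f"distillation skipped: {exc}")

        stage = "recovery"
        if cohort is not None:
            rec = synthetic.recover_parameters(cohort)
            report["parameter_recovery"] = {
                "axis_truth_corr": rec["axis_truth_corr"],
                "n_retained": rec["n_retained"],
            }

        stage = "figures"
        if config.figures:
            _write_figures(out, ax, fitted)

        report["warnings"] = warnings
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        _write_markdown(out, report)
        return report
    except Exception:
        (out / "report_partial.json").write_text(
            json.dumps({**report, "failed_stage": stage}, indent=2, default=str)
        )
        log.error("pipeline failed at stage %r", stage)
        raise


def _write_figures(out: Path, ax: pd.DataFrame, fitted: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(figsize=(6, 4))
    axes.hist(ax["axis"], bins=40, color="steelblue", edgecolor="white")
    axes.set_xlabel("Impulsivity-Compulsivity axis")
    axes.set_ylabel("Subjects")
    fig.tight_layout()
    fig.savefig(out / "axis_histogram.png", dpi=120)
    plt.close(fig)

    for name, (gpc, labeled, grid) in fitted.items():
        fig, axes = plt.subplots(figsize=(5.5, 5))
        axes.contourf(
            grid.x,
            grid.y,
            grid.p_compulsive,
            levels=[0.0, 0.5 - grid.delta, 0.5 + grid.delta, 1.0],
            colors=["#4c72b0", "#ffffff", "#c44e52"],
            alpha=0.5,
        )
        colors = labeled["label"].map({"impulsive": "#4c72b0", "compulsive": "#c44e52"})
        axes.scatter(
            labeled[grid.feature_names[0]],
            labeled[grid.feature_names[1]],
            c=colors,
            s=12,
            edgecolors="k",
            linewidths=0.3,
        )
        axes.set_xlabel(grid.feature_names[0])
        axes.set_ylabel(grid.feature_names[1])
        axes.set_title(name)
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)


def _write_markdown(out: Path, report: dict) -> None:
    lines = ["# Impulsivity-Compulsivity axis run report", ""]
    m = report["manifest"]
    lines.append(f"Package ictaxis {m['version']}; config sha256 {m['config_sha256'][:12]}.")
    ssr = report["sample_size_rule"]
    lines.append(
        f"\n## Sample\n\nn = {ssr['n']}, p = {ssr['p']} items, n/p = {ssr['ratio']} "
        f"({ssr['verdict']}; minimum n = {ssr['minimum_n']})."
    )
    outl = report["stages"].get("outliers", {})
    if outl:
        lines.append(
            f"Outlier screening: {outl['n_excluded']} of {outl['n_total']} excluded "
            f"(Mahalanobis d2 > {outl['threshold']:.2f}, chi2 df={outl['chi2_df']}, "
            f"p < {outl['alpha']})."
        )
    d = report.get("axis_descriptives", {})
    if d:
        lines.append(
            f"\n## Axis\n\nmean {d['mean']:.2f}, SD {d['sd']:.2f}, "
            f"range [{d['min']:.2f}, {d['max']:.2f}], skewness {d['skewness']:.2f}, "
            f"excess kurtosis {d['excess_kurtosis']:.2f}."
        )
    if "band_counts" in report:
        lines.append("\nBand counts: " + ", ".join(f"{k}: {v}" for k, v in report["band_counts"].items()))
    if "models" in report:
        lines.append("\n## Character models\n")
        for name, entry in report["models"].items():
            if "skipped" in entry:
                lines.append(f"- **{name}**: skipped ({entry['skipped']}).")
                continue
            accs = ", ".join(f"{f}: {a:.1f}%" for f, a in sorted(entry["accuracies_pct"].items()))
            lines.append(
                f"- **{name}** ({' x '.join(entry['feature_pair'])}): n={entry['n_labeled']} "
                f"({entry['retained_fraction']*100:.1f}% of cohort), split "
                f"{entry['n_train']}/{entry['n_test']}; {accs}; winner {entry['winner']}."
            )
    if "quadratic_rule" in report:
        q = report["quadratic_rule"]
        lines.append(
            f"\nDistilled quadratic rule agreement with GPC: {q['agreement_pct']:.1f}%."
        )
    if report.get("warnings"):
        lines.append("\n## Warnings\n")
        lines.extend(f"- {w}" for w in report["warnings"])
    (out / "report.md").write_text("\n".join(lines) + "\n")
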