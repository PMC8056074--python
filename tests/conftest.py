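import numpy as np
import pandas as pd
import pytest

from ictaxis import axis as axis_mod
from ictaxis import preprocess, synthetic
from ictaxis.instruments import default_specs, score_battery


def make_long(instrument: str, subject_responses: dict[str, list[int]]) -> pd.DataFrame:
    """Build a long-format response table for one instrument.

    ``subject_responses`` maps subject_id -> responses ordered by item 1..k.
    """
    spec = default_specs()[instrument]
    items = spec.items
    rows = []
    for sid, resp in subject_responses.items():
        assert len(resp) == len(items)
        for item, r in zip(items, resp):
            rows.append((sid, instrument, item, r))
    return pd.DataFrame(rows, columns=["subject_id", "instrument", "item", "response"])


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def cohort():
    """Default study-shaped cohort (n=807, seed 42, planted outliers)."""
    cfg = synthetic.default_config(n_subjects=807, outlier_fraction=0.006)
    return synthetic.generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def cohort_scores(cohort):
    return score_battery(cohort.responses)


@pytest.fixture(scope="session")
def cohort_axis(cohort, cohort_scores):
    """Retained normalized scores, residual-Z table and axis for the default cohort."""
    normalized = preprocess.rescale_0_100(cohort_scores)
    retained, report = preprocess.mahalanobis_filter(normalized)
    covs = preprocess.encode_covariates(cohort.demographics.loc[retained.index])
    z = preprocess.residualize_z(retained, covs)
    ax = axis_mod.compute_axis(z)
    return {"normalized": normalized, "retained": retained, "z": z, "axis": ax, "report": report}


# Printed 5-band x 5-scale percent-frequency table of axis bands among
# subjects flagged on each ICT screening scale (reference cohort).
TABLE6 = pd.DataFrame(
    {
        "internet": [1.22, 6.99, 68.39, 20.06, 3.34],
        "cell_phone": [0.22, 8.19, 72.12, 16.59, 2.88],
        "videogames": [1.30, 11.69, 71.43, 12.99, 2.60],
        "instant_messaging": [1.02, 9.49, 66.78, 18.64, 4.07],
        "social_networks": [1.08, 7.53, 63.98, 23.12, 4.30],
    },
    index=[
        "high_impulsivity",
        "moderate_impulsivity",
        "balance",
        "moderate_compulsivity",
        "high_compulsivity",
    ],
)
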