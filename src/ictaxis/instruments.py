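"""Structure and scoring of the four self-report instruments.

The battery consists of:

* **UPPS-P (short form)** — 20 items on a 1-4 Likert scale measuring five
  impulsivity traits (4 items each): negative urgency, lack of
  premeditation, lack of perseverance, sensation seeking, positive urgency.
  Because agreement is coded 1, the urgency and sensation-seeking subscales
  are inverted at the scale level so every subscale points toward higher
  impulsivity; each subscale scores in [4, 16].
* **OCDUS-ICT** — 12 items on a 1-7 scale measuring compulsive ICT use,
  with three factors: thoughts & interference (6 items), desire & control
  (4 items) and resistance (2 items). Items 6 and 12 are reverse-keyed at
  the item level.
* **PSI-20** — 20 items on a 0-4 scale screening everyday symptoms of
  prefrontal dysfunction; three factors plus a total score in [0, 80].
* **MULTICAGE-ICT** — 20 dichotomous (yes/no) items, four per ICT
  behavior (internet, cell phone, videogames, instant messaging, social
  networks); a scale at >= 50% endorsement flags possible addiction signs.

Item-to-factor assignments for UPPS, OCDUS and PSI are shipped as editable
defaults (``default_specs`` / YAML) because published factor tables vary
between validation studies; the OCDUS resistance factor is pinned to the
two reverse-keyed items {6, 12} (the only 2-item factor). Only the
instrument totals and the eight UPPS/OCDUS subscale scores feed the axis,
so alternative PSI factor maps affect reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import UndefinedResultError, ValidationError

__all__ = [
    "InstrumentSpec",
    "default_specs",
    "load_specs",
    "score_instrument",
    "score_multicage",
    "score_battery",
    "cronbach_alpha",
    "reverse_item",
    "invert_scale",
    "long_from_wide",
    "UPPS_SUBSCALES",
    "OCDUS_SUBSCALES",
    "PSI_SUBSCALES",
    "MULTICAGE_SCALES",
    "AXIS_COLUMNS",
    "TOTAL_RANGES",
]

UPPS_SUBSCALES = (
    "negative_urgency",
    "lack_premeditation",
    "lack_perseverance",
    "sensation_seeking",
    "positive_urgency",
)
OCDUS_SUBSCALES = ("thought_interference", "desire_control", "resistance")
PSI_SUBSCALES = ("behavioral_control", "emotional_control", "social_behavior", "total")
MULTICAGE_SCALES = (
    "internet",
    "cell_phone",
    "videogames",
    "instant_messaging",
    "social_networks",
)

#: The eight columns entering outlier filtering, residualization and the axis.
AXIS_COLUMNS = tuple(f"UPPS_{s}" for s in UPPS_SUBSCALES) + tuple(
    f"OCDUS_{s}" for s in OCDUS_SUBSCALES
)

#: Theoretical ranges of the instrument totals used as classifier features.
TOTAL_RANGES = {
    "UPPS_total": (20, 80),
    "OCDUS_total": (12, 84),
    "PSI_total": (0, 80),
    "MULTICAGE_total": (0, 20),
}


@dataclass(frozen=True)
class InstrumentSpec:
    """Static description of one questionnaire.

    Parameters
    ----------
    name : str
        Instrument identifier: UPPS, OCDUS, PSI or MULTICAGE.
    response_range : tuple of int
        Inclusive (min, max) of a valid item response.
    subscales : dict
        Map from subscale name to the tuple of item numbers it comprises.
        Item sets must partition ``items`` (the PSI/MULTICAGE ``total``
        pseudo-subscale spans all items and is exempt from the partition).
    reverse_keyed_items : frozenset of int
        Items reversed at the item level before summing (x -> lo + hi - x).
    inverted_subscales : frozenset of str
        Subscales whose *score* is inverted after summing
        (s -> LO + HI - s on the subscale's theoretical range).
    """

    name: str
    response_range: tuple[int, int]
    subscales: dict[str, tuple[int, ...]]
    reverse_keyed_items: frozenset[int] = field(default_factory=frozenset)
    inverted_subscales: frozenset[str] = field(default_factory=frozenset)

    @property
    def items(self) -> tuple[int, ...]:
        out: list[int] = []
        for name, its in self.subscales.items():
            if name == "total":
                continue
            out.extend(its)
        return tuple(sorted(out))

    def subscale_range(self, subscale: str) -> tuple[int, int]:
        """Theoretical (min, max) of a subscale score."""
        lo, hi = self.response_range
        k = len(self.subscales[subscale])
        return (k * lo, k * hi)

    def validate(self) -> None:
        items = self.items
        if len(items) != len(set(items)):
            raise ValidationError(
                f"{self.name}: subscales do not partition the item set (duplicates)"
            )
        lo, hi = self.response_range
        if lo >= hi:
            raise ValidationError(f"{self.name}: degenerate response range {lo}..{hi}")
        bad = self.reverse_keyed_items - set(items)
        if bad:
            raise ValidationError(f"{self.name}: reverse-keyed items {sorted(bad)} unknown")
        bad_s = self.inverted_subscales - set(self.subscales)
        if bad_s:
            raise ValidationError(f"{self.name}: inverted subscales {sorted(bad_s)} unknown")


def _block(start: int, k: int) -> tuple[int, ...]:
    return tuple(range(start, start + k))


def default_specs() -> dict[str, InstrumentSpec]:
    """Bundled default item maps for the four instruments."""
    specs = {
        "UPPS": InstrumentSpec(
            name="UPPS",
            response_range=(1, 4),
            subscales={
                "negative_urgency": _block(1, 4),
                "lack_premeditation": _block(5, 4),
                "lack_perseverance": _block(9, 4),
                "sensation_seeking": _block(13, 4),
                "positive_urgency": _block(17, 4),
            },
            inverted_subscales=frozenset(
                {"negative_urgency", "positive_urgency", "sensation_seeking"}
            ),
        ),
        "OCDUS": InstrumentSpec(
            name="OCDUS",
            response_range=(1, 7),
            subscales={
                "thought_interference": (1, 2, 3, 4, 5, 7),
                "desire_control": (8, 9, 10, 11),
                "resistance": (6, 12),
            },
            reverse_keyed_items=frozenset({6, 12}),
        ),
        "PSI": InstrumentSpec(
            name="PSI",
            response_range=(0, 4),
            subscales={
                "behavioral_control": _block(1, 8),
                "emotional_control": _block(9, 7),
                "social_behavior": _block(16, 5),
                "total": _block(1, 20),
            },
        ),
        "MULTICAGE": InstrumentSpec(
            name="MULTICAGE",
            response_range=(0, 1),
            subscales={
                "internet": _block(1, 4),
                "cell_phone": _block(5, 4),
                "videogames": _block(9, 4),
                "instant_messaging": _block(13, 4),
                "social_networks": _block(17, 4),
                "total": _block(1, 20),
            },
        ),
    }
    for s in specs.values():
        s.validate()
    return specs


def load_specs(path) -> dict[str, InstrumentSpec]:
    """Read instrument specs from a YAML file, falling back to defaults.

    The YAML maps instrument name to ``{response_range: [lo, hi],
    subscales: {name: [items]}, reverse_keyed_items: [...],
    inverted_subscales: [...]}``; instruments absent from the file keep
    their bundled defaults.
    """
    specs = default_specs()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for name, cfg in raw.items():
        base = specs.get(name)
        spec = InstrumentSpec(
            name=name,
            response_range=tuple(cfg.get("response_range", base.response_range if base else (0, 1))),
            subscales={k: tuple(v) for k, v in cfg["subscales"].items()}
            if "subscales" in cfg
            else dict(base.subscales),
            reverse_keyed_items=frozenset(
                cfg.get(
                    "reverse_keyed_items",
                    base.reverse_keyed_items if base else frozenset(),
                )
            ),
            inverted_subscales=frozenset(
                cfg.get(
                    "inverted_subscales",
                    base.inverted_subscales if base else frozenset(),
                )
            ),
        )
        spec.validate()
        specs[name] = spec
    return specs


def reverse_item(x, lo: int, hi: int):
    """Item-level reverse keying: x -> lo + hi - x (an involution)."""
    return lo + hi - x


def invert_scale(s, lo: int, hi: int):
    """Scale-level score inversion on the theoretical range [lo, hi]."""
    return lo + hi - s


def _validate_long(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    required = {"subject_id", "instrument", "item", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise ValidationError(f"response table lacks columns {sorted(missing)}")
    sub = responses[responses["instrument"] == spec.name]
    if sub.empty:
        raise ValidationError(f"no rows for instrument {spec.name}")
    lo, hi = spec.response_range
    resp = sub["response"]
    bad = sub[(resp < lo) | (resp > hi) | (resp != resp.round())]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"{spec.name}: out-of-range response {row['response']!r} "
            f"for subject {row['subject_id']!r}, item {int(row['item'])}"
        )
    counts = sub.groupby(["subject_id", "item"]).size()
    dups = counts[counts > 1]
    if not dups.empty:
        sid, item = dups.index[0]
        raise ValidationError(f"{spec.name}: duplicate item {int(item)} for subject {sid!r}")
    wide = sub.pivot(index="subject_id", columns="item", values="response")
    expected = set(spec.items)
    for sid, row in wide.iterrows():
        got = set(row.dropna().index)
        lost = expected - got
        if lost:
            raise ValidationError(
                f"{spec.name}: subject {sid!r} missing item {sorted(lost)[0]}"
            )
    extra = set(wide.columns) - expected
    if extra:
        raise ValidationError(f"{spec.name}: unknown items {sorted(extra)}")
    return wide.astype(int)


def score_instrument(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Score one instrument from a long-format item response table.

    Returns a wide frame indexed by ``subject_id`` with one column per
    subscale named ``{instrument}_{subscale}`` plus ``{instrument}_total``
    (sum over the named subscales, after reverse keys and inversions), at
    stage ``raw`` (``df.attrs['stage']``).
    """
    spec.validate()
    wide = _validate_long(responses, spec)
    lo, hi = spec.response_range
    keyed = wide.copy()
    for it in spec.reverse_keyed_items:
        keyed[it] = reverse_item(keyed[it], lo, hi)

    out = pd.DataFrame(index=wide.index)
    real_subscales = [s for s in spec.subscales if s != "total"]
    for name in real_subscales:
        items = list(spec.subscales[name])
        score = keyed[items].sum(axis=1)
        if name in spec.inverted_subscales:
            s_lo, s_hi = spec.subscale_range(name)
            score = invert_scale(score, s_lo, s_hi)
        out[f"{spec.name}_{name}"] = score
    out[f"{spec.name}_total"] = out[[f"{spec.name}_{s}" for s in real_subscales]].sum(axis=1)
    if "total" in spec.subscales and set(spec.subscales["total"]) != set(spec.items):
        # a partial 'total' pseudo-subscale would silently misreport
        raise ValidationError(f"{spec.name}: 'total' must span all items")
    out.attrs["stage"] = "raw"
    return out


def score_multicage(
    responses: pd.DataFrame, spec: InstrumentSpec | None = None
) -> pd.DataFrame:
    """Score MULTICAGE-ICT: per-scale yes-counts, percents and addiction flags.

    A scale is flagged when its endorsement reaches 50% of the maximum
    (i.e. >= 2 of 4 yes answers), the screening threshold for possible
    addiction signs. Returns columns ``MULTICAGE_{scale}`` (count),
    ``MULTICAGE_{scale}_pct`` and ``MULTICAGE_{scale}_flag`` for the five
    scales plus ``MULTICAGE_total`` / ``_pct`` / ``_flag``.
    """
    if spec is None:
        spec = default_specs()["MULTICAGE"]
    if spec.response_range != (0, 1):
        raise ValidationError("MULTICAGE responses must be dichotomous 0/1")
    wide = _validate_long(responses, spec)
    out = pd.DataFrame(index=wide.index)
    for name, items in spec.subscales.items():
        count = wide[list(items)].sum(axis=1)
        pct = count / len(items) * 100.0
        out[f"MULTICAGE_{name}"] = count
        out[f"MULTICAGE_{name}_pct"] = pct
        out[f"MULTICAGE_{name}_flag"] = pct >= 50.0
    out.attrs["stage"] = "raw"
    return out


def score_battery(
    responses: pd.DataFrame, specs: dict[str, InstrumentSpec] | None = None
) -> pd.DataFrame:
    """Score UPPS, OCDUS and PSI and join MULTICAGE counts/percents/flags."""
    if specs is None:
        specs = default_specs()
    parts = [score_instrument(responses, specs[n]) for n in ("UPPS", "OCDUS", "PSI")]
    parts.append(score_multicage(responses, specs["MULTICAGE"]))
    scores = pd.concat(parts, axis=1)
    if scores.isna().any().any():
        raise ValidationError("instruments cover different subject sets")
    scores.attrs["stage"] = "raw"
    return scores


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (n-1) sample variances over subjects (rows).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 items")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 subjects")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedResultError("zero variance of item sums: alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


def long_from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide response table to the long format.

    Wide columns are named ``{INSTRUMENT}_{item:02d}`` (e.g. ``UPPS_01``,
    ``OCDUS_12``); the index (or a ``subject_id`` column) identifies the
    subject. Returns columns subject_id, instrument, item, response.
    """
    df = wide.copy()
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    records = []
    for col in df.columns:
        try:
            instrument, item = col.rsplit("_", 1)
            item = int(item)
        except ValueError as exc:
            raise ValidationError(f"cannot parse wide column name {col!r}") from exc
        for sid, val in df[col].items():
            records.append((sid, instrument, item, val))
    out = pd.DataFrame(records, columns=["subject_id", "instrument", "item", "response"])
    return out
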