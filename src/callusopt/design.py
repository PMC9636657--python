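"""Design space, tabular schema, feature encoding and the induction-speed rate.

The experiment is a full factorial over four discrete factors:

* 8 hormone treatments (combinations of the auxins 2,4-D and NAA with the
  cytokinins BAP and kinetin, in mg/l; treatment 8 is hormone-free),
* 4 explant types (leaf, nodal segment, root, shoot),
* 3 strengths of Murashige–Skoog basal medium (1x, 4x, 8x minerals),
* 2 sampling days (8 and 25 days after plating),

for 8 x 4 x 3 x 2 = 192 culture conditions.  Each condition is scored on 24
replicate explant pieces, allocated to 3 sub-sets of 8, and summarised as a
callus-induction percentage, a mean callus diameter (mm, over callused pieces
only) and a derived induction-speed value.

Replicate data are carried as pandas DataFrames in a fixed CSV dialect
(``RAW_COLUMNS`` / ``SUMMARY_COLUMNS``); conditions are encoded for modelling
as 10-dimensional numeric vectors (four hormone concentrations, MS multiplier,
sampling day, explant one-hot block).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Factor levels
# ---------------------------------------------------------------------------

EXPLANTS: tuple[str, ...] = ("leaf", "nodal", "root", "shoot")
MS_LEVELS: tuple[int, ...] = (1, 4, 8)
SAMPLING_DAYS: tuple[int, ...] = (8, 25)
TREATMENT_IDS: tuple[int, ...] = tuple(range(1, 9))

N_CONDITIONS = len(TREATMENT_IDS) * len(EXPLANTS) * len(MS_LEVELS) * len(SAMPLING_DAYS)

RAW_COLUMNS = [
    "treatment_id",
    "explant",
    "ms_level",
    "sampling_day",
    "subset_id",
    "replicate_id",
    "callus",
    "diameter_mm",
]

SUMMARY_COLUMNS = [
    "treatment_id",
    "explant",
    "ms_level",
    "sampling_day",
    "n",
    "induction_pct",
    "mean_diameter_mm",
    "speed",
]

CONDITION_COLUMNS = ["treatment_id", "explant", "ms_level", "sampling_day"]

FEATURE_NAMES = [
    "conc_24d",
    "conc_bap",
    "conc_kin",
    "conc_naa",
    "ms_multiplier",
    "sampling_day",
    "explant_leaf",
    "explant_nodal",
    "explant_root",
    "explant_shoot",
]

#: Semantic feature groups used by the variable-sensitivity analysis.
FEATURE_GROUPS: dict[str, list[int]] = {
    "pgr": [0, 1, 2, 3],
    "ms": [4],
    "day": [5],
    "explant": [6, 7, 8, 9],
}


class SchemaError(ValueError):
    """A raw-data row violates the tabular schema (bad value or column)."""


# ---------------------------------------------------------------------------
# Treatments (hormone combinations)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Treatment:
    """One plant-growth-regulator combination (concentrations in mg/l)."""

    id: int
    conc_24d: float
    conc_bap: float
    conc_kin: float
    conc_naa: float

    def concentrations(self) -> tuple[float, float, float, float]:
        return (self.conc_24d, self.conc_bap, self.conc_kin, self.conc_naa)


def load_treatments() -> dict[int, Treatment]:
    """Return the 8 packaged hormone treatments keyed by id.

    Treatment 8 is the hormone-free control; every concentration is >= 0.
    """
    path = importlib.resources.files("callusopt.data") / "treatments.csv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    table = {
        int(r.treatment_id): Treatment(
            int(r.treatment_id),
            float(r.conc_24d),
            float(r.conc_bap),
            float(r.conc_kin),
            float(r.conc_naa),
        )
        for r in df.itertuples()
    }
    ids = tuple(sorted(table))
    if ids != TREATMENT_IDS:
        raise SchemaError(f"treatment table must contain ids 1..8, got {ids}")
    if any(c < 0 for t in table.values() for c in t.concentrations()):
        raise SchemaError("negative hormone concentration in treatment table")
    if table[8].concentrations() != (0.0, 0.0, 0.0, 0.0):
        raise SchemaError("treatment 8 must be hormone-free")
    return table


TREATMENTS: dict[int, Treatment] = load_treatments()


# ---------------------------------------------------------------------------
# Conditions and feature encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CultureCondition:
    """One point of the 192-point factorial design."""

    treatment_id: int
    explant: str
    ms_level: int
    sampling_day: int

    def __post_init__(self) -> None:
        if self.treatment_id not in TREATMENT_IDS:
            raise SchemaError(f"unknown treatment id {self.treatment_id!r}")
        if self.explant not in EXPLANTS:
            raise SchemaError(f"unknown explant {self.explant!r}")
        if self.ms_level not in MS_LEVELS:
            raise SchemaError(f"unknown MS level {self.ms_level!r}")
        if self.sampling_day not in SAMPLING_DAYS:
            raise SchemaError(f"unknown sampling day {self.sampling_day!r}")

    def as_tuple(self) -> tuple[int, str, int, int]:
        return (self.treatment_id, self.explant, self.ms_level, self.sampling_day)


def full_grid() -> list[CultureCondition]:
    """All 192 conditions in a fixed (ms, treatment, explant, day) order.

    1x-MS rows come first so that, where response values tie, row-order
    argmax-style reductions resolve to the natural-strength medium.
    """
    return [
        CultureCondition(t, e, m, d)
        for m in MS_LEVELS
        for t in TREATMENT_IDS
        for e in EXPLANTS
        for d in SAMPLING_DAYS
    ]


def encode_condition(
    condition: CultureCondition,
    treatments: Mapping[int, Treatment] | None = None,
) -> np.ndarray:
    """Encode a condition as the 10-vector used by the surrogate models.

    Layout: (2,4-D, BAP, Kin, NAA concentrations in mg/l, MS multiplier,
    sampling day, one-hot explant block in leaf/nodal/root/shoot order).
    """
    treatments = TREATMENTS if treatments is None else treatments
    try:
        t = treatments[condition.treatment_id]
    except KeyError as exc:
        raise SchemaError(f"treatment id {condition.treatment_id} not in table") from exc
    onehot = [1.0 if condition.explant == e else 0.0 for e in EXPLANTS]
    return np.array(
        [*t.concentrations(), float(condition.ms_level), float(condition.sampling_day), *onehot]
    )


def decode_features(
    x: Sequence[float], treatments: Mapping[int, Treatment] | None = None
) -> CultureCondition:
    """Invert :func:`encode_condition` on the 192-point grid."""
    treatments = TREATMENTS if treatments is None else treatments
    x = np.asarray(x, dtype=float)
    if x.shape != (10,):
        raise SchemaError(f"feature vector must have length 10, got shape {x.shape}")
    conc = tuple(x[:4])
    matches = [t.id for t in treatments.values() if np.allclose(t.concentrations(), conc)]
    if not matches:
        raise SchemaError(f"no treatment with concentrations {conc}")
    onehot = x[6:]
    if not (np.isin(onehot, (0.0, 1.0)).all() and onehot.sum() == 1):
        raise SchemaError("explant indicators must be one-hot")
    explant = EXPLANTS[int(np.argmax(onehot))]
    return CultureCondition(matches[0], explant, int(x[4]), int(x[5]))


def encode_frame(df: pd.DataFrame) -> np.ndarray:
    """Vectorised encoding of the condition columns of a DataFrame -> (n, 10)."""
    return np.stack(
        [
            encode_condition(CultureCondition(int(t), e, int(m), int(d)))
            for t, e, m, d in zip(
                df["treatment_id"], df["explant"], df["ms_level"], df["sampling_day"]
            )
        ]
    )


# ---------------------------------------------------------------------------
# Induction speed
# ---------------------------------------------------------------------------

SPEED_MODES = ("as_written", "inverted")


def compute_speed(sampling_day: float, mean_diameter: float, mode: str = "as_written") -> float:
    """Speed of callus induction derived from sampling day and mean diameter.

    ``as_written`` (default) is sampling time divided by mean callus diameter
    (day/mm); ``inverted`` is the physically conventional growth rate,
    diameter divided by time (mm/day).  A condition with no callus
    (``mean_diameter == 0``) has speed 0 in both modes so that every condition
    has a well-defined outcome.
    """
    if mode not in SPEED_MODES:
        raise ValueError(f"speed mode must be one of {SPEED_MODES}, got {mode!r}")
    if sampling_day <= 0:
        raise ValueError(f"sampling day must be positive, got {sampling_day}")
    if mean_diameter < 0:
        raise ValueError(f"mean diameter must be >= 0, got {mean_diameter}")
    if mean_diameter == 0:
        return 0.0
    if mode == "as_written":
        return sampling_day / mean_diameter
    return mean_diameter / sampling_day


# ---------------------------------------------------------------------------
# Raw replicate table I/O and validation
# ---------------------------------------------------------------------------


def validate_raw(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw replicate table against the schema; returns a typed copy.

    Checks column presence, categorical levels, the no-callus => zero-diameter
    rule and the 1–3 sub-set range, naming the offending row and column in
    every error.
    """
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[RAW_COLUMNS].copy()
    for col, allowed in (
        ("treatment_id", TREATMENT_IDS),
        ("explant", EXPLANTS),
        ("ms_level", MS_LEVELS),
        ("sampling_day", SAMPLING_DAYS),
        ("subset_id", (1, 2, 3)),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}, column {col!r}: value {df[col].iloc[row]!r} "
                f"not in allowed set {tuple(allowed)}"
            )
    df["callus"] = df["callus"].astype(int)
    if not df["callus"].isin((0, 1)).all():
        row = int(np.flatnonzero(~df["callus"].isin((0, 1)).to_numpy())[0])
        raise SchemaError(f"row {row}, column 'callus': must be 0/1")
    if df["diameter_mm"].isna().any():
        row = int(np.flatnonzero(df["diameter_mm"].isna().to_numpy())[0])
        raise SchemaError(f"row {row}, column 'diameter_mm': missing diameter")
    df["diameter_mm"] = df["diameter_mm"].astype(float)
    if (df["diameter_mm"] < 0).any():
        row = int(np.flatnonzero((df["diameter_mm"] < 0).to_numpy())[0])
        raise SchemaError(f"row {row}, column 'diameter_mm': negative diameter")
    viol = (df["callus"] == 0) & (df["diameter_mm"] != 0)
    if viol.any():
        row = int(np.flatnonzero(viol.to_numpy())[0])
        raise SchemaError(f"row {row}: callus=0 requires diameter_mm=0")
    for col in ("treatment_id", "ms_level", "sampling_day", "subset_id", "replicate_id"):
        df[col] = df[col].astype(int)
    return df


def load_raw_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a raw replicate CSV, optionally renaming user columns via ``schema``
    (a mapping from canonical name to the file's column name)."""
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_raw(df)


def save_raw_table(df: pd.DataFrame, path) -> None:
    validate_raw(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------


def summarize_conditions(records: pd.DataFrame, speed_mode: str = "as_written") -> pd.DataFrame:
    """Collapse replicate records to one row per condition.

    induction_pct is 100 x (callused replicates / n); mean diameter averages
    over callused replicates only (0 when none); speed comes from
    :func:`compute_speed`.  Empty input yields an empty frame.
    """
    records = validate_raw(records) if len(records) else records
    rows = []
    if len(records):
        grouped = records.groupby(CONDITION_COLUMNS, sort=True)
        for (t, e, m, d), g in grouped:
            n = len(g)
            n_callus = int(g["callus"].sum())
            pct = 100.0 * n_callus / n
            diam = float(g.loc[g["callus"] == 1, "diameter_mm"].mean()) if n_callus else 0.0
            rows.append(
                {
                    "treatment_id": int(t),
                    "explant": e,
                    "ms_level": int(m),
                    "sampling_day": int(d),
                    "n": n,
                    "induction_pct": pct,
                    "mean_diameter_mm": diam,
                    "speed": compute_speed(float(d), diam, speed_mode),
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def summary_features(summaries: pd.DataFrame) -> np.ndarray:
    """Feature matrix (n, 10) for a condition-summary table."""
    return encode_frame(summaries)


def summary_target(summaries: pd.DataFrame, target: str) -> np.ndarray:
    """Target vector for ``target`` in {"percentage", "speed"}."""
    if target == "percentage":
        return summaries["induction_pct"].to_numpy(dtype=float)
    if target == "speed":
        return summaries["speed"].to_numpy(dtype=float)
    raise ValueError(f"target must be 'percentage' or 'speed', got {target!r}")
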