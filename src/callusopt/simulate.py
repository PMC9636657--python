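"""Synthetic factorial replicate generator emulating the callus-induction study.

The generator draws per-replicate outcomes from a 192-row *effect table*
giving, for every culture condition, the induction probability ``p``, the
expected callus diameter ``mu`` (mm, conditional on induction) and its spread
``sigma``.  The default table encodes the study's reported outcome structure:

* 8x MS medium suppresses callus completely (p = 0 everywhere);
* 4x MS is all-or-nothing: treatments 5-7 induce on every explant (p = 1),
  treatments 1, 2, 4 and the hormone-free control 8 never do (p = 0);
* at 1x MS the response is graded, with shoot explants strongest in media
  1, 2, 5, 6, 7, nodal strongest in 2-6 and weakest in 1 and 7, and the
  global optimum at (shoot, 1x MS, treatment 6 = 0.5 mg/l 2,4-D + 0.5 mg/l
  BAP) on day 25.

Only the 0%/100% extremes and the orderings above are reported outcomes; the
intermediate 1x-MS probabilities and all diameter parameters are modelling
choices (see docs/methods.md) chosen to respect those orderings, to make
leaf explants at 1x MS / treatment 6 / day 8 the fastest-growing condition,
and to give leaf and root pieces in treatment 4 the smallest (hence, on the
time/diameter scale, "fastest") calli.

Between-sub-set heterogeneity is a logit-normal random effect on p; replicate
diameters are zero-truncated normal.  Conditions with p exactly 0 or 1 are
deterministic (no sub-set noise), so their summarised induction percentage is
exactly 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .design import (
    RAW_COLUMNS,
    SUMMARY_COLUMNS,
    TREATMENT_IDS,
    compute_speed,
    full_grid,
)

EFFECT_COLUMNS = [
    "treatment_id",
    "explant",
    "ms_level",
    "sampling_day",
    "p_induction",
    "mu_diameter_mm",
    "sigma_diameter_mm",
]

# Induction probability at 1x MS on day 25, by explant x treatment.
# Stated orderings from the study are honoured; the numeric values of the
# unreported cells are free generator parameters.
_P25_1X = {
    #         t1    t2    t3    t4    t5    t6    t7    t8
    "leaf":  (0.40, 0.50, 0.50, 0.60, 0.65, 0.75, 0.40, 0.0),
    "nodal": (0.15, 0.80, 0.80, 0.80, 0.80, 0.80, 0.15, 0.0),
    "root":  (0.45, 0.50, 0.50, 0.60, 0.60, 0.70, 0.45, 0.0),
    "shoot": (0.78, 0.80, 0.60, 0.70, 0.88, 1.00, 0.76, 0.0),
}

# Expected callus diameter (mm) at 1x MS on day 25 given induction.
# Treatment 6 grows the largest calli (leaf > shoot); treatment 4 the
# smallest on leaf/root.  Day-8 diameters are a fixed fraction of these.
_MU25_1X = {
    #         t1   t2   t3   t4   t5   t6   t7   t8
    "leaf":  (3.6, 4.2, 4.2, 2.0, 5.0, 6.5, 3.8, 0.0),
    "nodal": (2.5, 3.0, 3.0, 3.0, 3.2, 3.4, 2.5, 0.0),
    "root":  (3.0, 3.2, 3.2, 2.0, 3.4, 3.6, 3.0, 0.0),
    "shoot": (3.4, 3.4, 3.0, 3.2, 3.8, 4.8, 3.4, 0.0),
}

# 4x MS: treatments 5-7 induce everywhere; diameters modest, largest for
# root pieces in treatment 5.  Treatment 3 (1 mg/l 2,4-D) is unreported at
# 4x and given an intermediate probability.
_P25_4X = {t: 0.0 for t in TREATMENT_IDS} | {3: 0.30, 5: 1.0, 6: 1.0, 7: 1.0}
_MU25_4X = {
    "leaf":  {3: 2.0, 5: 2.8, 6: 3.0, 7: 2.6},
    "nodal": {3: 2.0, 5: 2.6, 6: 2.8, 7: 2.4},
    "root":  {3: 2.0, 5: 3.0, 6: 2.8, 7: 2.6},
    "shoot": {3: 2.0, 5: 2.8, 6: 2.8, 7: 2.6},
}

_DAY8_P_FACTOR = 0.85     # induction seen by day 8 relative to day 25
_DAY8_MU_FACTOR = 0.55    # diameter reached by day 8 relative to day 25
_SIGMA_MM = 0.6           # replicate diameter spread where callus forms
_P8_SHOOT_T6 = 0.90       # day-8 probability at the (clamped) 1x optimum


def default_effect_table() -> pd.DataFrame:
    """The packaged 192-row effect table emulating the study's outcomes."""
    rows = []
    for c in full_grid():
        if c.ms_level == 8:
            p25, mu25 = 0.0, 0.0
        elif c.ms_level == 4:
            p25 = _P25_4X[c.treatment_id]
            mu25 = _MU25_4X[c.explant].get(c.treatment_id, 0.0) if p25 > 0 else 0.0
        else:
            p25 = _P25_1X[c.explant][c.treatment_id - 1]
            mu25 = _MU25_1X[c.explant][c.treatment_id - 1]
        if c.sampling_day == 25 or p25 in (0.0, 1.0) and c.ms_level == 4:
            # 4x-MS extremes are clamped at both sampling days
            p, mu = p25, mu25 if c.sampling_day == 25 else mu25 * _DAY8_MU_FACTOR
        else:
            if c.explant == "shoot" and c.treatment_id == 6 and c.ms_level == 1:
                p = _P8_SHOOT_T6
            else:
                p = _DAY8_P_FACTOR * p25
            mu = mu25 * _DAY8_MU_FACTOR
        if p == 0.0:
            mu = 0.0
        rows.append(
            {
                "treatment_id": c.treatment_id,
                "explant": c.explant,
                "ms_level": c.ms_level,
                "sampling_day": c.sampling_day,
                "p_induction": p,
                "mu_diameter_mm": mu,
                "sigma_diameter_mm": _SIGMA_MM if mu > 0 else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    _validate_effect_table(table)
    return table


def _validate_effect_table(table: pd.DataFrame) -> None:
    missing = [c for c in EFFECT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"effect table missing columns: {missing}")
    p = table["p_induction"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_induction must lie in [0, 1]")
    if (table["mu_diameter_mm"] < 0).any() or (table["sigma_diameter_mm"] < 0).any():
        raise ValueError("diameter parameters must be >= 0")
    if ((p == 0) & (table["mu_diameter_mm"] > 0)).any():
        raise ValueError("p_induction = 0 requires mu_diameter_mm = 0")


@dataclass
class GeneratorConfig:
    """Configuration of one simulated factorial experiment.

    ``subset_effect_sd`` is the logit-scale standard deviation of the
    between-sub-set random effect on the induction probability (0.3 by
    default; conditions at p = 0 or 1 are unaffected).
    """

    seed: int = 0
    n_replicates: int = 24
    n_subsets: int = 3
    subset_effect_sd: float = 0.3
    effect_table: pd.DataFrame = field(default_factory=default_effect_table)

    def __post_init__(self) -> None:
        if self.n_replicates <= 0 or self.n_subsets <= 0:
            raise ValueError("replicate and sub-set counts must be positive")
        if self.n_replicates % self.n_subsets:
            raise ValueError(
                f"n_replicates ({self.n_replicates}) must be divisible by "
                f"n_subsets ({self.n_subsets})"
            )
        if self.subset_effect_sd < 0:
            raise ValueError("subset_effect_sd must be >= 0")
        _validate_effect_table(self.effect_table)


def simulate_experiment(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw one full replicate table (one row per explant piece).

    Per condition and sub-set, the induction probability is
    ``expit(logit(p) + e)`` with ``e ~ N(0, subset_effect_sd)``; p = 0 and
    p = 1 are clamped (no noise, deterministic outcome).  Callus presence is
    Bernoulli; diameters of callused pieces are Normal(mu, sigma) truncated
    at 0.  A fixed seed reproduces the table bit-exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    per_subset = cfg.n_replicates // cfg.n_subsets
    table = cfg.effect_table.set_index(
        ["treatment_id", "explant", "ms_level", "sampling_day"]
    )
    out = {c: [] for c in RAW_COLUMNS}
    for cond in full_grid():
        p, mu, sigma = table.loc[cond.as_tuple()]
        rep = 0
        for s in range(1, cfg.n_subsets + 1):
            if p in (0.0, 1.0):
                p_s = p
            else:
                p_s = float(expit(logit(p) + rng.normal(0.0, cfg.subset_effect_sd)))
            callus = rng.random(per_subset) < p_s
            if sigma > 0:
                diam = truncnorm.rvs(
                    -mu / sigma, np.inf, loc=mu, scale=sigma,
                    size=per_subset, random_state=rng,
                )
            else:
                diam = np.full(per_subset, mu)
            diam = np.where(callus, diam, 0.0)
            for k in range(per_subset):
                rep += 1
                out["treatment_id"].append(cond.treatment_id)
                out["explant"].append(cond.explant)
                out["ms_level"].append(cond.ms_level)
                out["sampling_day"].append(cond.sampling_day)
                out["subset_id"].append(s)
                out["replicate_id"].append(rep)
                out["callus"].append(int(callus[k]))
                out["diameter_mm"].append(float(diam[k]))
    return pd.DataFrame(out, columns=RAW_COLUMNS)


def expected_summaries(
    effect_table: pd.DataFrame | None = None, speed_mode: str = "as_written"
) -> pd.DataFrame:
    """Noise-free condition summaries implied by an effect table.

    Returns the 192-row summary table with induction_pct = 100 p and
    mean diameter mu: the infinite-replicate limit of
    ``summarize_conditions(simulate_experiment(...))``, useful as a
    deterministic regression surface for surrogate-model tests.
    """
    table = default_effect_table() if effect_table is None else effect_table
    _validate_effect_table(table)
    out = table.copy()
    out["n"] = 0
    out["induction_pct"] = 100.0 * out["p_induction"]
    out["mean_diameter_mm"] = out["mu_diameter_mm"]
    out["speed"] = [
        compute_speed(float(d), float(mu), speed_mode)
        for d, mu in zip(out["sampling_day"], out["mu_diameter_mm"])
    ]
    return out[SUMMARY_COLUMNS].reset_index(drop=True)
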