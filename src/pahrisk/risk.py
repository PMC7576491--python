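"""Deterministic inhalation dosimetry: IR, LADD, and ILCR.

Dose model
----------
Inhalation rate is measured by spirometry: IR (m3/day) = TV (L/breath)
x BF (breaths/min) x 1.44, where 1.44 = 1440 min/day / 1000 L/m3.

The lifetime average daily dose of BaP-equivalent exposure is

    LADD = C * EF * ED * CF * IR / (BW * AT)     mg/(kg day)

with C the BaPeq concentration (ng/m3), EF exposure frequency (day/yr),
ED exposure duration (yr), CF = 1e-6 mg/ng, IR inhalation rate (m3/day),
BW body weight (kg), and AT the carcinogenic averaging time (day).

Cancer risk is linear in dose: ILCR = SF * LADD, with SF = 3.14 per
(mg/kg/day), the standard benzo[a]pyrene inhalation slope factor, and
1e-6 the conventional acceptable incremental risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LPM_TO_M3_PER_DAY",
    "ExposureParams",
    "RiskConstants",
    "inhalation_rate",
    "pooled_mean",
    "ladd",
    "ilcr",
    "per_participant_risk",
]

#: (m3 min)/(L day): converts L/min to m3/day.
LPM_TO_M3_PER_DAY = 1.44

NG_PER_KG_DAY_PER_MG = 1e6  # presentation conversion for dose reporting


@dataclass(frozen=True)
class ExposureParams:
    """One parameter set for the LADD formula (units as module docstring)."""

    c: float      # BaPeq ng/m3
    ef: float     # day/year
    ed: float     # year
    cf: float     # mg/ng
    ir: float     # m3/day
    bw: float     # kg
    at: float     # day

    def __post_init__(self):
        for name in ("ef", "ed", "cf", "ir", "bw", "at"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.at < self.ef * self.ed:
            raise ValueError("averaging time must cover the exposure days (AT >= EF*ED)")


@dataclass(frozen=True)
class RiskConstants:
    sf: float = 3.14              # per (mg/kg/day)
    acceptable_risk: float = 1e-6

    def __post_init__(self):
        if self.sf <= 0 or self.acceptable_risk <= 0:
            raise ValueError("SF and acceptable_risk must be positive")


def inhalation_rate(tidal_volume_L, breathing_rate_per_min):
    """IR (m3/day) from tidal volume (L) and breathing frequency (1/min)."""
    tv = np.asarray(tidal_volume_L, dtype=float)
    bf = np.asarray(breathing_rate_per_min, dtype=float)
    if np.any(tv <= 0) or np.any(bf <= 0):
        raise ValueError("tidal volume and breathing rate must be positive")
    out = tv * bf * LPM_TO_M3_PER_DAY
    return float(out) if out.ndim == 0 else out


def pooled_mean(group_means, group_sizes) -> float:
    """Size-weighted pooled mean sum(m_i n_i)/sum(n_i)."""
    m = np.asarray(group_means, dtype=float)
    n = np.asarray(group_sizes, dtype=float)
    if len(m) != len(n):
        raise ValueError("group_means and group_sizes must have equal length")
    if np.any(n <= 0) or n.sum() == 0:
        raise ValueError("group sizes must be positive")
    return float((m * n).sum() / n.sum())


def ladd(params: ExposureParams) -> float:
    """Lifetime average daily dose, mg/(kg day)."""
    p = params
    return p.c * p.ef * p.ed * p.cf * p.ir / (p.bw * p.at)


def ilcr(dose, constants: RiskConstants = RiskConstants()):
    """Incremental lifetime cancer risk SF*LADD and its exceedance flag.

    Returns ``(risk, exceeds)`` where ``exceeds`` is True only for risk
    strictly above the acceptable level.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    risk = constants.sf * d
    exceeds = risk > constants.acceptable_risk
    if risk.ndim == 0:
        return float(risk), bool(exceeds)
    return risk, exceeds


def per_participant_risk(
    participants: pd.DataFrame,
    bapeq_by_participant: pd.Series,
    *,
    ef: float,
    ed: float = 10.0,
    cf: float = 1e-6,
    at: float = 25500.0,
    constants: RiskConstants = RiskConstants(),
):
    """Individual LADD/ILCR for a cohort plus sex-stratified summaries.

    ``bapeq_by_participant`` maps participant_id -> BaPeq exposure
    concentration (ng/m3), typically the participant's personal-sample
    value.  Every participant must be matched (linkage error otherwise).

    Returns ``(individual, strata)``: a per-participant table with
    ``ladd_mg_kg_day``, ``ladd_ng_kg_day``, ``ilcr`` and ``exceeds``, and a
    per-sex summary of mean/min/max ILCR.
    """
    missing = set(participants["participant_id"]) - set(bapeq_by_participant.index)
    if missing:
        raise KeyError(f"no exposure value for participant(s): {sorted(missing)}")

    rows = []
    for _, p in participants.iterrows():
        ir = inhalation_rate(p["tidal_volume_L"], p["breathing_rate_per_min"])
        params = ExposureParams(
            c=float(bapeq_by_participant[p["participant_id"]]),
            ef=ef, ed=ed, cf=cf, ir=ir, bw=float(p["weight_kg"]), at=at,
        )
        dose = ladd(params)
        risk, exceeds = ilcr(dose, constants)
        rows.append({
            "participant_id": p["participant_id"],
            "sex": p["sex"],
            "season": p["season"],
            "ir_m3_day": ir,
            "ladd_mg_kg_day": dose,
            "ladd_ng_kg_day": dose * NG_PER_KG_DAY_PER_MG,
            "ilcr": risk,
            "exceeds_acceptable": exceeds,
        })
    individual = pd.DataFrame(rows)
    strata = (
        individual.groupby("sex")["ilcr"]
        .agg(["count", "mean", "min", "max"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return individual, strata
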