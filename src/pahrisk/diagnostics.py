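"""Isomer-pair diagnostic ratios and threshold-rule source classification.

Isomer pairs of equal molecular weight fractionate differently between
combustion regimes, so the fraction A/(A+B) of an isomer pair carries a
source signature.  Five conventional pairs are computed; classification is
driven by BaA/(BaA+Chr) and IcdP/(IcdP+BghiP):

    BaA/(BaA+Chr):   < 0.2 petroleum | 0.2-0.35 mixed | > 0.35 coal/biomass
    IcdP/(IcdP+BghiP): < 0.2 petroleum | 0.2-0.5 mixed | > 0.5 coal/biomass

Boundary values fall in the closed middle interval.  A ratio whose pair sum
is zero is undefined (NaN) and classified indeterminate — undefined is a
value here, not an error.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "RATIO_PAIRS",
    "diagnostic_ratios",
    "classify_baa",
    "classify_icdp",
    "combined_verdict",
    "source_scatter",
]

#: name -> (numerator congener, other pair member)
RATIO_PAIRS: dict[str, tuple[str, str]] = {
    "baa_over_baa_chr": ("BaA", "Chr"),
    "icdp_over_icdp_bghip": ("IcdP", "BghiP"),
    "ant_over_ant_phe": ("Ant", "Phe"),
    "fla_over_fla_pyr": ("Fla", "Pyr"),
    "bbf_over_bbf_bkf": ("BbF", "BkF"),
}

PETROLEUM = "petroleum"
MIXED = "mixed"
COAL = "coal_or_biomass_combustion"
INDETERMINATE = "indeterminate"


def diagnostic_ratios(sample: pd.Series) -> pd.Series:
    """All five pair ratios A/(A+B) for one sample (row or congener vector).

    Each ratio lies in [0, 1]; NaN flags an undefined ratio (A + B = 0).
    """
    out = {}
    for name, (a, b) in RATIO_PAIRS.items():
        num = float(sample[a])
        den = num + float(sample[b])
        out[name] = num / den if den > 0 else float("nan")
    return pd.Series(out)


def classify_baa(ratio: float) -> str:
    """Source label from BaA/(BaA+Chr)."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return INDETERMINATE
    if not 0 <= ratio <= 1:
        raise ValueError(f"diagnostic ratio must be in [0, 1], got {ratio}")
    if ratio < 0.2:
        return PETROLEUM
    if ratio > 0.35:
        return COAL
    return MIXED


def classify_icdp(ratio: float) -> str:
    """Source label from IcdP/(IcdP+BghiP)."""
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return INDETERMINATE
    if not 0 <= ratio <= 1:
        raise ValueError(f"diagnostic ratio must be in [0, 1], got {ratio}")
    if ratio < 0.2:
        return PETROLEUM
    if ratio > 0.5:
        return COAL
    return MIXED


def combined_verdict(baa_label: str, icdp_label: str) -> str:
    """Joint call from the two classifying ratios.

    Agreement wins; disagreement between two defined labels is mixed; one
    indeterminate defers to the other; both indeterminate stays so.
    """
    if baa_label == INDETERMINATE and icdp_label == INDETERMINATE:
        return INDETERMINATE
    if baa_label == INDETERMINATE:
        return icdp_label
    if icdp_label == INDETERMINATE:
        return baa_label
    if baa_label == icdp_label:
        return baa_label
    return MIXED


def source_scatter(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ratio table for quadrant-style source scatter plots.

    One row per input sample with the two classifying ratios, their labels,
    and the combined verdict; rows with undefined ratios are retained and
    flagged (NaN ratio, indeterminate label).
    """
    rows = []
    for _, s in samples.iterrows():
        r = diagnostic_ratios(s)
        baa = float(r["baa_over_baa_chr"])
        icdp = float(r["icdp_over_icdp_bghip"])
        baa_label = classify_baa(baa)
        icdp_label = classify_icdp(icdp)
        rows.append({
            "sample_id": s["sample_id"],
            "season": s["season"],
            "sampler_kind": s["sampler_kind"],
            "baa_ratio": baa,
            "icdp_ratio": icdp,
            "baa_label": baa_label,
            "icdp_label": icdp_label,
            "verdict": combined_verdict(baa_label, icdp_label),
        })
    cols = ["sample_id", "season", "sampler_kind", "baa_ratio", "icdp_ratio",
            "baa_label", "icdp_label", "verdict"]
    return pd.DataFrame(rows, columns=cols)
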