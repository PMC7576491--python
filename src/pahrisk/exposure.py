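"""BaP-equivalent exposure, seasonal summaries, I/O ratios, and the study's
standard statistical comparisons.

The central quantity is the BaP-equivalent concentration

    BaPeq = sum_i C_i * TEF_i      (ng/m3)

which collapses a congener mixture into a single carcinogenicity-weighted
concentration against the benzo[a]pyrene reference.  Seasonal summaries use
the sample standard deviation (n-1); indoor/outdoor source attribution
follows the threshold rule: ratio > 1 implies an indoor source, < 1 an
outdoor source, exactly 1 (or undefined) is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .congeners import CongenerRegistry, TefTable, load_registry
from .io import filter_valid_personal

__all__ = [
    "BapEqResult",
    "SeasonSummary",
    "bap_equivalent",
    "bapeq_per_sample",
    "season_summary",
    "season_ratio",
    "io_ratio",
    "compare_groups",
    "correlate",
]


@dataclass(frozen=True)
class BapEqResult:
    """Total BaPeq with per-congener contributions and shares (ng/m3)."""

    total: float
    contributions: pd.Series  # ng/m3, indexed by abbreviation
    shares: pd.Series | None  # fractions summing to 1; None when total == 0

    @property
    def defined(self) -> bool:
        return self.shares is not None


@dataclass(frozen=True)
class SeasonSummary:
    """Moments of the personal-exposure metrics for one season.

    ``sd`` entries are NaN for n = 1 (sample sd undefined).  The PAH-to-PM
    mass fraction is mean(sum PAH)/mean(PM2.5), dimensionless, carried in
    the units as printed by the study without reinterpretation.
    """

    season: str
    n: int
    stats: pd.DataFrame  # rows: metric; cols: mean, sd, min, max
    pah_to_pm_fraction: float
    shapiro_p_log: float | None = None  # Shapiro-Wilk p on log(sum PAH)

    def mean(self, metric: str) -> float:
        return float(self.stats.loc[metric, "mean"])


def bap_equivalent(
    concentrations: pd.Series,
    tefs: TefTable | None = None,
    registry: CongenerRegistry | None = None,
) -> BapEqResult:
    """Compute BaPeq = sum C_i * TEF_i for one per-congener vector.

    ``concentrations`` must be indexed by the registry abbreviations
    (any order, no extras, no gaps); negative values are rejected.
    """
    registry = registry or load_registry()
    tefs = tefs or registry.tef_table()
    expected = set(registry.abbreviations)
    if set(concentrations.index) != expected:
        raise ValueError(
            "concentration vector not aligned to registry: "
            f"missing {sorted(expected - set(concentrations.index))}, "
            f"extra {sorted(set(concentrations.index) - expected)}"
        )
    conc = concentrations.reindex(registry.abbreviations).astype(float)
    if (conc < 0).any():
        raise ValueError("negative concentration in BaPeq input")
    tef_vec = pd.Series({a: tefs[a] for a in registry.abbreviations})
    contributions = conc * tef_vec
    total = float(contributions.sum())
    shares = contributions / total if total > 0 else None
    return BapEqResult(total=total, contributions=contributions, shares=shares)


def bapeq_per_sample(
    samples: pd.DataFrame,
    tefs: TefTable | None = None,
    registry: CongenerRegistry | None = None,
) -> pd.Series:
    """Total BaPeq (ng/m3) for every row of a samples table."""
    registry = registry or load_registry()
    tefs = tefs or registry.tef_table()
    tef_vec = np.array([tefs[a] for a in registry.abbreviations])
    conc = samples[registry.abbreviations].to_numpy(dtype=float)
    return pd.Series(conc @ tef_vec, index=samples.index, name="bapeq")


def season_summary(
    samples: pd.DataFrame,
    season: str,
    registry: CongenerRegistry | None = None,
    tefs: TefTable | None = None,
    *,
    check_lognormality: bool = False,
) -> SeasonSummary:
    """Summarize valid personal samples of one season.

    Moments (mean, sample sd, min, max) of the total PAH concentration,
    PM2.5, BaP, and total BaPeq; optionally a Shapiro-Wilk normality p-value
    on the log-transformed total PAH (the study's lognormality check).
    """
    registry = registry or load_registry()
    valid = filter_valid_personal(samples)
    sub = valid[(valid["season"] == season) & (valid["sampler_kind"] == "personal")]
    if sub.empty:
        raise ValueError(f"no valid personal samples for season {season!r}")

    total_pah = sub[registry.abbreviations].sum(axis=1)
    metrics = {
        "total_pah": total_pah,
        "pm25": sub["pm25"],
        "BaP": sub["BaP"],
        "bapeq": bapeq_per_sample(sub, tefs, registry),
    }
    rows = {}
    for name, vals in metrics.items():
        v = vals.to_numpy(dtype=float)
        rows[name] = {
            "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            "min": v.min(),
            "max": v.max(),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")

    shapiro_p = None
    if check_lognormality:
        logged = np.log(total_pah[total_pah > 0].to_numpy(dtype=float))
        shapiro_p = float(stats.shapiro(logged).pvalue) if len(logged) >= 3 else np.nan

    return SeasonSummary(
        season=season,
        n=len(sub),
        stats=table,
        pah_to_pm_fraction=float(total_pah.mean() / sub["pm25"].mean()),
        shapiro_p_log=shapiro_p,
    )


def season_ratio(summary_a: SeasonSummary, summary_b: SeasonSummary,
                 metric: str = "total_pah") -> float:
    """Fold change mean_a(metric)/mean_b(metric) between two seasons.

    ``metric`` may also be ``"pah_to_pm_fraction"``.  Returns NaN when the
    denominator is zero (undefined-flagged, not an error).
    """
    if metric == "pah_to_pm_fraction":
        a, b = summary_a.pah_to_pm_fraction, summary_b.pah_to_pm_fraction
    else:
        a, b = summary_a.mean(metric), summary_b.mean(metric)
    if b == 0:
        return float("nan")
    return float(a / b)


def io_ratio(
    indoor: pd.Series,
    outdoor: pd.Series,
    registry: CongenerRegistry | None = None,
) -> pd.DataFrame:
    """Per-congener indoor/outdoor concentration ratios with source calls.

    Input series are per-congener concentration vectors (or sample rows, from
    which the congener columns are taken).  Returns a DataFrame indexed by
    abbreviation with ``ratio`` and ``call`` columns; call is
    ``indoor_source`` (ratio > 1), ``outdoor_source`` (ratio < 1), or
    ``indeterminate`` (ratio exactly 1, or 0/0 and c/0 cases, flagged NaN).
    """
    registry = registry or load_registry()
    abbr = registry.abbreviations
    cin = indoor.reindex(abbr).astype(float)
    cout = outdoor.reindex(abbr).astype(float)
    if cin.isna().any() or cout.isna().any():
        raise ValueError("indoor/outdoor vectors must cover every registry congener")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cin / cout
    ratio[cout == 0] = np.nan
    call = pd.Series("indeterminate", index=abbr)
    call[ratio > 1] = "indoor_source"
    call[ratio < 1] = "outdoor_source"
    return pd.DataFrame({"ratio": ratio, "call": call})


def compare_groups(values_a, values_b, *, paired: bool = False):
    """Two-sided t-test between groups: Welch when unpaired, paired otherwise.

    Returns ``(statistic, pvalue)``.  A paired comparison with zero variance
    of differences (e.g. identical vectors) returns ``(nan, nan)`` rather
    than a spurious zero statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        if len(a) < 2:
            raise ValueError("need n >= 2 per group")
        if np.std(a - b, ddof=1) == 0:
            return float("nan"), float("nan")
        res = stats.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def correlate(values_a, values_b):
    """Pearson correlation with two-sided p-value.

    Constant input yields ``(nan, nan)`` (undefined-flagged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("correlate requires equal-length inputs")
    if len(a) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def write_summary_csv(summaries: list[SeasonSummary], path) -> None:
    """Tidy CSV: one row per season x metric x statistic."""
    rows = []
    for s in summaries:
        for metric in s.stats.index:
            for stat_name in s.stats.columns:
                rows.append({
                    "season": s.season, "n": s.n, "metric": metric,
                    "statistic": stat_name,
                    "value": s.stats.loc[metric, stat_name],
                })
        rows.append({"season": s.season, "n": s.n,
                     "metric": "pah_to_pm_fraction", "statistic": "mean",
                     "value": s.pah_to_pm_fraction})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
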