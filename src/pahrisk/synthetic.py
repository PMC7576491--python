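"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-season schoolchildren exposure study: personal
PM2.5-bound PAH samples dominated by coal-combustion signatures in the
heating season (high total PAH, 56% high-molecular-weight mass in the six
HMW congeners, IcdP/(IcdP+BghiP) near 0.51, BaA/(BaA+Chr) above 0.4) and by
petroleum/traffic signatures in the non-heating season (total PAH near
1.75 ng/m3, low-molecular-weight dominance with Ant 23% / Phe 15% / Fla
14%, BaA ratio mostly below 0.2, BaP at most 0.01 ng/m3).  Anthropometrics
and spirometric inhalation rates are drawn per the study's four
season-by-sex groups.

Construction draws each sample's total PAH first and splits it by a season
composition profile (with per-sample noise and isomer-pair ratios drawn
around their targets), rather than drawing congeners independently — that
is what guarantees the diagnostic-ratio and weight-class targets jointly.

Every generated table passes ``pahrisk.io`` validation, and the ground
truth of every target used is recorded so recovery tests can close the
loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .congeners import load_registry
from .io import write_participants, write_samples

__all__ = [
    "GeneratorSpec",
    "SyntheticCohort",
    "generate_participants",
    "generate_personal_samples",
    "generate_fixed_site_pairs",
    "generate_cohort",
    "write_fixture_bundle",
]

#: (season, sex) -> (n, height mean/sd cm, weight mean/sd kg, IR mean/sd m3/d)
ANTHROPOMETRY: dict[tuple[str, str], tuple[int, float, float, float, float, float, float]] = {
    ("heating", "boy"): (7, 138.8, 8.7, 31.7, 5.1, 41.2, 19.4),
    ("heating", "girl"): (9, 133.8, 8.7, 28.5, 5.8, 30.4, 9.1),
    ("non-heating", "boy"): (12, 143.2, 9.8, 37.3, 10.8, 42.2, 13.3),
    ("non-heating", "girl"): (10, 136.2, 10.0, 31.4, 7.4, 42.0, 12.3),
}

#: Season composition profiles: congener -> share of total PAH mass.
#: Heating: six HMW congeners carry 0.56; BaP 0.1156 so that the season-mean
#: BaP is ~10.3 ng/m3 at total 89.1; BbF large enough to be the second
#: BaPeq contributor; DahA small (its TEF of 1 would otherwise overtake BbF).
HEATING_PROFILE: dict[str, float] = {
    "Acy": 0.015, "Ace": 0.015, "Flu": 0.02, "Phe": 0.06, "Ant": 0.035,
    "Fla": 0.06, "Pyr": 0.05, "BaA": 0.10, "Chr": 0.085,
    "BbF": 0.178, "BkF": 0.11, "BaP": 0.1156, "IcdP": 0.0716,
    "DahA": 0.016, "BghiP": 0.0688,
}

#: Non-heating: LMW dominance with the printed Ant/Phe/Fla shares; isomer
#: pairs pre-set to petroleum signatures; BaP essentially absent.
NONHEATING_PROFILE: dict[str, float] = {
    "Acy": 0.07, "Ace": 0.05, "Flu": 0.10, "Phe": 0.15, "Ant": 0.23,
    "Fla": 0.14, "Pyr": 0.10, "BaA": 0.009, "Chr": 0.051,
    "BbF": 0.04, "BkF": 0.02, "BaP": 0.004, "IcdP": 0.0045,
    "DahA": 0.006, "BghiP": 0.0255,
}

_RATIO_PAIRS = (("BaA", "Chr"), ("IcdP", "BghiP"), ("Ant", "Phe"), ("Fla", "Pyr"))


@dataclass(frozen=True)
class SeasonTargets:
    """Per-season generating parameters (concentrations in ng/m3)."""

    sum_pah_mean: float
    sum_pah_sd: float
    pm25_mean: float
    pm25_sd: float
    profile: dict[str, float]
    baa_ratio_mean: float
    baa_ratio_sd: float
    baa_ratio_bounds: tuple[float, float]
    icdp_ratio_mean: float
    icdp_ratio_sd: float
    icdp_ratio_bounds: tuple[float, float]
    bap_mode: str                    # "truncnorm" or "uniform"
    bap_params: tuple[float, ...]    # truncnorm: mean, sd, lo, hi; uniform: lo, hi
    io_ratio_range: tuple[float, float]
    io_acy_range: tuple[float, float]
    fixed_outdoor_sum_pah: float


HEATING_TARGETS = SeasonTargets(
    sum_pah_mean=89.1, sum_pah_sd=47.3, pm25_mean=230.0, pm25_sd=35.0,
    profile=HEATING_PROFILE,
    baa_ratio_mean=0.46, baa_ratio_sd=0.03, baa_ratio_bounds=(0.41, 0.60),
    icdp_ratio_mean=0.51, icdp_ratio_sd=0.02, icdp_ratio_bounds=(0.501, 0.557),
    bap_mode="truncnorm", bap_params=(10.3, 4.79, 3.86, 21.86),
    io_ratio_range=(1.2, 3.0), io_acy_range=(0.5, 0.95),
    fixed_outdoor_sum_pah=40.0,
)

NONHEATING_TARGETS = SeasonTargets(
    sum_pah_mean=1.75, sum_pah_sd=0.9, pm25_mean=168.0, pm25_sd=25.0,
    profile=NONHEATING_PROFILE,
    baa_ratio_mean=0.15, baa_ratio_sd=0.05, baa_ratio_bounds=(0.01, 0.39),
    icdp_ratio_mean=0.15, icdp_ratio_sd=0.03, icdp_ratio_bounds=(0.02, 0.35),
    bap_mode="uniform", bap_params=(0.0, 0.01),
    io_ratio_range=(0.4, 0.9), io_acy_range=(0.4, 0.9),
    fixed_outdoor_sum_pah=2.2,
)


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the cohort generator; the defaults are the study design."""

    seed: int = 0
    group_sizes: dict = field(
        default_factory=lambda: {k: v[0] for k, v in ANTHROPOMETRY.items()}
    )
    targets: dict = field(
        default_factory=lambda: {"heating": HEATING_TARGETS,
                                 "non-heating": NONHEATING_TARGETS}
    )
    n_fixed_pairs_per_season: int = 2
    age_mean: float = 10.3
    age_sd: float = 1.5
    profile_noise_sd: float = 0.10   # lognormal sd on non-pair shares
    ir_floor: float = 5.0            # m3/day plausibility floor


@dataclass(frozen=True)
class SyntheticCohort:
    participants: pd.DataFrame
    samples: pd.DataFrame
    ground_truth: pd.DataFrame
    spec: GeneratorSpec


def _trunc_normal(rng, mean, sd, lo, hi=np.inf, size=None):
    """Normal draws resampled into [lo, hi]."""
    draws = rng.normal(mean, sd, size=size)
    scalar = np.ndim(draws) == 0
    draws = np.atleast_1d(draws)
    bad = (draws < lo) | (draws > hi)
    while bad.any():
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (draws < lo) | (draws > hi)
    return float(draws[0]) if scalar else draws


def _lognormal_from_moments(rng, mean, sd, size=None):
    """Lognormal draws with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def generate_participants(spec: GeneratorSpec,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Draw the four season-by-sex participant groups.

    Heights and weights come from the group normals (resampled above
    plausibility floors); tidal volume and breathing frequency are drawn so
    that TV x BF x 1.44 reproduces the group's spirometric inhalation-rate
    distribution exactly.
    """
    rows = []
    for (season, sex), (_, h_m, h_sd, w_m, w_sd, ir_m, ir_sd) in ANTHROPOMETRY.items():
        n = spec.group_sizes[(season, sex)]
        tag = f"{'H' if season == 'heating' else 'N'}{'B' if sex == 'boy' else 'G'}"
        heights = _trunc_normal(rng, h_m, h_sd, 100.0, size=n)
        weights = _trunc_normal(rng, w_m, w_sd, 12.0, size=n)
        irs = _trunc_normal(rng, ir_m, ir_sd, spec.ir_floor, size=n)
        bfs = rng.uniform(15.0, 25.0, size=n)
        tvs = irs / (1.44 * bfs)
        ages = _trunc_normal(rng, spec.age_mean, spec.age_sd, 6.0, 14.0, size=n)
        for i in range(n):
            rows.append({
                "participant_id": f"{tag}{i + 1:02d}",
                "sex": sex,
                "age_y": round(float(ages[i]), 1),
                "height_cm": float(heights[i]),
                "weight_kg": float(weights[i]),
                "tidal_volume_L": float(tvs[i]),
                "breathing_rate_per_min": float(bfs[i]),
                "season": season,
            })
    return pd.DataFrame(rows)


def _split_composition(rng, targets: SeasonTargets, total: float, bap: float,
                       noise_sd: float, abbreviations: list[str]) -> dict[str, float]:
    """Split (total - bap) over the 14 non-BaP congeners.

    Base shares get multiplicative lognormal noise and are renormalized;
    isomer pairs are then re-split by ratios drawn around the season's
    diagnostic targets, which leaves each pair's mass (hence the total)
    unchanged.
    """
    shares = {a: s for a, s in targets.profile.items() if a != "BaP"}
    noisy = {a: s * np.exp(rng.normal(0.0, noise_sd)) for a, s in shares.items()}
    norm = sum(noisy.values())
    noisy = {a: s / norm for a, s in noisy.items()}

    ratio_draws = {
        ("BaA", "Chr"): _trunc_normal(rng, targets.baa_ratio_mean,
                                      targets.baa_ratio_sd,
                                      *targets.baa_ratio_bounds),
        ("IcdP", "BghiP"): _trunc_normal(rng, targets.icdp_ratio_mean,
                                         targets.icdp_ratio_sd,
                                         *targets.icdp_ratio_bounds),
    }
    for a, b in (("Ant", "Phe"), ("Fla", "Pyr")):
        base_r = targets.profile[a] / (targets.profile[a] + targets.profile[b])
        ratio_draws[(a, b)] = _trunc_normal(rng, base_r, 0.03,
                                            max(base_r - 0.1, 0.01),
                                            min(base_r + 0.1, 0.99))
    for (a, b), r in ratio_draws.items():
        pair_total = noisy[a] + noisy[b]
        noisy[a] = r * pair_total
        noisy[b] = (1.0 - r) * pair_total

    rest = total - bap
    conc = {a: noisy[a] * rest for a in noisy}
    conc["BaP"] = bap
    return {a: conc.get(a, 0.0) for a in abbreviations}


def _draw_bap(rng, targets: SeasonTargets, total: float) -> float:
    if targets.bap_mode == "uniform":
        lo, hi = targets.bap_params
        return float(rng.uniform(lo, hi))
    mean, sd, lo, hi = targets.bap_params
    bap = _trunc_normal(rng, mean, sd, lo, hi)
    # keep composition physical when the total-PAH draw comes out low
    return float(min(bap, 0.35 * total))


def generate_personal_samples(spec: GeneratorSpec, participants: pd.DataFrame,
                              rng: np.random.Generator) -> pd.DataFrame:
    """One personal pump sample per participant in their season."""
    registry = load_registry()
    abbr = registry.abbreviations
    rows = []
    for _, p in participants.iterrows():
        t = spec.targets[p["season"]]
        total = float(_lognormal_from_moments(rng, t.sum_pah_mean, t.sum_pah_sd))
        bap = _draw_bap(rng, t, total)
        conc = _split_composition(rng, t, total, bap, spec.profile_noise_sd, abbr)
        # PM2.5 mass must at least carry the PAH mass it hosts
        pm25 = max(_trunc_normal(rng, t.pm25_mean, t.pm25_sd, 10.0),
                   1.05 * total)
        row = {
            "sample_id": f"S-{p['participant_id']}",
            "season": p["season"],
            "sampler_kind": "personal",
            "participant_id": p["participant_id"],
            "duration_h": float(rng.uniform(22.0, 26.0)),
            "pm25": float(pm25),
        }
        row.update(conc)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_fixed_site_pairs(spec: GeneratorSpec,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Indoor/outdoor fixed-sampler pairs with the seasons' I/O structure.

    Heating pairs have indoor/outdoor ratios above 1 for every congener
    except Acy (at most 1); non-heating pairs sit below 1 throughout.
    """
    registry = load_registry()
    abbr = registry.abbreviations
    rows = []
    for season in ("heating", "non-heating"):
        t = spec.targets[season]
        tag = "H" if season == "heating" else "N"
        for i in range(spec.n_fixed_pairs_per_season):
            total = float(t.fixed_outdoor_sum_pah
                          * np.exp(rng.normal(0.0, 0.15)))
            bap = _draw_bap(rng, t, total)
            outdoor = _split_composition(rng, t, total, bap,
                                         spec.profile_noise_sd, abbr)
            ratios = {a: float(rng.uniform(*t.io_ratio_range)) for a in abbr}
            if season == "heating":
                ratios["Acy"] = float(rng.uniform(*t.io_acy_range))
            indoor = {a: outdoor[a] * ratios[a] for a in abbr}
            for kind, conc in (("fixed_outdoor", outdoor),
                               ("fixed_indoor", indoor)):
                row = {
                    "sample_id": f"F-{tag}{i + 1}-{'in' if kind == 'fixed_indoor' else 'out'}",
                    "season": season,
                    "sampler_kind": kind,
                    "participant_id": "",
                    "duration_h": 48.0,
                    "pm25": float(_trunc_normal(rng, t.pm25_mean, t.pm25_sd, 10.0)),
                }
                row.update(conc)
                rows.append(row)
    return pd.DataFrame(rows)


def _ground_truth(spec: GeneratorSpec) -> pd.DataFrame:
    """Record every generating target and where it came from."""
    rows = [("seed", "all", float(spec.seed), "generator")]
    for season, t in spec.targets.items():
        rows += [
            ("sum_pah_mean", season, t.sum_pah_mean, "study"),
            ("sum_pah_sd", season, t.sum_pah_sd,
             "study" if season == "heating" else "generator"),
            ("pm25_mean", season, t.pm25_mean, "study"),
            ("pm25_sd", season, t.pm25_sd, "generator"),
            ("baa_ratio_mean", season, t.baa_ratio_mean,
             "study" if season == "heating" else "generator"),
            ("icdp_ratio_mean", season, t.icdp_ratio_mean,
             "study" if season == "heating" else "generator"),
            ("icdp_ratio_sd", season, t.icdp_ratio_sd,
             "study" if season == "heating" else "generator"),
        ]
        if t.bap_mode == "truncnorm":
            m, sd, lo, hi = t.bap_params
            rows += [("bap_mean", season, m, "study"),
                     ("bap_sd", season, sd, "study"),
                     ("bap_min", season, lo, "study"),
                     ("bap_max", season, hi, "study"),
                     ("bap_cap_fraction_of_total", season, 0.35, "generator")]
        else:
            lo, hi = t.bap_params
            rows += [("bap_min", season, lo, "study"),
                     ("bap_max", season, hi, "study")]
        printed = {"non-heating": {"Ant", "Phe", "Fla"}}.get(season, set())
        for a, s in t.profile.items():
            src = "study" if a in printed or a == "BaP" else "generator"
            rows.append((f"profile_share_{a}", season, s, src))
    for (season, sex), (n, *_rest) in ANTHROPOMETRY.items():
        rows.append((f"group_size_{sex}", season,
                     float(spec.group_sizes[(season, sex)]), "study"))
    rows.append(("hmw_share_target", "heating", 0.56, "study"))
    return pd.DataFrame(rows, columns=["parameter", "season", "value", "source"])


def generate_cohort(spec: GeneratorSpec | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate participants, personal samples, and fixed-site pairs.

    A single generator seeded from the spec drives everything, so the same
    spec always yields byte-identical tables.
    """
    spec = spec or GeneratorSpec()
    if seed is not None:
        spec = GeneratorSpec(seed=seed, group_sizes=spec.group_sizes,
                             targets=spec.targets,
                             n_fixed_pairs_per_season=spec.n_fixed_pairs_per_season)
    rng = np.random.default_rng(spec.seed)
    participants = generate_participants(spec, rng)
    personal = generate_personal_samples(spec, participants, rng)
    fixed = generate_fixed_site_pairs(spec, rng)
    samples = pd.concat([personal, fixed], ignore_index=True)
    return SyntheticCohort(
        participants=participants,
        samples=samples,
        ground_truth=_ground_truth(spec),
        spec=spec,
    )


def write_fixture_bundle(cohort: SyntheticCohort, directory,
                         *, overwrite: bool = False) -> dict[str, Path]:
    """Emit samples.csv, participants.csv, config.yaml and ground_truth.csv.

    Refuses to clobber an existing bundle unless ``overwrite`` is set.
    Re-reading the bundle through ``pahrisk.io`` reproduces the cohort.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.csv"
             for name in ("samples", "participants", "ground_truth")}
    paths["config"] = directory / "config.yaml"
    clashes = [str(p) for p in paths.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite existing bundle files: {clashes}"
        )
    write_samples(cohort.samples, paths["samples"])
    write_participants(cohort.participants, paths["participants"])
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False,
                               float_format="%.6g")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {"generator": {"seed": int(cohort.spec.seed),
                           "n_fixed_pairs_per_season":
                               int(cohort.spec.n_fixed_pairs_per_season)}},
            fh,
        )
    return paths
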