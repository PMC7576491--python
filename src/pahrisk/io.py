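"""Reading, validating and writing sample and participant tables.

Two CSV schemas are supported:

``samples.csv``
    sample_id, season, sampler_kind, participant_id, duration_h, pm25,
    then one column per congener abbreviation (concentrations in ng/m3).

``participants.csv``
    participant_id, sex, age_y, height_cm, weight_kg, tidal_volume_L,
    breathing_rate_per_min, season.

Concentrations below the detection limit may be encoded as ``ND`` (case
insensitive) or left blank; they are substituted according to the nondetect
policy (zero by default, LOD/2 optionally) and flagged, never silently
treated as observed zeros.

Personal pump samples are valid only when the pump ran 22-26 h; fixed-site
samplers run on their own schedule and are never filtered by duration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .congeners import CongenerRegistry, load_registry

__all__ = [
    "SEASONS",
    "SAMPLER_KINDS",
    "SEXES",
    "SchemaError",
    "SampleValidationError",
    "sample_columns",
    "read_samples",
    "write_samples",
    "filter_valid_personal",
    "read_participants",
    "write_participants",
]

SEASONS = ("heating", "non-heating")
SAMPLER_KINDS = ("personal", "fixed_indoor", "fixed_outdoor")
SEXES = ("boy", "girl")

PERSONAL_DURATION_H = (22.0, 26.0)

_SAMPLE_META = ["sample_id", "season", "sampler_kind", "participant_id",
                "duration_h", "pm25"]
_PARTICIPANT_COLS = ["participant_id", "sex", "age_y", "height_cm",
                     "weight_kg", "tidal_volume_L", "breathing_rate_per_min",
                     "season"]

_ND_TOKENS = {"nd", ""}


class SchemaError(ValueError):
    """Header does not match the documented schema."""


class SampleValidationError(ValueError):
    """A row violates a domain invariant; the message names the row."""


def sample_columns(registry: CongenerRegistry | None = None) -> list[str]:
    """Full ordered column list of the samples schema for ``registry``."""
    registry = registry or load_registry()
    return _SAMPLE_META + registry.abbreviations


def _check_header(actual: list[str], expected: list[str], path) -> None:
    if list(actual) != list(expected):
        missing = [c for c in expected if c not in actual]
        extra = [c for c in actual if c not in expected]
        raise SchemaError(
            f"{path}: header mismatch (missing: {missing or 'none'}, "
            f"unexpected: {extra or 'none'}, order must match schema)"
        )


def read_samples(
    path,
    registry: CongenerRegistry | None = None,
    *,
    nondetect: str = "zero",
    lod: float | dict[str, float] | None = None,
    return_nondetect: bool = False,
):
    """Read a samples CSV into a validated DataFrame.

    Parameters
    ----------
    nondetect
        ``"zero"`` stores nondetects as 0 (the study's convention for the
        non-heating BaP range of 0-0.01 ng/m3) or ``"half_lod"`` substitutes
        LOD/2 using ``lod`` (scalar or per-congener mapping).
    return_nondetect
        Also return the boolean nondetect mask (same shape as the congener
        block) so nondetects are never silently indistinguishable from
        observed zeros.
    """
    registry = registry or load_registry()
    cols = sample_columns(registry)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df.columns.tolist(), cols, path)

    congeners = registry.abbreviations
    raw = df[congeners]
    mask = raw.apply(lambda s: s.str.strip().str.lower().isin(_ND_TOKENS))

    out = pd.DataFrame(index=df.index)
    out["sample_id"] = df["sample_id"].astype(str)
    for col, vocab in (("season", SEASONS), ("sampler_kind", SAMPLER_KINDS)):
        vals = df[col].astype(str)
        bad = ~vals.isin(vocab)
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SampleValidationError(
                f"{path} line {row}: {col} {vals[bad].iloc[0]!r} not in {vocab}"
            )
        out[col] = vals
    out["participant_id"] = df["participant_id"].replace("", pd.NA)
    for col in ("duration_h", "pm25"):
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SampleValidationError(f"{path}: non-numeric {col}: {exc}") from exc

    conc = raw.mask(mask, "0")
    try:
        conc = conc.apply(pd.to_numeric).astype(float)
    except (ValueError, TypeError) as exc:
        raise SampleValidationError(f"{path}: non-numeric concentration: {exc}") from exc
    neg = conc.lt(0)
    if neg.any().any():
        col = [c for c in congeners if neg[c].any()][0]
        row = int(neg[col].idxmax()) + 2
        raise SampleValidationError(
            f"{path} line {row}: negative concentration in column {col}"
        )
    if (out["pm25"] < 0).any():
        row = int((out["pm25"] < 0).idxmax()) + 2
        raise SampleValidationError(f"{path} line {row}: negative pm25")

    if nondetect == "half_lod":
        if lod is None:
            raise ValueError("half_lod policy requires a lod value or mapping")
        lod_vec = (pd.Series(lod, index=congeners, dtype=float)
                   if np.isscalar(lod) else pd.Series(lod).reindex(congeners))
        for c in congeners:
            conc.loc[mask[c], c] = lod_vec[c] / 2.0
    elif nondetect != "zero":
        raise ValueError(f"unknown nondetect policy {nondetect!r}")

    out = pd.concat([out, conc], axis=1)
    if return_nondetect:
        return out, mask
    return out


def write_samples(samples: pd.DataFrame, path,
                  registry: CongenerRegistry | None = None) -> None:
    """Write samples to CSV (floats at 6 significant digits)."""
    cols = sample_columns(registry)
    samples[cols].to_csv(path, index=False, float_format="%.6g")


def filter_valid_personal(samples: pd.DataFrame) -> pd.DataFrame:
    """Drop personal samples whose pump ran outside 22-26 h.

    Fixed-site samples pass through untouched.
    """
    lo, hi = PERSONAL_DURATION_H
    personal = samples["sampler_kind"] == "personal"
    keep = ~personal | samples["duration_h"].between(lo, hi)
    return samples[keep].reset_index(drop=True)


def read_participants(path) -> pd.DataFrame:
    """Read and validate a participants CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df.columns.tolist(), _PARTICIPANT_COLS, path)

    out = pd.DataFrame(index=df.index)
    out["participant_id"] = df["participant_id"].astype(str)
    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise SampleValidationError(
            f"{path} line {row}: sex {df['sex'][bad].iloc[0]!r} not in {SEXES}"
        )
    out["sex"] = df["sex"]
    for col in ("age_y", "height_cm", "weight_kg", "tidal_volume_L",
                "breathing_rate_per_min"):
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SampleValidationError(f"{path}: non-numeric {col}: {exc}") from exc
    for col in ("weight_kg", "tidal_volume_L", "breathing_rate_per_min"):
        nonpos = out[col] <= 0
        if nonpos.any():
            row = int(nonpos.idxmax()) + 2
            raise SampleValidationError(f"{path} line {row}: {col} must be > 0")
    bad = ~df["season"].isin(SEASONS)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise SampleValidationError(f"{path} line {row}: bad season")
    out["season"] = df["season"]
    return out


def write_participants(participants: pd.DataFrame, path) -> None:
    participants[_PARTICIPANT_COLS].to_csv(path, index=False, float_format="%.6g")
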