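"""Registry of priority PM2.5-bound PAH congeners and their toxic equivalency factors.

The sixteen US-EPA priority PAHs are known by conventional abbreviations
(Nap naphthalene ... BghiP benzo[g,h,i]perylene).  Particulate-phase studies
typically quantify fifteen of them; naphthalene, being almost entirely
gas-phase, is excluded by default but the exclusion is configurable.

Each congener carries a toxic equivalency factor (TEF) expressing its
carcinogenic potency relative to benzo[a]pyrene (TEF = 1 by definition).
Default TEFs follow the Nisbet & LaGoy scheme except that
dibenz[a,h]anthracene is assigned TEF 1; all TEFs can be overridden
through the ``tef`` section of a config mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "CongenerRecord",
    "TefTable",
    "CongenerRegistry",
    "load_registry",
    "EPA16",
    "HMW_CONGENERS",
    "DEFAULT_TEFS",
]

#: The sixteen EPA priority PAHs in conventional (volatility) order.
EPA16: tuple[str, ...] = (
    "Nap", "Acy", "Ace", "Flu", "Phe", "Ant", "Fla", "Pyr",
    "BaA", "Chr", "BbF", "BkF", "BaP", "IcdP", "DahA", "BghiP",
)

#: High-molecular-weight congeners: the five- and six-ring species that are
#: predominantly particle-bound and dominate carcinogenicity.
HMW_CONGENERS: frozenset[str] = frozenset(
    {"BbF", "BkF", "BaP", "IcdP", "DahA", "BghiP"}
)

#: Nisbet & LaGoy-style TEFs with DahA = 1 (see module docstring).
DEFAULT_TEFS: dict[str, float] = {
    "Nap": 0.001, "Acy": 0.001, "Ace": 0.001, "Flu": 0.001,
    "Phe": 0.001, "Ant": 0.01, "Fla": 0.001, "Pyr": 0.001,
    "BaA": 0.1, "Chr": 0.01, "BbF": 0.1, "BkF": 0.1,
    "BaP": 1.0, "IcdP": 0.1, "DahA": 1.0, "BghiP": 0.01,
}


class RegistryConfigError(ValueError):
    """Raised when a TEF override names an unknown congener or is incomplete."""


@dataclass(frozen=True)
class CongenerRecord:
    """One PAH congener: abbreviation, weight class, and TEF."""

    abbreviation: str
    weight_class: str  # "LMW" or "HMW"
    tef: float

    def __post_init__(self) -> None:
        if self.weight_class not in ("LMW", "HMW"):
            raise ValueError(f"weight_class must be LMW or HMW, got {self.weight_class!r}")
        if not (0 < self.tef <= 5):
            raise ValueError(
                f"TEF for {self.abbreviation} must be in (0, 5], got {self.tef}"
            )
        if self.abbreviation == "BaP" and self.tef != 1.0:
            raise ValueError("BaP is the reference compound; its TEF must be exactly 1")


@dataclass(frozen=True)
class TefTable:
    """Mapping abbreviation -> TEF with a provenance label.

    Serializes losslessly to the ``tef`` section of a config mapping.
    """

    values: Mapping[str, float]
    provenance: str = "NisbetLaGoy1992-DahA1"

    def __getitem__(self, abbreviation: str) -> float:
        return self.values[abbreviation]

    def to_config(self) -> dict:
        return {"tef": dict(self.values), "tef_provenance": self.provenance}

    @classmethod
    def from_config(cls, config: Mapping) -> "TefTable":
        return cls(
            values=dict(config["tef"]),
            provenance=config.get("tef_provenance", "config"),
        )


class CongenerRegistry:
    """Ordered, immutable collection of :class:`CongenerRecord`.

    Iteration order follows :data:`EPA16` and is stable across runs.
    """

    def __init__(self, records: list[CongenerRecord]):
        seen = set()
        for r in records:
            if r.abbreviation in seen:
                raise ValueError(f"duplicate congener {r.abbreviation}")
            seen.add(r.abbreviation)
        self._records = {r.abbreviation: r for r in records}

    def __iter__(self) -> Iterator[CongenerRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._records

    @property
    def abbreviations(self) -> list[str]:
        return list(self._records)

    def record(self, abbreviation: str) -> CongenerRecord:
        try:
            return self._records[abbreviation]
        except KeyError:
            raise KeyError(f"unknown congener {abbreviation!r}") from None

    def weight_class_of(self, abbreviation: str) -> str:
        """Return ``"LMW"`` or ``"HMW"`` for a registered congener."""
        return self.record(abbreviation).weight_class

    def tef_table(self) -> TefTable:
        return TefTable(values={a: r.tef for a, r in self._records.items()})

    @property
    def hmw_abbreviations(self) -> list[str]:
        return [a for a, r in self._records.items() if r.weight_class == "HMW"]

    @property
    def lmw_abbreviations(self) -> list[str]:
        return [a for a, r in self._records.items() if r.weight_class == "LMW"]


def load_registry(
    config: Mapping | None = None,
    *,
    exclude: str = "Nap",
    merge_defaults: bool = False,
) -> CongenerRegistry:
    """Build the active congener registry, optionally with TEF overrides.

    Parameters
    ----------
    config
        Parsed config mapping.  If it has a ``tef`` section it must supply a
        TEF for every active congener, unless ``merge_defaults`` is set, in
        which case missing entries fall back to :data:`DEFAULT_TEFS`.
        An abbreviation not in the active registry raises
        :class:`RegistryConfigError` naming the offender.
    exclude
        Which of the sixteen EPA congeners to leave out of the default
        fifteen-congener registry.  Pass ``""`` to keep all sixteen.
    merge_defaults
        Allow a partial ``tef`` override; without it a partial table is an
        error rather than being silently completed.
    """
    active = [a for a in EPA16 if a != exclude]
    if len(active) == len(EPA16) and exclude:
        raise RegistryConfigError(f"cannot exclude unknown congener {exclude!r}")

    tefs = dict(DEFAULT_TEFS)
    if config is not None and "tef" in config:
        override = dict(config["tef"])
        unknown = sorted(set(override) - set(active))
        if unknown:
            raise RegistryConfigError(
                f"unknown congener(s) in tef config: {', '.join(unknown)}"
            )
        if not merge_defaults and set(override) != set(active):
            missing = sorted(set(active) - set(override))
            raise RegistryConfigError(
                "partial tef override (missing "
                f"{', '.join(missing)}); pass merge_defaults=True to fill "
                "gaps with defaults"
            )
        tefs.update({k: float(v) for k, v in override.items()})

    records = [
        CongenerRecord(
            abbreviation=a,
            weight_class="HMW" if a in HMW_CONGENERS else "LMW",
            tef=tefs[a],
        )
        for a in active
    ]
    return CongenerRegistry(records)
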