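"""Domain types, unit handling and the built-in kinetic-constant registry.

All computation inside :mod:`redoxkin` is carried out in SI units
(concentrations in M, time in s, second-order rate constants in M⁻¹s⁻¹).
Micromolar values are accepted and reported only at the boundaries, through
:func:`convert_concentration`.

Several literature constants are only known as ranges (e.g. the cellular
glutathione peroxidase concentration, 0.2–10 µM).  These are kept as
:class:`Interval` objects and propagated endpoint-wise; a point query uses
the interval midpoint unless an endpoint is requested explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "UnitError",
    "convert_concentration",
    "round_sig",
    "Interval",
    "as_interval",
    "RateConstants",
    "CellContext",
    "ProteinEntry",
    "ThresholdPolicy",
    "Registry",
    "builtin_registry",
]


class UnitError(ValueError):
    """Raised for an unknown concentration unit tag."""


#: Scale of each supported concentration unit relative to molar.
_CONC_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between M, mM, µM and nM.

    Pure power-of-ten scaling, so round-trips are exact.  ``uM`` and ``µM``
    are interchangeable spellings.
    """
    try:
        f = _CONC_UNITS[from_unit]
        t = _CONC_UNITS[to_unit]
    except KeyError as exc:
        raise UnitError(
            f"unknown concentration unit {exc.args[0]!r}; "
            f"expected one of {sorted(set(_CONC_UNITS) - {'uM'})}"
        ) from None
    return value * (f / t)


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures, half away from zero.

    Used when comparing computed quantities against values printed at
    limited precision in the literature.
    """
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    shift = sig - 1 - d.adjusted()
    q = d.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(q.scaleb(-shift))


@dataclass(frozen=True)
class Interval:
    """A closed interval [low, high] of positive physical quantities."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValueError(f"interval bounds out of order: [{self.low}, {self.high}]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def scale(self, c: float) -> "Interval":
        """Multiply both endpoints by a non-negative scalar."""
        if c < 0:
            raise ValueError("scale factor must be non-negative")
        return Interval(self.low * c, self.high * c)

    def __mul__(self, other: Union["Interval", float, int]) -> "Interval":
        # endpoint-wise product; valid because all quantities here are >= 0
        if isinstance(other, Interval):
            return Interval(self.low * other.low, self.high * other.high)
        return self.scale(float(other))

    __rmul__ = __mul__

    def __iter__(self):
        yield self.low
        yield self.high

    def __contains__(self, x: float) -> bool:
        return self.low <= x <= self.high


Scalarish = Union[float, Interval]


def as_interval(x: Scalarish) -> Interval:
    """Promote a scalar to a degenerate interval; pass intervals through."""
    if isinstance(x, Interval):
        return x
    return Interval(float(x), float(x))


def _point(x: Scalarish) -> float:
    """Point value of a possibly interval-valued quantity (midpoint rule)."""
    return x.midpoint if isinstance(x, Interval) else float(x)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """Kinetic constants of one redox switch.

    Parameters
    ----------
    name
        Protein label, e.g. ``"PTP1B"``.
    k_ox
        Second-order rate constant for oxidation of the reduced switch by
        H₂O₂, M⁻¹s⁻¹.
    k_switchoff
        Pseudo-first-order rate constant lumping the enzymatic reduction of
        the oxidized switch back to the reduced state, s⁻¹.
    note
        Free-text provenance, e.g. ``"+CO2, 37 °C"``.
    """

    name: str
    k_ox: float
    k_switchoff: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("switch name must be non-empty")
        if not self.k_ox > 0:
            raise ValueError(f"{self.name}: k_ox must be > 0, got {self.k_ox}")
        if not self.k_switchoff > 0:
            raise ValueError(
                f"{self.name}: k_switchoff must be > 0, got {self.k_switchoff}"
            )

    @property
    def half_oxidation_h2o2(self) -> float:
        """H₂O₂ concentration (M) giving 50% steady-state oxidation."""
        return self.k_switchoff / self.k_ox


@dataclass(frozen=True)
class CellContext:
    """Cellular H₂O₂ production/removal context.

    ``v_formation`` is the H₂O₂ formation rate (M·s⁻¹); ``k_cons`` and
    ``k_sign`` are the pseudo-first-order constants for removal by
    antioxidant systems and by the signaling (switch-oxidation) reaction,
    s⁻¹.  ``gradient`` is the dimensionless extracellular/intracellular
    H₂O₂ ratio across the plasma membrane.
    """

    v_formation: float
    k_cons: float
    k_sign: float = 0.0
    gradient: float = 1.0

    def __post_init__(self) -> None:
        if self.v_formation < 0:
            raise ValueError("v_formation must be >= 0")
        if not self.k_cons > 0:
            raise ValueError("k_cons must be > 0")
        if self.k_sign < 0:
            raise ValueError("k_sign must be >= 0")
        if self.gradient < 1:
            raise ValueError("gradient must be >= 1")


@dataclass(frozen=True)
class ProteinEntry:
    """One protein competing for H₂O₂: an antioxidant or a redox switch.

    ``k2`` (M⁻¹s⁻¹) and ``conc_uM`` (µM) may each be a scalar or an
    :class:`Interval`; their product (after µM → M conversion) is the
    pseudo-first-order rate constant of the protein's reaction with H₂O₂.
    """

    name: str
    k2: Scalarish
    conc_uM: Scalarish
    protein_class: str  # "antioxidant" | "redox_switch"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("protein name must be non-empty")
        if self.protein_class not in ("antioxidant", "redox_switch"):
            raise ValueError(f"unknown protein class {self.protein_class!r}")
        for label, v in (("k2", self.k2), ("conc_uM", self.conc_uM)):
            iv = as_interval(v)
            if not iv.low > 0:
                raise ValueError(f"{self.name}: {label} must be > 0")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Oxidation thresholds defining signal-transmitting responses.

    Below ``ox_low`` (default 10%) a switch response is considered too weak
    to transmit the H₂O₂ signal; above ``ox_high`` (default 90%) it is near
    saturated.  ``ox_half`` is the oxidation level at which the response
    time is reported, and ``t_max_signal`` (default 600 s = 10 min) the
    longest response time still considered useful for signaling.
    """

    ox_low: float = 0.10
    ox_high: float = 0.90
    ox_half: float = 0.50
    t_max_signal: float = 600.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ox_low < self.ox_half < self.ox_high < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < ox_low < ox_half < ox_high < 1"
            )
        if not self.t_max_signal > 0:
            raise ValueError("t_max_signal must be > 0")


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def _norm(name: str) -> str:
    return name.replace(" ", "").casefold()


@dataclass
class Registry:
    """Named collection of redox-switch constants and competing proteins.

    Lookups are case-insensitive and ignore spaces, so ``"ptp1b + co2"``
    resolves to ``"PTP1B+CO2"``.
    """

    switches: dict[str, RateConstants] = field(default_factory=dict)
    proteins: dict[str, ProteinEntry] = field(default_factory=dict)

    # -- mutation ----------------------------------------------------------
    def add_switch(self, rc: RateConstants) -> None:
        self.switches[rc.name] = rc

    def add_protein(self, entry: ProteinEntry) -> None:
        self.proteins[entry.name] = entry

    # -- lookup ------------------------------------------------------------
    def lookup_switch(self, name: str) -> RateConstants:
        key = _norm(name)
        for k, v in self.switches.items():
            if _norm(k) == key:
                return v
        raise KeyError(f"no redox switch named {name!r} in registry")

    def lookup_protein(self, name: str) -> ProteinEntry:
        key = _norm(name)
        for k, v in self.proteins.items():
            if _norm(k) == key:
                return v
        raise KeyError(f"no protein entry named {name!r} in registry")

    def lookup(self, name: str) -> Union[RateConstants, ProteinEntry]:
        """Resolve a name: redox-switch constants first, then proteins."""
        try:
            return self.lookup_switch(name)
        except KeyError:
            return self.lookup_protein(name)

    def antioxidants(self) -> list[ProteinEntry]:
        return [p for p in self.proteins.values() if p.protein_class == "antioxidant"]

    def redox_switch_entries(self) -> list[ProteinEntry]:
        return [p for p in self.proteins.values() if p.protein_class == "redox_switch"]

    # -- serialization -----------------------------------------------------
    @staticmethod
    def _dump_scalarish(x: Scalarish):
        return [x.low, x.high] if isinstance(x, Interval) else float(x)

    @staticmethod
    def _load_scalarish(x) -> Scalarish:
        if isinstance(x, (list, tuple)):
            return Interval(float(x[0]), float(x[1]))
        return float(x)

    def to_dict(self) -> dict:
        return {
            "switches": [
                {
                    "name": rc.name,
                    "k_ox": rc.k_ox,
                    "k_switchoff": rc.k_switchoff,
                    "note": rc.note,
                }
                for rc in self.switches.values()
            ],
            "proteins": [
                {
                    "name": p.name,
                    "k2": self._dump_scalarish(p.k2),
                    "conc_uM": self._dump_scalarish(p.conc_uM),
                    "class": p.protein_class,
                    "note": p.note,
                }
                for p in self.proteins.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Registry":
        reg = cls()
        for s in d.get("switches", []):
            reg.add_switch(
                RateConstants(
                    name=s["name"],
                    k_ox=float(s["k_ox"]),
                    k_switchoff=float(s["k_switchoff"]),
                    note=s.get("note", ""),
                )
            )
        for p in d.get("proteins", []):
            reg.add_protein(
                ProteinEntry(
                    name=p["name"],
                    k2=cls._load_scalarish(p["k2"]),
                    conc_uM=cls._load_scalarish(p["conc_uM"]),
                    protein_class=p["class"],
                    note=p.get("note", ""),
                )
            )
        return reg

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "Registry":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "Registry":
        """Load user-supplied constants from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


# Pseudo-first-order reduction constants: protein tyrosine phosphatases and
# the slow non-catalytic switches are re-reduced at ~2e-3 s⁻¹, whereas the
# thioredoxin system recycles peroxiredoxins about three orders of magnitude
# faster, at ~2 s⁻¹.
K_SWITCHOFF_SLOW = 2e-3
K_SWITCHOFF_PRX = 2.0

#: Names of the six switches with tabulated dynamic ranges and response times.
TABLE2_SWITCHES = ("PTP1B", "PTP1B+CO2", "SHP-2", "SHP-2+CO2", "Prx5", "Prx2")


def builtin_registry() -> Registry:
    """The built-in registry of literature kinetic constants.

    Redox switches carry second-order oxidation constants spanning six
    orders of magnitude (20 M⁻¹s⁻¹ for SHP-2 up to 1×10⁷ M⁻¹s⁻¹ for
    peroxiredoxin 2), with CO₂/bicarbonate-enhanced variants for the two
    phosphatases (peroxymonocarbonate chemistry, 37 °C).  Protein entries
    hold the concentrations and rate constants used in the
    antioxidant-vs-switch competition analysis.
    """
    reg = Registry()
    for name, k_ox, k_off, note in [
        ("Prx2", 1e7, K_SWITCHOFF_PRX, "peroxiredoxin 2"),
        ("Prx5", 3e5, K_SWITCHOFF_PRX, "peroxiredoxin 5"),
        ("Keap1", 140.0, K_SWITCHOFF_SLOW, "Kelch-like ECH-associated protein 1"),
        ("cdc25B", 140.0, K_SWITCHOFF_SLOW, "cell division cycle 25B"),
        ("PTP1B", 24.0, K_SWITCHOFF_SLOW, "protein tyrosine phosphatase 1B"),
        ("PTP1B+CO2", 396.0, K_SWITCHOFF_SLOW, "+CO2, 37 °C"),
        ("SHP-2", 20.0, K_SWITCHOFF_SLOW, "src-homology-2 tyrosine phosphatase"),
        ("SHP-2+CO2", 167.0, K_SWITCHOFF_SLOW, "+CO2, 37 °C"),
    ]:
        reg.add_switch(RateConstants(name, k_ox, k_off, note))

    reg.add_protein(
        ProteinEntry("Prx", Interval(1e5, 1e7), 10.0, "antioxidant", "peroxiredoxin")
    )
    reg.add_protein(
        ProteinEntry(
            "GPx", 6e7, Interval(0.2, 10.0), "antioxidant", "glutathione peroxidase 1"
        )
    )
    reg.add_protein(
        ProteinEntry(
            "catalase", 1e7, 1e3, "antioxidant", "concentration refers to the peroxisome"
        )
    )
    reg.add_protein(ProteinEntry("PTP1B", 24.0, 0.01, "redox_switch"))
    reg.add_protein(ProteinEntry("SHP-2", 20.0, 0.01, "redox_switch"))
    reg.add_protein(ProteinEntry("Keap1", 140.0, 1.0, "redox_switch"))
    return reg
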