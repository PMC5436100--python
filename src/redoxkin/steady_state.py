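"""Steady-state H₂O₂ levels and the antioxidant-vs-signaling flux competition.

H₂O₂ formation (rate ``v_formation``) is balanced by first-order removal
through antioxidant systems (``k_cons·[H₂O₂]``) and, when a redox switch is
present, through the signaling oxidation reaction (``k_sign·[H₂O₂]``).  The
steady state is

    [H₂O₂]_ss = v_formation / (k_cons + k_sign)

with the antioxidant-only case being the special case ``k_sign = 0``.
Because both sinks are first order in H₂O₂, the fraction of removal flux
each captures is a ratio of rate constants and is independent of the H₂O₂
level — the basis of the observation that antioxidants divert essentially
all H₂O₂ away from signaling targets, while the *rate* of the signaling
reaction still tracks the H₂O₂ concentration profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CellContext, Interval, ProteinEntry, Scalarish, as_interval

__all__ = [
    "SteadyStateResult",
    "h2o2_steady_state",
    "pseudo_first_order",
    "removal_half_time",
    "competition_orders",
]


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state H₂O₂ level and partition of the removal flux.

    ``frac_cons``/``frac_sign`` are the fractions of removal flux going
    through antioxidants and through the signaling reaction; they are
    defined on rate constants (``k_cons/(k_cons+k_sign)``) so that they are
    well defined even away from steady state, where they coincide with the
    flux fractions.
    """

    h2o2_ss: float  # M
    flux_cons: float  # M/s
    flux_sign: float  # M/s
    frac_cons: float
    frac_sign: float


def h2o2_steady_state(ctx: CellContext) -> SteadyStateResult:
    """Steady-state H₂O₂ concentration and flux partition for a context.

    Raises
    ------
    ZeroDivisionError
        If ``k_cons + k_sign == 0`` — no removal pathway, so no steady
        state exists.  (Unreachable for a valid :class:`CellContext`,
        which requires ``k_cons > 0``.)
    """
    k_total = ctx.k_cons + ctx.k_sign
    if k_total == 0:
        raise ZeroDivisionError(
            "k_cons + k_sign = 0: no H2O2 removal pathway, steady state undefined"
        )
    h_ss = ctx.v_formation / k_total
    frac_sign = ctx.k_sign / k_total
    frac_cons = 1.0 - frac_sign
    # fluxes via fractions so flux_cons + flux_sign == v_formation exactly
    return SteadyStateResult(
        h2o2_ss=h_ss,
        flux_cons=frac_cons * ctx.v_formation,
        flux_sign=frac_sign * ctx.v_formation,
        frac_cons=frac_cons,
        frac_sign=frac_sign,
    )


def pseudo_first_order(entry: ProteinEntry) -> Scalarish:
    """Pseudo-first-order rate constant of a protein's reaction with H₂O₂.

    The product of the second-order rate constant ``k2`` (M⁻¹s⁻¹) and the
    protein concentration (µM, converted to M), s⁻¹.  Interval-valued
    inputs multiply endpoint-wise and return an :class:`Interval`.
    """
    if isinstance(entry.k2, Interval) or isinstance(entry.conc_uM, Interval):
        return as_interval(entry.k2) * as_interval(entry.conc_uM).scale(1e-6)
    return entry.k2 * entry.conc_uM * 1e-6


def removal_half_time(k_total: float) -> float:
    """Half-time ln(2)/k of a first-order removal process, s."""
    if not k_total > 0:
        raise ValueError(f"rate constant must be > 0, got {k_total}")
    return math.log(2.0) / k_total


def competition_orders(
    antioxidants: list[ProteinEntry], switches: list[ProteinEntry]
) -> Interval:
    """Range of log10(k_cons/k_sign) over an antioxidant × switch grid.

    Summarizes by how many orders of magnitude antioxidant consumption
    outcompetes redox-switch oxidation for H₂O₂.
    """
    if not antioxidants or not switches:
        raise ValueError("need at least one antioxidant and one redox switch")
    logs = []
    for a in antioxidants:
        ka = as_interval(pseudo_first_order(a))
        for s in switches:
            ks = as_interval(pseudo_first_order(s))
            logs.append(math.log10(ka.low / ks.high))
            logs.append(math.log10(ka.high / ks.low))
    return Interval(min(logs), max(logs))
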