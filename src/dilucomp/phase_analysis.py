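"""Mortality re-parameterization and pairwise outcome classification.

Adding a uniform per-capita mortality delta to the two-species LV model is
equivalent to a mortality-free LV model with rescaled densities
N~_i = N_i / (1 - delta/r_i), reduced rates r~_i = r_i - delta, and
effective competition coefficients

    a~_ij = alpha_ij * (1 - delta/r_j) / (1 - delta/r_i).

The qualitative outcome depends only on whether each a~ exceeds one:
both below one gives stable coexistence, both above one gives bistability,
and exactly one above one gives exclusion of the more-inhibited species.

Because a~_ij * a~_ji is independent of delta, sweeping mortality moves a
pair along a line of slope -1 in (log a~_12, log a~_21) space -- a 45-degree
trajectory -- so a pair whose slow grower dominates at delta = 0 must pass
through coexistence (alpha product < 1) or bistability (product > 1) before
the fast grower dominates at high mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ContractViolation, DegenerateEquilibria, MortalityDomainError
from .lv_dynamics import CommunityParams

__all__ = [
    "Outcome",
    "EffectiveParams",
    "PairOutcome",
    "dilution_to_delta",
    "delta_to_dilution",
    "effective_alpha",
    "classify_pair",
    "classify_pair_at",
    "pair_survivor_sets",
    "critical_mortalities",
    "mortality_sweep",
]

#: |a~ - 1| below this is treated as a degenerate tie, not an arbitrary side
TIE_TOLERANCE = 1e-9


class Outcome(str, Enum):
    """Qualitative result of a two-species competition.

    ``NON_LV`` and ``ALL_EXTINCT`` are produced only by experiment-level
    inference (a mixed coexistence/exclusion bistability is not an allowed
    LV outcome; total extinction happens when mortality exceeds all growth
    rates), never by the analytic classifier.
    """

    EXCLUSION_1 = "species-1-excludes-2"
    EXCLUSION_2 = "species-2-excludes-1"
    COEXISTENCE = "coexistence"
    BISTABILITY = "bistability"
    DEGENERATE = "degenerate"
    NON_LV = "non-LV"
    ALL_EXTINCT = "all-extinct"


@dataclass(frozen=True)
class EffectiveParams:
    """Mortality-transformed parameters of a community.

    Defined only while every species' mortality is below its growth rate.
    ``rescale[i]`` = 1 - delta_i/r_i maps rescaled densities back to
    normalized ones (N_i = N~_i * rescale[i]).
    """

    species_ids: tuple
    delta: np.ndarray  # per-species mortality (uniform case repeats a scalar)
    alpha_eff: np.ndarray
    r_eff: np.ndarray
    rescale: np.ndarray


def dilution_to_delta(dilution_factor: float, cycle_hours: float = 24.0) -> float:
    """Continuous mortality rate equivalent to a per-cycle dilution factor.

    Equal per-cycle survival fractions force delta = ln(DF) / T.
    """
    if dilution_factor < 1:
        raise ContractViolation("dilution_factor must be >= 1")
    if cycle_hours <= 0:
        raise ContractViolation("cycle_hours must be > 0")
    return math.log(dilution_factor) / cycle_hours


def delta_to_dilution(delta: float, cycle_hours: float = 24.0) -> float:
    """Dilution factor equivalent to a continuous mortality rate."""
    if delta < 0:
        raise ContractViolation("delta must be >= 0")
    return math.exp(delta * cycle_hours)


def effective_alpha(params: CommunityParams, delta) -> EffectiveParams:
    """Compute the mortality-transformed coefficients.

    ``delta`` may be a scalar (uniform mortality, the standard case) or a
    per-species vector (species-specific mortality, e.g. a drug that targets
    fast growers); the transform generalizes to
    a~_ij = alpha_ij (1 - delta_j/r_j) / (1 - delta_i/r_i).
    """
    d = np.broadcast_to(np.asarray(delta, dtype=float), (params.n,)).copy()
    if np.any(d < 0):
        raise ContractViolation("mortality rates must be >= 0")
    bad = np.nonzero(d >= params.growth_rates)[0]
    if bad.size:
        names = ", ".join(params.species_ids[i] for i in bad)
        raise MortalityDomainError(
            f"mortality >= growth rate for species: {names}; "
            "the re-parameterization is undefined"
        )
    rescale = 1.0 - d / params.growth_rates
    alpha_eff = params.alpha * rescale[None, :] / rescale[:, None]
    return EffectiveParams(
        species_ids=params.species_ids,
        delta=d,
        alpha_eff=alpha_eff,
        r_eff=params.growth_rates - d,
        rescale=rescale,
    )


@dataclass(frozen=True)
class PairOutcome:
    """Classified outcome of a pair plus the interior equilibrium, if any.

    ``interior_fraction`` is the fraction of species 1 (normalized-density
    weighting) at the interior fixed point: the stable coexistence fraction,
    or the unstable separatrix fraction for a bistable pair.
    """

    category: Outcome
    interior_fraction: float | None
    alpha_eff_12: float
    alpha_eff_21: float


def _interior_fraction(eff: EffectiveParams) -> float:
    a12, a21 = eff.alpha_eff[0, 1], eff.alpha_eff[1, 0]
    prod = a12 * a21
    n1 = (1.0 - a12) / (1.0 - prod) * eff.rescale[0]
    n2 = (1.0 - a21) / (1.0 - prod) * eff.rescale[1]
    return n1 / (n1 + n2)


def classify_pair(eff: EffectiveParams, tie_tolerance: float = TIE_TOLERANCE) -> PairOutcome:
    """Apply the both-coefficients-versus-one rule to a pair.

    Both a~ < 1: stable coexistence (interior fraction reported). Both > 1:
    bistability (unstable separatrix fraction reported). Exactly one > 1:
    the species facing the above-one incoming coefficient is excluded.
    Either coefficient within ``tie_tolerance`` of 1 is degenerate.
    """
    if len(eff.species_ids) != 2:
        raise ContractViolation("classify_pair requires a two-species EffectiveParams")
    a12, a21 = float(eff.alpha_eff[0, 1]), float(eff.alpha_eff[1, 0])
    if not (np.isfinite(a12) and np.isfinite(a21) and a12 > 0 and a21 > 0):
        raise ContractViolation("effective coefficients must be finite and positive")
    if abs(a12 - 1.0) < tie_tolerance or abs(a21 - 1.0) < tie_tolerance:
        return PairOutcome(Outcome.DEGENERATE, None, a12, a21)
    if a12 < 1 and a21 < 1:
        return PairOutcome(Outcome.COEXISTENCE, _interior_fraction(eff), a12, a21)
    if a12 > 1 and a21 > 1:
        return PairOutcome(Outcome.BISTABILITY, _interior_fraction(eff), a12, a21)
    if a12 > 1:  # species 1 strongly inhibited -> species 2 wins
        return PairOutcome(Outcome.EXCLUSION_2, None, a12, a21)
    return PairOutcome(Outcome.EXCLUSION_1, None, a12, a21)


def classify_pair_at(params: CommunityParams, delta: float) -> PairOutcome:
    """Classify a pair at a given uniform mortality."""
    if params.n != 2:
        raise ContractViolation("classify_pair_at requires a two-species community")
    return classify_pair(effective_alpha(params, delta))


def pair_survivor_sets(params: CommunityParams, delta: float) -> list[frozenset]:
    """Model-predicted stable survivor sets of a pair at uniform mortality.

    Unlike :func:`classify_pair_at` this also covers mortality at or above a
    growth rate: a species with delta >= r_i dies in any company, so the
    surviving set follows from monoculture viability alone.
    """
    if params.n != 2:
        raise ContractViolation("pair_survivor_sets requires a two-species community")
    r = params.growth_rates
    s1, s2 = params.species_ids
    viable = [delta < r[0], delta < r[1]]
    if not any(viable):
        return [frozenset()]
    if viable[0] != viable[1]:
        return [frozenset({s1 if viable[0] else s2})]
    out = classify_pair_at(params, delta)
    if out.category is Outcome.COEXISTENCE:
        return [frozenset({s1, s2})]
    if out.category is Outcome.BISTABILITY:
        return [frozenset({s1}), frozenset({s2})]
    if out.category is Outcome.EXCLUSION_1:
        return [frozenset({s1})]
    if out.category is Outcome.EXCLUSION_2:
        return [frozenset({s2})]
    raise DegenerateEquilibria("pair sits on a classification boundary")


@dataclass(frozen=True)
class CriticalMortality:
    """A mortality rate at which one effective coefficient crosses one."""

    delta: float
    coefficient: tuple  # ordered (i, j) index pair of the crossing a~_ij


def critical_mortalities(params: CommunityParams) -> list[CriticalMortality]:
    """Mortality rates where a~_ij(delta) = 1, within (0, min r).

    Solving alpha_ij (1 - delta/r_j) = (1 - delta/r_i) gives
    delta* = r_i r_j (1 - alpha_ij) / (r_j - alpha_ij r_i). Between
    consecutive critical values the pair's category is constant. Equal
    growth rates leave every a~ independent of delta (empty list).
    """
    if params.n != 2:
        raise ContractViolation("critical_mortalities requires a two-species community")
    r = params.growth_rates
    if math.isclose(r[0], r[1], rel_tol=0, abs_tol=1e-12):
        return []
    rmin = float(r.min())
    out = []
    for i, j in ((0, 1), (1, 0)):
        aij = params.alpha[i, j]
        denom = r[j] - aij * r[i]
        if abs(denom) < 1e-300:
            continue
        dstar = r[i] * r[j] * (1.0 - aij) / denom
        if 0.0 < dstar < rmin:
            out.append(CriticalMortality(float(dstar), (i, j)))
    return sorted(out, key=lambda c: c.delta)


def mortality_sweep(
    params: CommunityParams,
    deltas=None,
    dilution_factors=None,
    cycle_hours: float = 24.0,
) -> pd.DataFrame:
    """Classify a pair along a mortality (or dilution-factor) grid.

    Exactly one of ``deltas`` / ``dilution_factors`` must be given; every
    grid point must lie in [0, min r). Returns one row per grid point with
    both axes (delta and the equivalent DF = exp(delta * T)) so model and
    experiment line up, plus the per-point classification -- the data behind
    a pair's "subway map".
    """
    if (deltas is None) == (dilution_factors is None):
        raise ContractViolation("give exactly one of deltas / dilution_factors")
    if dilution_factors is not None:
        deltas = [dilution_to_delta(df, cycle_hours) for df in dilution_factors]
    deltas = np.asarray(list(deltas), dtype=float)
    if np.any(deltas < 0) or np.any(deltas >= params.growth_rates.min()):
        raise ContractViolation("sweep grid must lie in [0, min growth rate)")
    rows = []
    for d in deltas:
        out = classify_pair_at(params, float(d))
        rows.append(
            {
                "delta": float(d),
                "DF_equivalent": delta_to_dilution(float(d), cycle_hours),
                "category": out.category.value,
                "interior_fraction": out.interior_fraction,
                "alpha_eff_12": out.alpha_eff_12,
                "alpha_eff_21": out.alpha_eff_21,
            }
        )
    return pd.DataFrame(rows)
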