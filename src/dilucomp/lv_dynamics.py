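"""Lotka-Volterra competition dynamics with added mortality.

The model for n competing species is

    dN_i/dt = r_i N_i (1 - sum_j alpha_ij N_j) - delta N_i,    alpha_ii = 1,

where N_i is the density of species i normalized to its own carrying
capacity, r_i its maximum growth rate (per hour), alpha_ij the dimensionless
inhibition of species i by species j, and delta a per-capita mortality rate
applied equally to all species.

Mortality can act in two experimentally motivated modes:

* ``continuous-death``: delta appears directly in the ODE.
* ``serial-dilution``: growth proceeds with delta = 0 for a fixed cycle
  (default 24 h), then every density is divided by a dilution factor DF.
  Equal per-cycle survival forces the correspondence delta = ln(DF) / T.

Trajectories record post-growth (pre-dilution) states, which is when a
serial-dilution experiment plates its cultures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import (
    ContractViolation,
    DataError,
    DegenerateEquilibria,
    NumericalError,
)

__all__ = [
    "CommunityParams",
    "Protocol",
    "Trajectory",
    "FixedPoint",
    "lv_derivatives",
    "integrate_cycle",
    "run_serial_dilution",
    "run_continuous",
    "monoculture_equilibrium",
    "pair_fixed_points",
]

#: default normalized density below which a species is declared extinct
EXTINCTION_THRESHOLD = 1e-10


@dataclass(frozen=True)
class CommunityParams:
    """Ground-truth parameters of an n-species competitive community.

    Attributes
    ----------
    species_ids : tuple of str
        Labels, one per species.
    growth_rates : ndarray, shape (n,)
        Maximum growth rates r_i (per hour), all > 0.
    alpha : ndarray, shape (n, n)
        Competition matrix; alpha[i, j] is the inhibition of species i by
        species j. Diagonal entries are exactly 1 (self-inhibition is the
        -N_i term of the model).
    """

    species_ids: tuple
    growth_rates: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.species_ids)
        r = np.asarray(self.growth_rates, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "growth_rates", r)
        object.__setattr__(self, "alpha", a)
        n = len(ids)
        if len(set(ids)) != n:
            raise ContractViolation("species_ids must be unique")
        if r.shape != (n,):
            raise ContractViolation(
                f"growth_rates shape {r.shape} does not match {n} species"
            )
        if a.shape != (n, n):
            raise ContractViolation(
                f"alpha shape {a.shape} does not match {n} species"
            )
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ContractViolation("all growth rates must be finite and > 0")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ContractViolation("all alpha_ij must be finite and >= 0")
        if not np.allclose(np.diag(a), 1.0, rtol=0, atol=0):
            raise ContractViolation("alpha diagonal must equal 1 exactly")

    @property
    def n(self) -> int:
        return len(self.species_ids)

    def index(self, species) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise ContractViolation(f"unknown species {species!r}") from None

    def subset(self, species: Sequence) -> "CommunityParams":
        """Restrict the community to the given species (order preserved)."""
        idx = [self.index(s) for s in species]
        return CommunityParams(
            species_ids=tuple(self.species_ids[i] for i in idx),
            growth_rates=self.growth_rates[idx],
            alpha=self.alpha[np.ix_(idx, idx)],
        )

    def pair(self, a, b) -> "CommunityParams":
        """Two-species restriction, species ``a`` first."""
        return self.subset([a, b])

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": list(self.species_ids),
            "growth_rates": [float(x) for x in self.growth_rates],
            "alpha": [[float(x) for x in row] for row in self.alpha],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityParams":
        missing = {"species", "growth_rates", "alpha"} - set(d)
        if missing:
            raise DataError(f"community params missing keys: {sorted(missing)}")
        return cls(
            species_ids=tuple(d["species"]),
            growth_rates=np.asarray(d["growth_rates"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise DataError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)


@dataclass(frozen=True)
class Protocol:
    """How mortality is applied and for how long dynamics are run.

    Exactly one of ``delta`` (continuous-death mode) or ``dilution_factor``
    (serial-dilution mode) governs mortality, selected by ``mode``.
    """

    mode: str  # "serial-dilution" | "continuous-death"
    delta: float | None = None
    dilution_factor: float | None = None
    cycle_hours: float = 24.0
    n_cycles: int = 7
    extinction_threshold: float = EXTINCTION_THRESHOLD
    rtol: float = 1e-8
    atol: float = 1e-12
    max_hours: float = 5000.0  # continuous mode horizon

    def __post_init__(self):
        if self.mode not in ("serial-dilution", "continuous-death"):
            raise ContractViolation(f"unknown protocol mode {self.mode!r}")
        if self.cycle_hours <= 0:
            raise ContractViolation("cycle_hours must be > 0")
        if not (0 < self.extinction_threshold < 1e-2):
            raise ContractViolation("extinction_threshold must be in (0, 1e-2)")
        if self.mode == "serial-dilution":
            if self.dilution_factor is None or self.dilution_factor < 1:
                raise ContractViolation("serial-dilution mode needs dilution_factor >= 1")
        else:
            if self.delta is None or self.delta < 0:
                raise ContractViolation("continuous-death mode needs delta >= 0")


@dataclass
class Trajectory:
    """Time series of normalized densities.

    ``times`` are hours for continuous runs and cycle indices (1-based,
    post-growth) for serial-dilution runs. ``densities`` has one row per
    recorded time, one column per species.
    """

    species_ids: tuple
    times: np.ndarray
    densities: np.ndarray
    mode: str
    converged: bool = False

    @property
    def fractions(self) -> np.ndarray:
        tot = self.densities.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.densities / np.where(tot > 0, tot, 1.0), 0.0)
        return f

    @property
    def final_densities(self) -> np.ndarray:
        return self.densities[-1]

    def survivors(self, threshold: float = 0.0) -> frozenset:
        return frozenset(
            s for s, d in zip(self.species_ids, self.final_densities) if d > threshold
        )

    def to_dataframe(self, condition_id: str = ""):
        import pandas as pd

        rows = []
        frac = self.fractions
        for t, dens, fr in zip(self.times, self.densities, frac):
            for s, d, f in zip(self.species_ids, dens, fr):
                rows.append(
                    {
                        "condition_id": condition_id,
                        "cycle": t,
                        "species": s,
                        "density": d,
                        "fraction": f,
                    }
                )
        return pd.DataFrame(rows)


def lv_derivatives(
    params: CommunityParams, N: np.ndarray, delta: float
) -> np.ndarray:
    """Right-hand side of the mortality-augmented LV model.

    Returns r_i N_i (1 - sum_j alpha_ij N_j) - delta N_i per species; a
    species at zero density has exactly zero rate.
    """
    N = np.asarray(N, dtype=float)
    if N.shape != (params.n,):
        raise ContractViolation(
            f"density vector shape {N.shape} does not match {params.n} species"
        )
    if delta < 0:
        raise ContractViolation("delta must be >= 0")
    return params.growth_rates * N * (1.0 - params.alpha @ N) - delta * N


def integrate_cycle(
    params: CommunityParams,
    N0: np.ndarray,
    hours: float,
    delta: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the model for a fixed interval and return the final state.

    Uses an adaptive, stiffness-switching integrator (LSODA): competitive
    exclusions drive densities toward zero and the solution must not
    oscillate numerically there. Extinct (zero) species stay exactly zero.
    """
    N0 = np.asarray(N0, dtype=float)
    if N0.shape != (params.n,):
        raise ContractViolation("N0 dimension mismatch")
    if np.any(N0 < 0):
        raise ContractViolation("initial densities must be >= 0")
    if hours <= 0:
        raise ContractViolation("hours must be > 0")
    alive = N0 > 0
    if not alive.any():
        return np.zeros_like(N0)

    r = params.growth_rates
    a = params.alpha

    def rhs(_t, y):
        y = np.maximum(y, 0.0)
        return r * y * (1.0 - a @ y) - delta * y

    sol = solve_ivp(
        rhs,
        (0.0, float(hours)),
        N0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(
            f"LSODA failed after t={sol.t[-1]:.3g} h (of {hours} h): {sol.message}"
        )
    out = np.maximum(sol.y[:, -1], 0.0)
    out[~alive] = 0.0  # extinction is absorbing
    if not np.all(np.isfinite(out)):
        raise NumericalError("integrator produced non-finite densities")
    return out


def run_serial_dilution(
    params: CommunityParams,
    N0: np.ndarray,
    protocol: Protocol,
    stop_on_convergence: bool = False,
    convergence_tol: float = 1e-9,
) -> Trajectory:
    """Simulate growth/dilution cycles.

    Each cycle integrates the model with delta = 0 for ``cycle_hours``,
    records the post-growth state, then divides all densities by the
    dilution factor and zeroes anything below the extinction threshold.

    With ``stop_on_convergence`` the run ends early once the post-growth
    state changes by less than ``convergence_tol`` (sup norm) between
    consecutive cycles; the returned trajectory is marked converged. The
    default 7-cycle run also reports convergence of the composition
    (change < 1e-4 in sup norm across the final 3 cycles).
    """
    if protocol.mode != "serial-dilution":
        raise ContractViolation("protocol.mode must be 'serial-dilution'")
    df = float(protocol.dilution_factor)
    N = np.asarray(N0, dtype=float).copy()
    if np.any(N < 0):
        raise ContractViolation("initial densities must be >= 0")
    N[N < protocol.extinction_threshold] = 0.0

    states = []
    converged = False
    for cycle in range(1, protocol.n_cycles + 1):
        N = integrate_cycle(
            params, N, protocol.cycle_hours, 0.0, protocol.rtol, protocol.atol
        )
        states.append(N.copy())
        if stop_on_convergence and len(states) >= 2:
            if np.max(np.abs(states[-1] - states[-2])) < convergence_tol:
                converged = True
                break
        N = N / df
        N[N < protocol.extinction_threshold] = 0.0

    dens = np.array(states)
    times = np.arange(1, len(states) + 1, dtype=float)
    traj = Trajectory(
        species_ids=params.species_ids,
        times=times,
        densities=dens,
        mode="serial-dilution",
        converged=converged,
    )
    if not stop_on_convergence and len(states) >= 3:
        frac = traj.fractions
        window = frac[-3:]
        traj.converged = bool(np.max(window.max(0) - window.min(0)) < 1e-4)
    return traj


def run_continuous(
    params: CommunityParams,
    N0: np.ndarray,
    protocol: Protocol,
    check_hours: float = 50.0,
    convergence_tol: float = 1e-9,
) -> Trajectory:
    """Integrate the continuous-death model until convergence or max_hours.

    The state is checkpointed every ``check_hours``; the run is converged
    when the density vector changes by less than ``convergence_tol`` (sup
    norm) between checkpoints. The extinction threshold is applied at each
    checkpoint so asymptotic exclusions resolve in finite time.
    """
    if protocol.mode != "continuous-death":
        raise ContractViolation("protocol.mode must be 'continuous-death'")
    delta = float(protocol.delta)
    N = np.asarray(N0, dtype=float).copy()
    if np.any(N < 0):
        raise ContractViolation("initial densities must be >= 0")
    N[N < protocol.extinction_threshold] = 0.0

    times = [0.0]
    states = [N.copy()]
    t = 0.0
    converged = False
    while t < protocol.max_hours:
        step = min(check_hours, protocol.max_hours - t)
        N = integrate_cycle(params, N, step, delta, protocol.rtol, protocol.atol)
        N[N < protocol.extinction_threshold] = 0.0
        t += step
        times.append(t)
        states.append(N.copy())
        if np.max(np.abs(states[-1] - states[-2])) < convergence_tol:
            converged = True
            break
    return Trajectory(
        species_ids=params.species_ids,
        times=np.array(times),
        densities=np.array(states),
        mode="continuous-death",
        converged=converged,
    )


def monoculture_equilibrium(r: float, delta: float) -> float:
    """Equilibrium normalized density of a single species: max(0, 1 - delta/r)."""
    if r <= 0:
        raise ContractViolation("r must be > 0")
    if delta < 0:
        raise ContractViolation("delta must be >= 0")
    return max(0.0, 1.0 - delta / r)


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the two-species system with its linear stability."""

    densities: np.ndarray
    stable: bool
    kind: str  # "origin" | "boundary-1" | "boundary-2" | "interior"


def _jacobian(params: CommunityParams, N: np.ndarray, delta: float) -> np.ndarray:
    r, a = params.growth_rates, params.alpha
    s = a @ N
    J = -(r * N)[:, None] * a
    J[np.diag_indices_from(J)] += r * (1.0 - s) - delta
    return J


def pair_fixed_points(
    params: CommunityParams,
    delta: float,
    degenerate_tol: float = 1e-9,
) -> list[FixedPoint]:
    """All candidate equilibria of a two-species community at mortality delta.

    Returns the origin, the two boundary (monoculture) points with positive
    density, and the interior point when it exists in the positive quadrant,
    each flagged stable/unstable by linearization. The interior point, in
    mortality-rescaled units, is N~_i = (1 - a~_ij) / (1 - a~_ij a~_ji),
    mapped back through N_i = N~_i (1 - delta/r_i).

    Raises
    ------
    DegenerateEquilibria
        If a~_12 * a~_21 = 1 (a line of fixed points; no discrete answer).
    """
    if params.n != 2:
        raise ContractViolation("pair_fixed_points requires exactly 2 species")
    if delta < 0:
        raise ContractViolation("delta must be >= 0")
    r = params.growth_rates

    def stab(N):
        eig = np.linalg.eigvals(_jacobian(params, N, delta))
        return bool(np.all(eig.real < 0))

    pts = [FixedPoint(np.zeros(2), stab(np.zeros(2)), "origin")]
    for i in (0, 1):
        ni = monoculture_equilibrium(r[i], delta)
        if ni > 0:
            N = np.zeros(2)
            N[i] = ni
            pts.append(FixedPoint(N, stab(N), f"boundary-{i + 1}"))

    if delta < r.min():
        # interior point via the rescaled (effective) coefficients
        from .phase_analysis import effective_alpha

        eff = effective_alpha(params, delta)
        a12, a21 = eff.alpha_eff[0, 1], eff.alpha_eff[1, 0]
        prod = a12 * a21
        if abs(prod - 1.0) < degenerate_tol:
            raise DegenerateEquilibria(
                f"alpha_eff product {prod:.12g} is within {degenerate_tol} of 1: "
                "continuum of fixed points"
            )
        n1t = (1.0 - a12) / (1.0 - prod)
        n2t = (1.0 - a21) / (1.0 - prod)
        if n1t > 0 and n2t > 0:
            N = np.array([n1t * eff.rescale[0], n2t * eff.rescale[1]])
            pts.append(FixedPoint(N, stab(N), "interior"))
    return pts
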