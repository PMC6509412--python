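"""Synthetic communities and simulated serial-dilution experiments.

The generator produces ground-truth LV communities exhibiting (by default)
a growth/competitive-ability tradeoff -- slower growers carry larger
incoming advantages, so they dominate pairwise competition at low mortality
and lose it at high mortality -- and then emulates the laboratory design:
six dilution factors from 10 to 10^6, 24-hour growth cycles, seven cycles,
starting compositions that are either an even split or 90% dominance of one
species, and endpoint plating that counts on average ~42 colonies, drawn
multinomially. Every random draw flows from a single root seed, so a given
seed reproduces tables byte for byte.

Observed fractions weight the model's normalized densities by each species'
absolute carrying capacity (plating counts cells; the model's N_i does
not), a deliberate model/observation mismatch that lets the analysis be
tested for robustness; a switch turns the weighting off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ContractViolation, DataError
from .lv_dynamics import CommunityParams, Protocol, run_serial_dilution

__all__ = [
    "GroundTruth",
    "DesignSpec",
    "sample_params",
    "condition_is_resolvable",
    "community_starting_compositions",
    "simulate_experiment",
    "simulate_pairwise_experiments",
    "simulate_community_experiment",
    "simulate_monocultures",
    "simulate_od_curves",
]


@dataclass(frozen=True)
class GroundTruth:
    """A generated community plus everything the experiments cannot observe."""

    params: CommunityParams
    carrying_capacities: np.ndarray  # absolute densities K_i (CFU/ml)
    lags: np.ndarray  # lag times (hours)
    od_plateaus: np.ndarray  # monoculture OD600 saturation levels
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("carrying_capacities", "lags", "od_plateaus"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (self.params.n,):
                raise ContractViolation(f"{name} must have one entry per species")
        if np.any(self.carrying_capacities <= 0):
            raise ContractViolation("carrying capacities must be > 0")

    def to_dict(self) -> dict:
        return {
            "community": self.params.to_dict(),
            "carrying_capacities": [float(x) for x in self.carrying_capacities],
            "lags": [float(x) for x in self.lags],
            "od_plateaus": [float(x) for x in self.od_plateaus],
            "seed": self.seed,
            "settings": dict(self.settings),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls(
                params=CommunityParams.from_dict(d["community"]),
                carrying_capacities=d["carrying_capacities"],
                lags=d["lags"],
                od_plateaus=d["od_plateaus"],
                seed=d.get("seed"),
                settings=d.get("settings", {}),
            )
        except KeyError as e:
            raise DataError(f"ground-truth file missing key {e}") from None


@dataclass(frozen=True)
class DesignSpec:
    """The serial-dilution experimental design being emulated.

    Defaults mirror the laboratory protocol: dilution factors 10-10^6,
    24-h cycles for 7 days, pair starting fractions {0.05, 0.5, 0.95},
    multispecies starts of an even split plus one 90%-dominant start per
    species, and a mean of 42 colonies counted per plating (totals drawn
    Poisson unless ``mean_colonies`` is None, which records exact
    fractions). Day 0 inocula are prediluted by the condition's dilution
    factor, capped at 10^5 so the harshest condition does not start with a
    stochastic extinction.
    """

    dilution_factors: tuple = (1e1, 1e2, 1e3, 1e4, 1e5, 1e6)
    cycle_hours: float = 24.0
    n_cycles: int = 7
    replicates: int = 2
    pair_starts: tuple = (0.05, 0.5, 0.95)
    dominant_fraction: float = 0.90
    mean_colonies: float | None = 42.0
    day0_max_dilution: float = 1e5
    stock_density: float = 0.5  # normalized density of the equalized stock
    abundance_weighting: bool = True
    extinction_threshold: float = 1e-10
    # OD-curve leg of the design
    stock_od: float = 0.5
    od_dilutions: tuple = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
    od_span_hours: float = 50.0
    od_step_hours: float = 0.25

    def __post_init__(self):
        if any(df < 1 for df in self.dilution_factors):
            raise ContractViolation("dilution factors must be >= 1")
        if not (0 < self.dominant_fraction < 1):
            raise ContractViolation("dominant_fraction must be in (0, 1)")
        if self.n_cycles < 1 or self.replicates < 1:
            raise ContractViolation("n_cycles and replicates must be >= 1")


def sample_params(
    n_species: int,
    tradeoff: float = 2.5,
    noise: float = 0.35,
    seed: int | None = None,
    r_range: tuple = (0.25, 1.0),
    alpha_scale: float = 0.75,
    k_range: tuple = (5e8, 5e9),
    lag_range: tuple = (0.5, 4.0),
    od_plateau_range: tuple = (2.5, 3.5),
) -> GroundTruth:
    """Draw a ground-truth community with a tunable growth/competition tradeoff.

    Growth rates are log-uniform on ``r_range``. Off-diagonal competition
    coefficients are alpha_ij = alpha_scale * exp(tradeoff * (r_i - r_j) +
    eps_ij) with eps ~ Normal(0, noise): a positive ``tradeoff`` makes
    faster growers suffer stronger incoming inhibition from slower ones
    (slow-grower dominance at zero mortality), while tradeoff = 0 gives
    tradeoff-free controls. Carrying capacities, lags and OD plateaus are
    log-/uniform draws on their configured ranges.
    """
    if n_species < 2:
        raise ContractViolation("need at least 2 species")
    if tradeoff < 0 or noise < 0:
        raise ContractViolation("tradeoff and noise must be >= 0")
    rng = np.random.default_rng(seed)
    r = np.exp(rng.uniform(np.log(r_range[0]), np.log(r_range[1]), n_species))
    eps = rng.normal(0.0, noise, (n_species, n_species)) if noise > 0 else np.zeros(
        (n_species, n_species)
    )
    alpha = alpha_scale * np.exp(tradeoff * (r[:, None] - r[None, :]) + eps)
    np.fill_diagonal(alpha, 1.0)
    K = np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]), n_species))
    lags = rng.uniform(*lag_range, n_species)
    plateaus = rng.uniform(*od_plateau_range, n_species)
    ids = tuple(f"sp{i + 1}" for i in range(n_species))
    return GroundTruth(
        params=CommunityParams(ids, r, alpha),
        carrying_capacities=K,
        lags=lags,
        od_plateaus=plateaus,
        seed=seed,
        settings={
            "tradeoff": tradeoff,
            "noise": noise,
            "r_range": list(r_range),
            "alpha_scale": alpha_scale,
        },
    )


def condition_is_resolvable(
    truth: GroundTruth,
    a,
    b,
    delta: float,
    log_margin: float = 0.15,
    fraction_band: tuple = (0.10, 0.90),
    viability_margin: float = 0.08,
) -> bool:
    """Is a pair x mortality condition far enough from every outcome boundary
    for a finite 7-cycle, ~42-colony experiment to resolve it?

    Three boundaries matter. (1) Classification: both effective coefficients
    must sit at least ``log_margin`` away from 1 in log space. (2) Viability:
    mortality must differ from each growth rate by ``viability_margin``
    (absolute, per hour) so that a dying species actually crosses the
    extinction threshold -- and a viable one becomes detectable -- within the
    experiment's cycles. (3) Detectability of interior points: a coexistence
    fraction or bistable separatrix outside ``fraction_band`` (checked in
    both normalized-density and abundance-weighted units) is invisible to
    the standard starting fractions and colony totals. Conditions failing
    any check are boundary-adjacent; recovery benchmarks score only
    resolvable ones.
    """
    from .phase_analysis import classify_pair, effective_alpha

    p2 = truth.params.pair(a, b)
    r = p2.growth_rates
    if np.any(np.abs(delta - r) < viability_margin):
        return False
    if delta >= r.min():
        return True  # decided by viability alone, margin already checked
    eff = effective_alpha(p2, delta)
    a12, a21 = eff.alpha_eff[0, 1], eff.alpha_eff[1, 0]
    if min(abs(np.log(a12)), abs(np.log(a21))) <= log_margin:
        return False
    out = classify_pair(eff)
    if out.interior_fraction is not None:
        lo, hi = fraction_band
        if not (lo <= out.interior_fraction <= hi):
            return False
        K = np.array([truth.carrying_capacities[truth.params.index(s)] for s in (a, b)])
        n1 = (1 - a12) / (1 - a12 * a21) * eff.rescale[0] * K[0]
        n2 = (1 - a21) / (1 - a12 * a21) * eff.rescale[1] * K[1]
        if not (lo <= n1 / (n1 + n2) <= hi):
            return False
    return True


def community_starting_compositions(species) -> dict:
    """Even split plus one 90%-dominant start per species (90-5-5 pattern)."""
    species = list(species)
    n = len(species)
    starts = {"equal": np.full(n, 1.0 / n)}
    for i, sp in enumerate(species):
        v = np.full(n, 0.10 / (n - 1))
        v[i] = 0.90
        starts[f"{sp}-dominant"] = v
    return starts


def _observe_cycle(
    rng: np.random.Generator,
    densities: np.ndarray,
    K: np.ndarray,
    mean_colonies: float | None,
    abundance_weighting: bool,
):
    weights = densities * K if abundance_weighting else densities
    total_weight = weights.sum()
    if total_weight > 0:
        frac = weights / total_weight
    else:
        frac = np.zeros_like(weights)
    if mean_colonies is None:
        # exact-observation switch: record fractions at a huge fixed total
        counts = np.round(frac * 10**6).astype(int)
    else:
        total = rng.poisson(mean_colonies)
        counts = rng.multinomial(total, frac) if total_weight > 0 else np.zeros_like(
            weights, dtype=int
        )
    return counts, frac


def simulate_experiment(
    truth: GroundTruth,
    design: DesignSpec,
    seed: int | None = None,
    species_subset=None,
    starts: dict | None = None,
    condition_prefix: str = "",
) -> pd.DataFrame:
    """Simulate the full design for given species and starting compositions.

    For every dilution factor x start x replicate, initial densities follow
    the day-0 rule (composition times stock density, divided by the
    dilution factor capped at ``day0_max_dilution``), the community runs
    through ``n_cycles`` growth/dilution cycles, and each post-growth state
    is plated: fractions weighted by absolute abundance, colony totals
    Poisson around the design mean, counts multinomial. Returns the
    long-format experiment table (with ground-truth ``true_fraction`` and
    ``abs_density`` columns alongside the observable counts).
    """
    rng = np.random.default_rng(seed)
    subset = list(species_subset) if species_subset is not None else list(
        truth.params.species_ids
    )
    params = truth.params.subset(subset)
    K = np.array([truth.carrying_capacities[truth.params.index(s)] for s in subset])
    if starts is None:
        starts = community_starting_compositions(subset)
    rows = []
    for df_ in design.dilution_factors:
        protocol = Protocol(
            mode="serial-dilution",
            dilution_factor=df_,
            cycle_hours=design.cycle_hours,
            n_cycles=design.n_cycles,
            extinction_threshold=design.extinction_threshold,
        )
        day0 = min(df_, design.day0_max_dilution)
        for start_label, comp in starts.items():
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (len(subset),) or abs(comp.sum() - 1.0) > 1e-9:
                raise ContractViolation(
                    f"start {start_label!r} is not a composition over {subset}"
                )
            N0 = comp * design.stock_density / day0
            for rep in range(1, design.replicates + 1):
                traj = run_serial_dilution(params, N0, protocol)
                cond = f"{condition_prefix}DF{df_:g}|{start_label}|rep{rep}"
                for cyc, dens in zip(traj.times, traj.densities):
                    counts, frac = _observe_cycle(
                        rng, dens, K, design.mean_colonies, design.abundance_weighting
                    )
                    for s, c, f, d, k in zip(subset, counts, frac, dens, K):
                        rows.append(
                            {
                                "condition_id": cond,
                                "dilution_factor": df_,
                                "replicate": rep,
                                "starting_composition": start_label,
                                "cycle": int(cyc),
                                "species": s,
                                "colony_count": int(c),
                                "true_fraction": float(f),
                                "abs_density": float(d * k),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_pairwise_experiments(
    truth: GroundTruth, design: DesignSpec, seed: int | None = None
) -> pd.DataFrame:
    """All pairwise cocultures: every pair at every DF from each pair start."""
    rng = np.random.default_rng(seed)
    frames = []
    for a, b in itertools.combinations(truth.params.species_ids, 2):
        starts = {
            f"f{frac:g}": np.array([frac, 1.0 - frac]) for frac in design.pair_starts
        }
        frames.append(
            simulate_experiment(
                truth,
                design,
                seed=int(rng.integers(2**31)),
                species_subset=[a, b],
                starts=starts,
                condition_prefix=f"{a}-{b}|",
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_community_experiment(
    truth: GroundTruth,
    design: DesignSpec,
    seed: int | None = None,
    species_subset=None,
) -> pd.DataFrame:
    """The multispecies coculture leg (even + each-species-dominant starts)."""
    subset = list(species_subset) if species_subset is not None else list(
        truth.params.species_ids
    )
    label = "-".join(subset)
    return simulate_experiment(
        truth,
        design,
        seed=seed,
        species_subset=subset,
        condition_prefix=f"{label}|",
    )


def simulate_monocultures(
    truth: GroundTruth, design: DesignSpec, seed: int | None = None
) -> pd.DataFrame:
    """Monoculture controls at every DF (for carrying-capacity baselines)."""
    rng = np.random.default_rng(seed)
    frames = []
    for sp in truth.params.species_ids:
        frames.append(
            simulate_experiment(
                truth,
                design,
                seed=int(rng.integers(2**31)),
                species_subset=[sp],
                starts={"mono": np.array([1.0])},
                condition_prefix=f"{sp}|",
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_od_curves(
    truth: GroundTruth,
    design: DesignSpec,
    noise_sd: float = 0.002,
    seed: int | None = None,
    replicates: int = 2,
) -> pd.DataFrame:
    """Monoculture OD600 curves at 15-minute resolution over ~50 hours.

    Each curve sits flat at its starting OD for the species' lag, then
    grows logistically at the species' rate toward its OD plateau; Gaussian
    noise of SD ``noise_sd`` is added to every reading.
    """
    if noise_sd < 0:
        raise ContractViolation("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, design.od_span_hours + 1e-9, design.od_step_hours)
    rows = []
    for i, sp in enumerate(truth.params.species_ids):
        r = truth.params.growth_rates[i]
        lag = truth.lags[i]
        plateau = truth.od_plateaus[i]
        for dil in design.od_dilutions:
            od0 = design.stock_od * dil
            grow = np.clip(t - lag, 0.0, None)
            od = plateau / (1.0 + (plateau / od0 - 1.0) * np.exp(-r * grow))
            for rep in range(1, replicates + 1):
                noisy = od + rng.normal(0.0, noise_sd, od.shape) if noise_sd else od
                for ti, yi in zip(t, noisy):
                    rows.append(
                        {
                            "species": sp,
                            "replicate": rep,
                            "initial_dilution": dil,
                            "time_h": float(ti),
                            "od": float(yi),
                        }
                    )
    return pd.DataFrame(rows)
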