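"""Shared fixtures: worked parameter sets and the random-pair oracle ensemble."""

import numpy as np
import pytest

from dilucomp import CommunityParams
from dilucomp.lv_dynamics import Protocol, run_continuous, run_serial_dilution
from dilucomp.phase_analysis import Outcome, classify_pair, effective_alpha

CYCLE_HOURS = 24.0
ORACLE_STARTS = (0.05, 0.5, 0.95)
#: endpoint fraction above which a species counts as surviving in oracle runs
ORACLE_SURVIVAL_FRACTION = 1e-3


@pytest.fixture
def worked_pair():
    """Fast/slow pair in which the slow grower dominates without mortality
    and the competition-coefficient product is below one (coexistence
    window between critical mortalities 1/3 and 0.375)."""
    return CommunityParams(("fast", "slow"), [1.0, 0.5], [[1.0, 2.0], [0.4, 1.0]])


@pytest.fixture
def bistable_pair():
    """Same structure but coefficient product above one: the intermediate
    mortality window (1/6, 1/3) is bistable."""
    return CommunityParams(("fast", "slow"), [1.0, 0.5], [[1.0, 2.0], [0.8, 1.0]])


def oracle_survivors(traj) -> frozenset:
    frac = traj.fractions[-1]
    return frozenset(
        s for s, f in zip(traj.species_ids, frac) if f > ORACLE_SURVIVAL_FRACTION
    )


def brute_force_sets(params, delta, mode) -> set:
    """Survivor-set collection from simulations started at the oracle
    compositions (unit total density, where competition acts immediately)."""
    out = set()
    for f0 in ORACLE_STARTS:
        N0 = np.array([f0, 1.0 - f0])
        if mode == "continuous":
            traj = run_continuous(
                params, N0, Protocol(mode="continuous-death", delta=delta)
            )
        else:
            traj = run_serial_dilution(
                params,
                N0,
                Protocol(
                    mode="serial-dilution",
                    dilution_factor=float(np.exp(delta * CYCLE_HOURS)),
                    n_cycles=400,
                ),
                stop_on_convergence=True,
            )
        out.add(oracle_survivors(traj))
    return out


def draw_margin_condition(rng):
    """One random pair x mortality condition away from every outcome boundary.

    Margins: both |log alpha_eff| > 0.1; any interior-point fraction inside
    [0.10, 0.90]; (r_i - delta) * T >= 5 for both species (distance from the
    viability bifurcation, where the discrete and continuous processes
    genuinely part ways); and for bistable conditions delta <= 0.35 min r so
    the two processes' separatrices stay within the probed starts.
    Returns (params, delta, analytic PairOutcome) or None for a reject.
    """
    r = rng.uniform(0.2, 1.5, 2)
    alpha = np.exp(rng.uniform(np.log(0.1), np.log(10.0), 2))
    params = CommunityParams(
        ("s1", "s2"), r, [[1.0, alpha[0]], [alpha[1], 1.0]]
    )
    dmax = min(r.min() - 5.0 / CYCLE_HOURS, 0.576)
    if dmax <= 0.03:
        return None
    delta = rng.uniform(0.02, dmax)
    eff = effective_alpha(params, delta)
    a12, a21 = eff.alpha_eff[0, 1], eff.alpha_eff[1, 0]
    if min(abs(np.log(a12)), abs(np.log(a21))) <= 0.1:
        return None
    outcome = classify_pair(eff)
    if outcome.interior_fraction is not None and not (
        0.10 <= outcome.interior_fraction <= 0.90
    ):
        return None
    if outcome.category is Outcome.BISTABILITY and delta > 0.35 * r.min():
        return None
    return params, delta, outcome


@pytest.fixture(scope="session")
def pair_ensemble():
    """220 margin-filtered random conditions with brute-force survivor sets
    from both mortality modes (shared by the oracle-equivalence checks)."""
    rng = np.random.default_rng(20)
    conditions = []
    while len(conditions) < 220:
        drawn = draw_margin_condition(rng)
        if drawn is None:
            continue
        params, delta, outcome = drawn
        conditions.append(
            {
                "params": params,
                "delta": delta,
                "outcome": outcome,
                "continuous_sets": brute_force_sets(params, delta, "continuous"),
                "serial_sets": brute_force_sets(params, delta, "serial"),
            }
        )
    return conditions
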