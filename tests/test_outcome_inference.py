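"""Endpoint composition estimates and outcome calls from colony counts."""

import numpy as np
import pandas as pd
import pytest

from dilucomp import CommunityParams, GroundTruth
from dilucomp.errors import ContractViolation, DataError
from dilucomp.metrics import beta_sd
from dilucomp.outcome_inference import (
    call_community_state,
    call_pair_outcome,
    endpoint_fractions,
    subway_table,
)
from dilucomp.phase_analysis import Outcome, classify_pair_at, dilution_to_delta
from dilucomp.synthetic_data import DesignSpec, simulate_experiment


def make_table(counts_by_condition, dilution_factor=100.0):
    """Build an experiment table from {(start, replicate): [per-cycle {species: count}]}."""
    rows = []
    for (start, rep), cycles in counts_by_condition.items():
        cond = f"DF{dilution_factor:g}|{start}|rep{rep}"
        for cyc, counts in enumerate(cycles, start=1):
            for sp, c in counts.items():
                rows.append(
                    {
                        "condition_id": cond,
                        "dilution_factor": dilution_factor,
                        "replicate": rep,
                        "starting_composition": start,
                        "cycle": cyc,
                        "species": sp,
                        "colony_count": c,
                    }
                )
    return pd.DataFrame(rows)


def steady(counts, n_cycles=7):
    return [dict(counts)] * n_cycles


class TestEndpointFractions:
    def test_even_split_symmetric(self):
        table = make_table({("equal", 1): steady({"A": 21, "B": 21})})
        out = endpoint_fractions(table)
        assert set(out["fraction"]) == {0.5}
        assert out["beta_sd"].nunique() == 1

    def test_total_sweep_with_shutout(self):
        table = make_table({("equal", 1): steady({"A": 42, "B": 0})})
        out = endpoint_fractions(table).set_index("species")
        assert out.loc["A", "fraction"] == 1.0
        assert out.loc["A", "beta_sd"] == pytest.approx(beta_sd(42, 0))
        assert out.loc["B", "beta_sd"] == pytest.approx(beta_sd(0, 42))

    def test_trio_errors_pool_all_other_species(self):
        table = make_table({("equal", 1): steady({"A": 10, "B": 20, "C": 12})})
        out = endpoint_fractions(table).set_index("species")
        np.testing.assert_allclose(
            out["fraction"][list("ABC")], np.array([10, 20, 12]) / 42
        )
        assert out.loc["A", "beta_sd"] == pytest.approx(beta_sd(10, 32))

    def test_zero_total_flagged_unusable(self):
        table = make_table({("equal", 1): steady({"A": 0, "B": 0})})
        out = endpoint_fractions(table)
        assert not out["usable"].any()
        assert out["fraction"].isna().all()

    def test_moving_fractions_not_converged(self):
        cycles = [{"A": c, "B": 42 - c} for c in (5, 10, 15, 21, 27, 33, 40)]
        table = make_table({("equal", 1): cycles})
        out = endpoint_fractions(table)
        assert not out["converged"].any()


def _pair_truth(params, k=(1e9, 1e9)):
    return GroundTruth(
        params=params,
        carrying_capacities=np.asarray(k),
        lags=np.zeros(2),
        od_plateaus=np.full(2, 2.0),
        seed=0,
    )


def simulate_pair_at(params, dilution_factor, seed=0, replicates=2):
    design = DesignSpec(dilution_factors=(dilution_factor,), replicates=replicates)
    starts = {f"f{f:g}": np.array([f, 1 - f]) for f in design.pair_starts}
    return simulate_experiment(
        _pair_truth(params), design, seed=seed, starts=starts
    )


class TestCallPairOutcome:
    def test_clean_exclusion(self):
        table = make_table(
            {
                (s, 1): steady({"A": 42, "B": 0})
                for s in ("f0.05", "f0.5", "f0.95")
            }
        )
        call = call_pair_outcome(table)
        assert call.category is Outcome.EXCLUSION_1
        assert call.survivor_sets == [frozenset({"A"})]

    def test_coexistence_recovers_interior_fraction(self):
        # robustly coexisting pair at modest relative mortality (DF 100)
        pair = CommunityParams(("a", "b"), [1.0, 0.8], [[1.0, 0.6], [0.5, 1.0]])
        df = 100.0
        delta = dilution_to_delta(df)
        assert classify_pair_at(pair, delta).category is Outcome.COEXISTENCE
        call = call_pair_outcome(simulate_pair_at(pair, df, seed=5))
        # expected stable fraction: the generating process's own equilibrium
        from dilucomp.lv_dynamics import Protocol, run_serial_dilution

        traj = run_serial_dilution(
            pair,
            np.array([0.5, 0.5]),
            Protocol(mode="serial-dilution", dilution_factor=df, n_cycles=400),
            stop_on_convergence=True,
        )
        expected = traj.fractions[-1][0]
        assert 0.05 < expected < 0.95
        assert call.category is Outcome.COEXISTENCE
        assert call.stable_fraction == pytest.approx(expected, abs=0.08)
        assert call.stable_fraction_sd is not None

    def test_bistability_from_divergent_starts(self, bistable_pair):
        delta = 0.25  # inside the bistable window
        df = float(np.exp(delta * 24))
        call = call_pair_outcome(simulate_pair_at(bistable_pair, df, seed=11))
        assert call.category is Outcome.BISTABILITY
        assert frozenset({"fast"}) in call.survivor_sets
        assert frozenset({"slow"}) in call.survivor_sets
        assert not call.non_LV

    def test_mixed_coexistence_exclusion_flagged_non_lv(self):
        table = make_table(
            {
                ("f0.05", 1): steady({"A": 30, "B": 12}),
                ("f0.95", 1): steady({"A": 42, "B": 0}),
            }
        )
        call = call_pair_outcome(table)
        assert call.category is Outcome.BISTABILITY
        assert call.non_LV

    def test_slow_exclusion_transient_not_called_bistable(self):
        # start favoring B shows B still falling steadily at endpoint while
        # the other starts already resolved: an exclusion in progress
        declining = [
            {"A": int(42 * f), "B": 42 - int(42 * f)}
            for f in (0.10, 0.20, 0.35, 0.50, 0.65, 0.78, 0.88)
        ]
        table = make_table(
            {
                ("f0.05", 1): steady({"A": 42, "B": 0}),
                ("f0.5", 1): steady({"A": 42, "B": 0}),
                ("f0.95", 1): declining,
            }
        )
        call = call_pair_outcome(table)
        assert call.survivor_sets == [frozenset({"A"})]
        assert call.category is Outcome.EXCLUSION_1

    def test_replicate_disagreement_flagged(self):
        table = make_table(
            {
                ("f0.05", 1): steady({"A": 42, "B": 0}),
                ("f0.05", 2): steady({"A": 12, "B": 30}),
                ("f0.95", 1): steady({"A": 42, "B": 0}),
                ("f0.95", 2): steady({"A": 42, "B": 0}),
            }
        )
        call = call_pair_outcome(table)
        assert call.ambiguous
        assert "disagree" in call.notes

    def test_needs_two_starts(self):
        table = make_table({("f0.5", 1): steady({"A": 21, "B": 21})})
        with pytest.raises(ContractViolation):
            call_pair_outcome(table)


class TestCallCommunityState:
    def test_single_dominant_state(self):
        table = make_table(
            {
                (s, 1): steady({"A": 42, "B": 0, "C": 0})
                for s in ("equal", "A-dom", "B-dom", "C-dom")
            }
        )
        call = call_community_state(table)
        assert call.survivor_sets == [frozenset({"A"})]

    def test_two_stable_states_reported(self):
        table = make_table(
            {
                ("A-dom", 1): steady({"A": 30, "B": 12, "C": 0}),
                ("C-dom", 1): steady({"A": 28, "B": 0, "C": 14}),
            }
        )
        call = call_community_state(table)
        assert frozenset({"A", "B"}) in call.survivor_sets
        assert frozenset({"A", "C"}) in call.survivor_sets

    def test_coexisting_triplet_single_state(self):
        table = make_table(
            {
                (s, 1): steady({"A": 15, "B": 14, "C": 13})
                for s in ("equal", "A-dom")
            }
        )
        call = call_community_state(table)
        assert call.survivor_sets == [frozenset({"A", "B", "C"})]


class TestSubwayTable:
    def test_long_format_with_state_indices(self):
        table_lo = make_table(
            {("equal", 1): steady({"A": 0, "B": 42})}, dilution_factor=10
        )
        table_hi = make_table(
            {
                ("A-dom", 1): steady({"A": 42, "B": 0}),
                ("B-dom", 1): steady({"A": 0, "B": 42}),
            },
            dilution_factor=1000,
        )
        calls = {
            10: call_community_state(table_lo),
            1000: call_pair_outcome(table_hi),
        }
        sub = subway_table(calls, ["A", "B"])
        assert set(sub.columns) == {
            "dilution_factor",
            "state_index",
            "species",
            "present",
        }
        assert sub[sub["dilution_factor"] == 1000]["state_index"].max() == 1
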