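"""Dynamics engine: derivatives, integration, serial dilution, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilucomp import CommunityParams
from dilucomp.errors import ContractViolation, DegenerateEquilibria
from dilucomp.lv_dynamics import (
    Protocol,
    integrate_cycle,
    lv_derivatives,
    monoculture_equilibrium,
    pair_fixed_points,
    run_continuous,
    run_serial_dilution,
)


@pytest.fixture
def fast_dominant_pair():
    # fast grower is also the stronger competitor: no outcome change with mortality
    return CommunityParams(("fast", "slow"), [1.0, 0.5], [[1.0, 0.4], [2.0, 1.0]])


class TestDerivatives:
    def test_monoculture_fixed_point(self):
        p = CommunityParams(("a",), [1.0], [[1.0]])
        assert lv_derivatives(p, np.array([0.75]), 0.25) == pytest.approx(0.0)

    def test_extinction_is_absorbing(self, fast_dominant_pair):
        rates = lv_derivatives(fast_dominant_pair, np.zeros(2), 0.3)
        assert np.all(rates == 0.0)

    def test_hand_evaluated_two_species(self, fast_dominant_pair):
        # r=(1, 0.5), alpha_12=0.4, alpha_21=2, delta=0, N=(0.5, 0.2):
        # dN1 = 1*0.5*(1 - 0.5 - 0.4*0.2) = 0.21
        # dN2 = 0.5*0.2*(1 - 2*0.5 - 0.2) = -0.02
        rates = lv_derivatives(fast_dominant_pair, np.array([0.5, 0.2]), 0.0)
        assert rates == pytest.approx([0.21, -0.02])

    def test_dimension_mismatch_rejected(self, fast_dominant_pair):
        with pytest.raises(ContractViolation):
            lv_derivatives(fast_dominant_pair, np.array([0.1]), 0.0)


class TestCommunityParams:
    def test_diagonal_must_be_one(self):
        with pytest.raises(ContractViolation):
            CommunityParams(("a", "b"), [1, 1], [[1.0, 0.5], [0.5, 0.9]])

    def test_rates_positive(self):
        with pytest.raises(ContractViolation):
            CommunityParams(("a", "b"), [1, -0.1], [[1, 0.5], [0.5, 1]])

    def test_yaml_round_trip(self, tmp_path, fast_dominant_pair):
        path = tmp_path / "params.yaml"
        fast_dominant_pair.to_yaml(path)
        back = CommunityParams.from_yaml(path)
        assert back.species_ids == fast_dominant_pair.species_ids
        np.testing.assert_allclose(back.alpha, fast_dominant_pair.alpha)


class TestIntegrateCycle:
    def test_carrying_capacity_is_fixed(self):
        p = CommunityParams(("a",), [1.0], [[1.0]])
        assert integrate_cycle(p, np.array([1.0]), 48.0) == pytest.approx(1.0)

    def test_logistic_limit(self):
        p = CommunityParams(("a",), [1.0], [[1.0]])
        out = integrate_cycle(p, np.array([0.01]), 200.0)
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_mortality_equilibrium_closed_form(self):
        p = CommunityParams(("a",), [1.0], [[1.0]])
        out = integrate_cycle(p, np.array([0.9]), 300.0, delta=0.25)
        assert out[0] == pytest.approx(0.75, abs=1e-6)


class TestMonocultureEquilibrium:
    @pytest.mark.parametrize(
        "r,delta,expected", [(1.0, 0.0, 1.0), (1.0, 1.5, 0.0), (0.5, 0.125, 0.75)]
    )
    def test_closed_form(self, r, delta, expected):
        assert monoculture_equilibrium(r, delta) == pytest.approx(expected)

    def test_continuous_run_matches_closed_form_on_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            r = rng.uniform(0.3, 1.5)
            delta = rng.uniform(0.0, 1.2 * r)
            p = CommunityParams(("a",), [r], [[1.0]])
            traj = run_continuous(
                p, np.array([0.5]), Protocol(mode="continuous-death", delta=delta)
            )
            assert traj.final_densities[0] == pytest.approx(
                monoculture_equilibrium(r, delta), abs=1e-6
            )


class TestSerialDilution:
    def test_df_one_is_pure_growth(self, fast_dominant_pair):
        prot = Protocol(mode="serial-dilution", dilution_factor=1.0, n_cycles=3)
        traj = run_serial_dilution(fast_dominant_pair, np.array([0.01, 0.01]), prot)
        direct = integrate_cycle(fast_dominant_pair, np.array([0.01, 0.01]), 72.0)
        np.testing.assert_allclose(traj.final_densities, direct, rtol=1e-6)

    def test_monoculture_extinct_when_growth_below_dilution(self):
        # r < ln(DF)/T: per-cycle multiplication e^{rT}/DF < 1
        p = CommunityParams(("a",), [0.2], [[1.0]])
        prot = Protocol(mode="serial-dilution", dilution_factor=1e4, n_cycles=20)
        traj = run_serial_dilution(p, np.array([0.5]), prot)
        assert traj.final_densities[0] == 0.0

    def test_fast_grower_wins_at_high_dilution(self, fast_dominant_pair):
        prot = Protocol(mode="serial-dilution", dilution_factor=1e5, n_cycles=30)
        traj = run_serial_dilution(
            fast_dominant_pair, np.array([5e-6, 5e-6]), prot, stop_on_convergence=True
        )
        assert traj.survivors() == {"fast"}

    def test_dilution_factor_below_one_rejected(self):
        with pytest.raises(ContractViolation):
            Protocol(mode="serial-dilution", dilution_factor=0.5)

    @settings(max_examples=15, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        df=st.floats(1.0, 1e6),
    )
    def test_positivity_and_absorbing_extinction(self, seed, df):
        rng = np.random.default_rng(seed)
        n = 3
        alpha = np.exp(rng.normal(0, 0.7, (n, n)))
        np.fill_diagonal(alpha, 1.0)
        p = CommunityParams(tuple("abc"), rng.uniform(0.3, 1.2, n), alpha)
        N0 = rng.uniform(0, 0.5, n)
        N0[rng.integers(n)] = 0.0  # one species starts extinct
        prot = Protocol(mode="serial-dilution", dilution_factor=df, n_cycles=5)
        traj = run_serial_dilution(p, N0, prot)
        assert np.all(traj.densities >= 0.0)
        dead = np.nonzero(N0 == 0.0)[0]
        assert np.all(traj.densities[:, dead] == 0.0)


class TestPairFixedPoints:
    def test_symmetric_coexistence(self):
        p = CommunityParams(("a", "b"), [1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]])
        pts = {fp.kind: fp for fp in pair_fixed_points(p, 0.0)}
        interior = pts["interior"]
        # (1 - 0.5)/(1 - 0.25) = 2/3 per species
        np.testing.assert_allclose(interior.densities, [2 / 3, 2 / 3], rtol=1e-12)
        assert interior.stable
        assert not pts["boundary-1"].stable and not pts["boundary-2"].stable

    def test_bistability_has_unstable_interior(self):
        p = CommunityParams(("a", "b"), [1.0, 1.0], [[1.0, 1.5], [1.2, 1.0]])
        pts = {fp.kind: fp for fp in pair_fixed_points(p, 0.0)}
        assert not pts["interior"].stable
        assert pts["boundary-1"].stable and pts["boundary-2"].stable

    def test_exclusion_has_no_interior(self):
        p = CommunityParams(("a", "b"), [1.0, 1.0], [[1.0, 2.0], [0.4, 1.0]])
        pts = {fp.kind: fp for fp in pair_fixed_points(p, 0.0)}
        assert "interior" not in pts
        assert pts["boundary-2"].stable and not pts["boundary-1"].stable

    def test_degenerate_product_signalled(self):
        p = CommunityParams(("a", "b"), [1.0, 1.0], [[1.0, 2.0], [0.5, 1.0]])
        with pytest.raises(DegenerateEquilibria):
            pair_fixed_points(p, 0.0)

    def test_stable_points_attract_perturbed_trajectories(self, worked_pair):
        delta = 0.35  # inside the coexistence window of the worked pair
        pts = pair_fixed_points(worked_pair, delta)
        prot = Protocol(mode="continuous-death", delta=delta, max_hours=3000)
        for fp in pts:
            if not fp.stable or fp.kind == "origin":
                continue
            start = np.clip(fp.densities + np.array([0.01, -0.01]), 1e-4, None)
            traj = run_continuous(worked_pair, start, prot)
            np.testing.assert_allclose(traj.final_densities, fp.densities, atol=1e-4)
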