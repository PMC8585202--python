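"""Energetics: Hamiltonian, transfer enthalpy, dG bookkeeping, profiles, features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dipscreen import (
    AgentSpec,
    CoreNotReachedError,
    EnvironmentParams,
    FreeEnergyProfile,
    MembraneGeometry,
    SimulationParams,
    build_profile,
    find_extrema,
    free_energy_increment,
    hamiltonian,
    make_toy_membrane,
    replicate_statistics,
    run_trajectory,
    transfer_enthalpy,
    trans_free_energy,
)
from dipscreen.constants import KB, KCAL, N_AVOGADRO, mass_kg_from_gmol


def make_profile(z, dg, bin_width=0.2, reference_z=None):
    z = np.asarray(z, dtype=float)
    return FreeEnergyProfile(
        z_centers=z,
        delta_g=np.asarray(dg, dtype=float),
        counts=np.ones(len(z), dtype=int),
        bin_width=bin_width,
        reference_z=float(z.max()) if reference_z is None else reference_z,
    )


class TestHamiltonian:
    def test_at_rest_equals_potential(self):
        assert hamiltonian(1.5e-21, (0, 0, 0), 1e-24, 300.0) == 1.5e-21

    def test_kinetic_part_capped_at_kbt(self):
        m = 1e-24
        v = math.sqrt(2 * 3 * KB * 300.0 / m)  # KE = 3 kbT
        h = hamiltonian(0.0, (v, 0, 0), m, 300.0)
        assert h == pytest.approx(KB * 300.0, rel=1e-12)

    def test_unit_chain_to_kcalmol(self):
        """The 9.09e-24 J pair energy converts to 1.31e-3 kcal/mol."""
        h = hamiltonian(9.091e-24, (0, 0, 0), 1e-24, 300.0)
        assert h * N_AVOGADRO / KCAL == pytest.approx(1.3085e-3, rel=1e-3)


class TestTransferEnthalpy:
    def test_zero_logp(self):
        assert transfer_enthalpy(0.0, 300.0) == 0.0

    @pytest.mark.parametrize(
        "logp, kcalmol",
        [(9.25, 12.70), (5.48, 7.522)],  # octenidine, chlorhexidine at 300 K
    )
    def test_reference_agents_to_four_digits(self, logp, kcalmol):
        assert transfer_enthalpy(logp, 300.0) / KCAL == pytest.approx(kcalmol, rel=5e-4)

    def test_joule_per_mol_scale(self):
        assert transfer_enthalpy(9.25, 300.0) == pytest.approx(5.313e4, rel=1e-3)


class TestIncrement:
    def test_no_crossing_no_change(self):
        assert free_energy_increment(2.0, 2.0, "water", "water", 5.0) == 0.0

    def test_crossing_terms_cancel_on_enter_exit(self):
        t = transfer_enthalpy(9.25, 300.0) / N_AVOGADRO
        inc_in = free_energy_increment(1.0, 1.0, "water", "membrane", t, +1)
        inc_out = free_energy_increment(1.0, 1.0, "membrane", "water", t, +1)
        assert inc_in + inc_out == 0.0
        assert inc_in == pytest.approx(t)

    def test_oct_entry_increment_in_kcalmol(self):
        t = transfer_enthalpy(9.25, 300.0) / N_AVOGADRO
        inc = free_energy_increment(0.0, 0.0, "water", "membrane", t, +1)
        assert inc * N_AVOGADRO / KCAL == pytest.approx(12.70, rel=1e-3)

    @given(
        h1=st.floats(-1e-20, 1e-20),
        h2=st.floats(-1e-20, 1e-20),
        t=st.floats(0, 1e-19),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_antisymmetry_property(self, h1, h2, t):
        fwd = free_energy_increment(h1, h2, "water", "membrane", t, +1)
        back = free_energy_increment(h2, h1, "membrane", "water", t, +1)
        assert fwd + back == pytest.approx(0.0, abs=1e-32)

    def test_bad_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            free_energy_increment(0, 0, "air", "water", 0.0)


class TestClosedLoop:
    def test_reflected_trajectory_returns_to_zero_dg(self, env):
        """Head-on repulsion, conservative limit: dG back at the start height < 1e-3."""
        m = make_toy_membrane([[20.0, 20.0, 0.0]], dipole=(0, 0, 30.0),
                              geometry=MembraneGeometry(40, 40, 2))
        agent = AgentSpec("t", mass=623.84, dipole=(0, 0, 30.0), logp=0.0, drag_radius=1e-30)
        sim = SimulationParams(n_steps=60_000, z_start=30.0, ke_mode="off",
                               initial_speed=60.0, stop_at_core=False)
        traj = run_trajectory(agent, m, env, sim)
        assert traj.z.min() > 2.0  # reflected before the membrane region
        after_turn = np.argmin(traj.z)
        returned = np.nonzero(traj.z[after_turn:] >= 30.0)[0]
        assert len(returned) > 0, "agent never returned to the start height"
        i = after_turn + returned[0]
        assert abs(traj.dg_kcal[i]) < 1e-3


class TestBuildProfile:
    def test_flat_zero_trajectory(self, env):
        m = make_toy_membrane([[20.0, 20.0, 0.0]], dipole=(0, 0, 0),
                              geometry=MembraneGeometry(40, 40, 10))
        agent = AgentSpec("t", mass=600.0, dipole=(1, 0, 0), logp=0.0)
        sim = SimulationParams(n_steps=100, z_start=25.0, ke_mode="cap",
                               initial_speed=0.0, stop_at_core=False)
        traj = run_trajectory(agent, m, env, sim)
        prof = build_profile(traj)
        np.testing.assert_array_equal(prof.delta_g, 0.0)

    def test_reference_bin_is_exactly_zero(self, env, toy_agent, square_membrane):
        sim = SimulationParams(n_steps=2000, z_start=25.0, stop_at_core=False)
        traj = run_trajectory(toy_agent, square_membrane, env, sim)
        prof = build_profile(traj)
        assert prof.value_at(prof.reference_z) == 0.0

    def test_bin_means_match_independent_groupby(self, env, toy_agent, square_membrane):
        sim = SimulationParams(n_steps=3000, z_start=25.0, stop_at_core=False)
        traj = run_trajectory(toy_agent, square_membrane, env, sim)
        w = 0.5
        prof = build_profile(traj, bin_width=w)
        # brute-force re-aggregation
        sums, counts = {}, {}
        for z, g in zip(traj.z, traj.dg_kcal):
            k = math.floor(z / w)
            sums[k] = sums.get(k, 0.0) + g
            counts[k] = counts.get(k, 0) + 1
        ref_k = math.floor(25.0 / w)
        ref = sums[ref_k] / counts[ref_k]
        for zc, dg, n in zip(prof.z_centers, prof.delta_g, prof.counts):
            k = round(zc / w - 0.5)
            assert n == counts[k]
            assert dg == pytest.approx(sums[k] / counts[k] - ref, abs=1e-12)


class TestTransFreeEnergy:
    def test_flat_profile_zero(self):
        z = np.arange(0.1, 30.0, 0.2)
        prof = make_profile(z, np.zeros(len(z)))
        assert trans_free_energy(prof) == 0.0

    def test_direct_difference(self):
        prof = make_profile([0.1, 10.1, 20.1, 30.1], [1.7, 0.4, 0.2, 0.0], bin_width=0.2,
                            reference_z=30.1)
        assert trans_free_energy(prof) == pytest.approx(1.7)

    def test_core_not_reached_raises(self):
        prof = make_profile([20.1, 25.1, 30.1], [0.5, 0.1, 0.0], reference_z=30.1)
        with pytest.raises(CoreNotReachedError):
            trans_free_energy(prof)


class TestFindExtrema:
    def _well_barrier_profile(self):
        z = np.arange(0.1, 40.0, 0.2)
        dg = 1.5 * np.exp(-((z - 22.0) ** 2) / 4.0) - 2.0 * np.exp(-((z - 14.0) ** 2) / 6.0)
        return make_profile(z, dg)

    def test_single_well_recovered(self):
        z = np.arange(0.1, 40.0, 0.2)
        dg = -2.0 * np.exp(-((z - 15.0) ** 2) / 8.0)
        f = find_extrema(make_profile(z, dg))
        assert len(f.minima) == 1
        zmin, depth = f.minima[0]
        assert zmin == pytest.approx(15.0, abs=0.3)
        assert depth == pytest.approx(-2.0, abs=0.1)

    def test_well_plus_barrier_ordering(self):
        f = find_extrema(self._well_barrier_profile())
        assert len(f.barriers) == 1 and len(f.minima) == 1
        assert f.barriers[0][0] > f.minima[0][0]  # barrier outside the well in |z|
        assert f.barriers[0][1] == pytest.approx(1.5, abs=0.1)

    def test_noisy_extrema_within_one_bin(self):
        rng = np.random.default_rng(5)
        z = np.arange(0.1, 40.0, 0.2)
        clean = 1.5 * np.exp(-((z - 22.0) ** 2) / 4.0) - 2.0 * np.exp(-((z - 14.0) ** 2) / 6.0)
        noisy = clean + rng.normal(0, 0.02, len(z))
        f = find_extrema(make_profile(z, noisy), prominence=0.5)
        assert abs(f.barriers[0][0] - 22.0) <= 0.4
        assert abs(f.minima[0][0] - 14.0) <= 0.4

    def test_flat_profile_has_no_features(self):
        z = np.arange(0.1, 10.0, 0.2)
        f = find_extrema(make_profile(z, np.zeros(len(z))))
        assert f.barriers == [] and f.minima == []

    def test_features_invariant_to_constant_shift(self):
        """Heights are bulk-referenced, so adding a constant changes nothing."""
        base = self._well_barrier_profile()
        shifted = make_profile(base.z_centers, base.delta_g + 3.7)
        f1 = find_extrema(base)
        f2 = find_extrema(shifted)
        # the shifted profile's reference is also shifted, heights must agree
        for (z1, h1), (z2, h2) in zip(f1.barriers, f2.barriers):
            assert z1 == z2 and h1 == pytest.approx(h2, abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="5 populated bins"):
            find_extrema(make_profile([0.1, 0.3, 0.5], [0, 1, 0]))


class TestReplicateStatistics:
    def test_identical_profiles_zero_sd(self):
        z = np.arange(0.1, 10.0, 0.2)
        profs = [make_profile(z, np.sin(z)) for _ in range(4)]
        mean, sd = replicate_statistics(profs)
        np.testing.assert_allclose(sd, 0.0)

    def test_two_profile_arithmetic(self):
        p1 = make_profile([0.1, 1.1], [0.0, 2.0], bin_width=1.0, reference_z=0.1)
        p2 = make_profile([0.1, 1.1], [0.0, 4.0], bin_width=1.0, reference_z=0.1)
        mean, sd = replicate_statistics([p1, p2])
        np.testing.assert_allclose(mean.delta_g, [0.0, 3.0])
        np.testing.assert_allclose(sd, [0.0, math.sqrt(2.0)])

    def test_incompatible_bin_widths_rejected(self):
        p1 = make_profile([0.1, 1.1], [0, 1], bin_width=1.0)
        p2 = make_profile([0.25, 0.75], [0, 1], bin_width=0.5)
        with pytest.raises(ValueError, match="incompatible"):
            replicate_statistics([p1, p2])

    def test_underpopulated_bins_dropped(self):
        p1 = make_profile([0.5, 1.5, 2.5], [0.0, 1.0, 2.0], bin_width=1.0, reference_z=2.5)
        p2 = make_profile([1.5, 2.5], [3.0, 2.0], bin_width=1.0, reference_z=2.5)
        mean, _ = replicate_statistics([p1, p2])
        assert 0.5 not in mean.z_centers  # only one replicate sampled that bin


class TestDipoleScalingProperty:
    def test_profile_dipole_part_scales_linearly(self, env, square_membrane):
        """Scaling the agent dipole by s scales the dipole part of dG by s."""
        sim = SimulationParams(n_steps=400, z_start=25.0, ke_mode="off",
                               initial_speed=40.0, stop_at_core=False)
        a1 = AgentSpec("t", mass=600.0, dipole=(1.0, 0.5, -0.5), logp=0.0, drag_radius=1e-30)
        a3 = AgentSpec("t", mass=600.0, dipole=(3.0, 1.5, -1.5), logp=0.0, drag_radius=1e-30)
        t1 = run_trajectory(a1, square_membrane, env, sim)
        e1_start = t1.ep_kcal[0]
        t3 = run_trajectory(a3, square_membrane, env, sim)
        # same start position: initial energies scale exactly by 3
        assert t3.ep_kcal[0] == pytest.approx(3 * e1_start, rel=1e-12)
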