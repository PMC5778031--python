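"""Cluster builder, toy force field, integrators, hopper, fixtures."""

import numpy as np
import pytest

from protir.cluster_sim import (
    ConfinementSpec,
    HopperSpec,
    SimParams,
    StabilityError,
    attach_proton_hopper,
    build_cluster,
    confinement_energy,
    generate_oscillator_dipole,
    nve_energy_drift,
    run_toy_md,
    single_water_frame,
    synthesize_wannier,
    water_normal_modes,
)
from protir.dipole_defect import ChargeModel, dipole_series, total_charge
from protir.spectra import SpectralConfig, spectrum_from_dipole
from protir.trajectory_io import Frame


class TestBuildCluster:
    def test_neutral_chain_geometry(self):
        fr = build_cluster(ConfinementSpec.narrow_chain(), SimParams(n_waters=15, seed=0))
        assert fr.n_atoms == 45
        o = fr.positions[np.array(fr.elements) == "O"]
        assert np.max(np.hypot(o[:, 0], o[:, 1])) < 1.0

    def test_protonated_droplet_counts_and_charge(self):
        fr = build_cluster(
            ConfinementSpec.droplet(), SimParams(n_waters=26, protonated=True, seed=0)
        )
        assert fr.n_atoms == 79
        assert total_charge(fr, ChargeModel.nuclear_effective()) == pytest.approx(1.0)

    def test_disc_is_planar(self):
        fr = build_cluster(ConfinementSpec.disc(), SimParams(n_waters=15, seed=0))
        o = fr.positions[np.array(fr.elements) == "O"]
        assert np.max(np.abs(o[:, 2])) < 1.0


class TestConfinement:
    def test_zero_on_axis(self):
        fr = build_cluster(ConfinementSpec.narrow_chain(), SimParams(n_waters=3, seed=0))
        o_mask = np.array(fr.elements) == "O"
        pos = fr.positions.copy()
        pos[o_mask, 0:2] = 0.0
        E, _ = confinement_energy(Frame(fr.elements, pos), ConfinementSpec.narrow_chain())
        assert E == pytest.approx(0.0, abs=1e-12)

    def test_single_oxygen_at_one_angstrom(self):
        # 0.1 nm off-axis with K_xy = 2000 kJ/mol/nm^2 -> 10 kJ/mol
        fr = Frame(["O", "H", "H"], np.array([[1.0, 0, 0], [1.8, 0, 0.5], [0.2, 0, 0.5]]))
        E, _ = confinement_energy(fr, ConfinementSpec.narrow_chain())
        assert E == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [ConfinementSpec.narrow_chain(), ConfinementSpec.disc(), ConfinementSpec.droplet()],
    )
    def test_forces_match_finite_difference(self, spec):
        rng = np.random.default_rng(0)
        fr = Frame(["O", "H", "H", "O", "H", "H"], rng.normal(scale=2.0, size=(6, 3)))
        _, F = confinement_energy(fr, spec)
        h = 1e-5
        for i in range(fr.n_atoms):
            for c in range(3):
                pp, pm = fr.positions.copy(), fr.positions.copy()
                pp[i, c] += h
                pm[i, c] -= h
                ep, _ = confinement_energy(Frame(fr.elements, pp), spec)
                em, _ = confinement_energy(Frame(fr.elements, pm), spec)
                fd = -(ep - em) / (2 * h)
                assert F[i, c] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestToyMD:
    def test_two_water_nve_conserves_energy(self):
        spec = ConfinementSpec.droplet()
        params = SimParams(n_waters=2, equil_time=0.5, segment_time=1.0, n_segments=1, seed=1)
        seg = run_toy_md(build_cluster(spec, params), spec, params)[0]
        assert nve_energy_drift(seg) < 0.01

    def test_thermostat_reaches_target_temperature(self, thermostat_info):
        assert thermostat_info["nvt_mean_temperature_K"] == pytest.approx(300.0, abs=15.0)

    def test_chain_bands_near_normal_mode_oracle(self, neutral_chain_segments):
        modes = water_normal_modes()  # bend, two stretches of the toy water
        series = dipole_series(neutral_chain_segments[0], ChargeModel.nuclear_effective())
        sp = spectrum_from_dipole(series, SpectralConfig(sigma_nu=25.0))
        total = sp.components.sum(axis=0)

        def band_power(lo, hi):
            m = (sp.nu >= lo) & (sp.nu <= hi)
            return np.trapezoid(total[m], sp.nu[m]) / (hi - lo)

        bend = band_power(modes[0] - 150, modes[0] + 150)
        stretch = band_power(modes[1] - 150, modes[2] + 150)
        gap = band_power(2300, 2800)
        assert bend > 10 * gap
        assert stretch > 10 * gap

    def test_narrow_chain_tighter_than_wide(self, chain_segments):
        wide_spec = ConfinementSpec.wide_chain()
        params = SimParams(n_waters=15, protonated=True, equil_time=1.0,
                           segment_time=1.0, n_segments=1, seed=1)
        wide = run_toy_md(build_cluster(wide_spec, params), wide_spec, params)[0]

        def rms_radial(traj):
            o = np.array(traj.elements) == "O"
            pos = traj.positions_array()[:, o, :2]
            return np.sqrt(np.mean(pos**2))

        assert rms_radial(chain_segments[0]) < rms_radial(wide)

    def test_fixed_seed_bit_reproducible(self):
        spec = ConfinementSpec.narrow_chain()
        params = SimParams(n_waters=4, equil_time=0.1, segment_time=0.1,
                           n_segments=1, protonated=True, seed=7)
        a = run_toy_md(build_cluster(spec, params), spec, params)[0]
        b = run_toy_md(build_cluster(spec, params), spec, params)[0]
        np.testing.assert_array_equal(a.positions_array(), b.positions_array())
        ha = attach_proton_hopper(a, HopperSpec(policy="chain"), seed=7)
        hb = attach_proton_hopper(b, HopperSpec(policy="chain"), seed=7)
        np.testing.assert_array_equal(ha.mu, hb.mu)

    def test_oversized_timestep_raises_stability_error(self):
        spec = ConfinementSpec.droplet()
        params = SimParams(n_waters=2, equil_time=0.5, segment_time=0.1,
                           n_segments=1, dt=5.0, seed=0)
        with pytest.raises(StabilityError):
            run_toy_md(build_cluster(spec, params), spec, params)


class TestHopper:
    def test_zero_rate_constant_dipole(self, chain_segments):
        hop = attach_proton_hopper(chain_segments[0], HopperSpec(hop_rate=0.0, policy="chain"), seed=1)
        # z rides a single oxygen site; x,y are exactly zero by the chain policy
        assert np.all(hop.mu[:, :2] == 0.0)
        assert np.std(hop.mu[:, 2]) < 0.5  # no hops: bounded thermal site motion

    def test_chain_policy_has_zero_xy_components(self, chain_segments):
        hop = attach_proton_hopper(chain_segments[0], HopperSpec(policy="chain"), seed=3)
        assert np.all(hop.mu[:, :2] == 0.0)
        assert np.ptp(hop.mu[:, 2]) > 1.0  # hops move the defect between sites

    def test_disc_policy_has_zero_z(self, disc_segments):
        hop = attach_proton_hopper(disc_segments[0], HopperSpec(policy="disc"), seed=3)
        assert np.all(hop.mu[:, 2] == 0.0)


class TestWannierSynthesis:
    def test_ideal_water_template_exact(self):
        fr = synthesize_wannier(single_water_frame())
        assert fr.wannier.shape == (4, 3)
        o = fr.positions[0]
        for k in (0, 1):  # bond centers 0.5 A along O-H
            u = fr.positions[1 + k] - o
            u /= np.linalg.norm(u)
            np.testing.assert_allclose(fr.wannier[k], o + 0.5 * u, atol=1e-12)
        for k in (2, 3):  # lone pairs 0.3 A from O
            assert np.linalg.norm(fr.wannier[k] - o) == pytest.approx(0.3, abs=1e-12)

    def test_jitter_reproducible_and_small(self):
        fr = single_water_frame()
        a = synthesize_wannier(fr, jitter_sd=0.02, seed=5)
        b = synthesize_wannier(fr, jitter_sd=0.02, seed=5)
        np.testing.assert_array_equal(a.wannier, b.wannier)
        assert np.max(np.abs(a.wannier - synthesize_wannier(fr).wannier)) < 0.2


class TestOscillatorFixture:
    def test_zero_modes_zero_series(self):
        series, ref = generate_oscillator_dipole([], None, 64, 0.5)
        assert np.all(series.mu == 0.0) and ref["lines"] == []

    def test_equivalent_direction_symmetry(self):
        series, _ = generate_oscillator_dipole(
            [(1000.0, 1.0, "x", 0.0), (1000.0, 1.0, "y", 0.0)], None, 4096, 0.5
        )
        sp = spectrum_from_dipole(series, SpectralConfig(sigma_nu=0.0))
        np.testing.assert_allclose(sp.A_xx, sp.A_yy, rtol=1e-8, atol=1e-18)

    def test_line_integral_reference(self):
        series, ref = generate_oscillator_dipole([(3400.0, 1.0, "z", 0.0)], None, 2**13, 0.5)
        sp = spectrum_from_dipole(series, SpectralConfig(sigma_nu=0.0, nu_max=4000.0))
        dnu = sp.nu[1] - sp.nu[0]
        # central differences attenuate a line at omega by (sin(w dt)/(w dt))^2
        w_dt = 2 * np.pi * 3400.0 * 0.5 * 2.99792458e-5
        transfer = (np.sin(w_dt) / w_dt) ** 2
        assert sp.A_zz.sum() * dnu == pytest.approx(
            ref["lines"][0]["integral"] * transfer, rel=0.01
        )
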