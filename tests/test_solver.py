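"""FDTD solver: discrete nulls, limits, oracles, boundaries and stability."""

import numpy as np
import pytest

from kvfdwave.grid import GridSpec, MaterialMap, build_grid, build_pml, half_node_materials
from kvfdwave.rheology import KVFDMaterial, MATERIALS, phase_velocity
from kvfdwave.solver import (
    Probe,
    ReceiverArray,
    SourceSpec,
    StabilityError,
    TorsionalSolver,
    gaussian_monocycle,
    tone_burst,
)
from kvfdwave.experiments import plane_wave_trace, time_to_peak_velocity

NORMAL = MATERIALS["prostate_normal"]


def small_grid(n_r=24, n_z=20, n_pml=0, dr=0.5e-3, ru=3.25e-3):
    return GridSpec(dr=dr, dz=dr, n_r=n_r, n_z=n_z, r0=ru, n_pml=n_pml)


def zero_source(n_steps):
    return SourceSpec(z_center=0.0, length=0.0, samples=np.zeros(n_steps + 1))


class TestMonocycle:
    def test_starts_at_zero_and_peaks_at_arc_displacement(self):
        fc, a, ru = 700.0, 0.3, 3.25e-3
        tau = 1 / (2 * np.pi * fc)
        t = np.linspace(0, 10e-3, 20001)
        s = gaussian_monocycle(fc, a, ru, t)
        assert gaussian_monocycle(fc, a, ru, 4 * tau) == pytest.approx(0.0, abs=1e-18)
        assert np.max(np.abs(s)) == pytest.approx(a * ru, rel=1e-6)
        # 0.3 rad at the 3.25 mm wall is the ~1 mm emitter stroke
        assert np.max(np.abs(s)) == pytest.approx(0.975e-3, rel=1e-6)

    def test_spectrum_peaks_at_centre_frequency(self):
        fc, dt = 700.0, 20e-6
        t = dt * np.arange(4096)
        s = gaussian_monocycle(fc, 0.3, 3.25e-3, t)
        spec = np.abs(np.fft.rfft(s))
        f = np.fft.rfftfreq(len(s), dt)
        assert f[np.argmax(spec)] == pytest.approx(fc, abs=f[1])

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            gaussian_monocycle(0.0, 0.3, 3e-3, 0.0)


class TestDiscreteNulls:
    def test_rigid_rotation_produces_no_strain_stress_or_acceleration(self):
        g = small_grid()
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, NORMAL), dt=20e-6,
                                 t_memory=None)
        st = solver.prepare(8)
        omega_like = 0.01
        u = omega_like * np.broadcast_to(g.r_nodes[:, None], (g.nr_tot, g.nz_tot))
        st.u = u.copy()
        st.u_prev = u.copy()
        eps_rt, eps_tz = solver.compute_strains()
        # null at machine precision (strain scale of this field is ~u/r ~ 1e-2)
        assert np.max(np.abs(eps_rt)) < 1e-15
        assert np.all(eps_tz == 0.0)
        solver.compute_stresses()
        assert np.max(np.abs(st.sig_rt)) < 1e-15 * NORMAL.shear_elastic
        u_new = solver.update_displacement()
        # interior acceleration vanishes: u_new = 2u - u_prev = u
        np.testing.assert_allclose(u_new[:-1, 1:-1], u[:-1, 1:-1],
                                   rtol=0, atol=1e-18)

    def test_quiescent_run_stays_identically_zero(self):
        g = small_grid(n_pml=2)
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, NORMAL), dt=20e-6)
        res = solver.run(zero_source(50), 50)
        assert res.max_displacement == 0.0
        assert res.stable

    def test_linear_axial_field_gives_exact_half_strain(self):
        g = small_grid()
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, NORMAL), dt=20e-6,
                                 t_memory=None)
        st = solver.prepare(4)
        c = 0.002
        st.u = c * np.broadcast_to(g.z_nodes[None, :], (g.nr_tot, g.nz_tot)).copy()
        _, eps_tz = solver.compute_strains()
        assert np.allclose(eps_tz, c / 2, rtol=1e-13)
        # uniform field has zero axial strain
        st2 = solver.prepare(4)
        st2.u = np.full((g.nr_tot, g.nz_tot), 1e-4)
        _, eps_tz2 = solver.compute_strains()
        assert np.all(eps_tz2 == 0.0)


class TestStencilOracle:
    def test_single_update_matches_loop_stencil(self):
        """One momentum update vs an independent pure-python loop stencil,
        on a small heterogeneous grid with the wall stress image."""
        rng = np.random.default_rng(7)
        g = small_grid(n_r=7, n_z=6)
        mat = MaterialMap.homogeneous(g, NORMAL)
        mat.mu += rng.uniform(0, 500, mat.mu.shape)
        mat.eta += rng.uniform(0, 5, mat.eta.shape)
        mat.rho += rng.uniform(0, 100, mat.rho.shape)
        dt = 10e-6
        solver = TorsionalSolver(g, mat, dt=dt, t_memory=None)
        st = solver.prepare(4)
        st.u = rng.normal(0, 1e-5, (g.nr_tot, g.nz_tot))
        st.u_prev = rng.normal(0, 1e-5, (g.nr_tot, g.nz_tot))
        solver.compute_strains()
        solver.compute_stresses()
        got = solver.update_displacement()

        half = half_node_materials(mat)
        sig_rt, sig_tz = st.sig_rt, st.sig_tz
        expect = np.zeros_like(st.u)
        for i in range(g.nr_tot - 1):
            for j in range(1, g.nz_tot - 1):
                if i == 0:
                    ddr = 2 * sig_rt[0, j] / g.dr       # image: -sig at r0-dr/2
                    sbar = 0.0
                else:
                    ddr = (sig_rt[i, j] - sig_rt[i - 1, j]) / g.dr
                    sbar = 0.5 * (sig_rt[i, j] + sig_rt[i - 1, j])
                ddz = (sig_tz[i, j] - sig_tz[i, j - 1]) / g.dz
                rhs = ddr + ddz + 2 * sbar / g.r_nodes[i]
                expect[i, j] = (2 * st.u[i, j] - st.u_prev[i, j]
                                + dt**2 / half["rho"][i, j] * rhs)
        np.testing.assert_allclose(got[:-1, 1:-1], expect[:-1, 1:-1],
                                   rtol=1e-13, atol=1e-20)

    def test_elastic_and_kv_stress_limits(self):
        g = small_grid(n_r=10, n_z=8)
        elastic = KVFDMaterial(1000.0, 3000.0, 0.0, 0.35, "el")
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, elastic), dt=10e-6,
                                 t_memory=None)
        st = solver.prepare(4)
        st.u = np.random.default_rng(0).normal(0, 1e-5, (g.nr_tot, g.nz_tot))
        eps_rt, _ = solver.compute_strains()
        sig_rt, _ = solver.compute_stresses()
        np.testing.assert_allclose(sig_rt, 2 * 3000.0 * eps_rt, rtol=1e-14)


class TestKelvinVoigtLimit:
    def test_alpha_one_matches_independent_classical_kv_solver(self):
        """alpha = 1 reduces the GL operator to a backward first difference;
        the whole run must match a separately coded classical Kelvin-Voigt
        solver to near machine precision."""
        g = small_grid(n_r=30, n_z=25, n_pml=0)
        kv_mat = KVFDMaterial(1000.0, 3000.0, 1.5, 1.0, "kv")
        mat = MaterialMap.homogeneous(g, kv_mat)
        dt = 20e-6
        n_steps = 200
        t = dt * np.arange(n_steps + 1)
        samples = gaussian_monocycle(500.0, 0.1, g.r0, t)
        src = SourceSpec(z_center=4e-3, length=2e-3, samples=samples)

        solver = TorsionalSolver(g, mat, dt=dt, t_memory=None)
        res = solver.run(src, n_steps,
                         probes=[Probe(5, np.array([10]), "p")])

        u_ref = self._classical_kv_run(g, kv_mat, dt, n_steps, src)
        assert res.traces[:, 0] == pytest.approx(u_ref[:, 5, 10].tolist(),
                                                 rel=1e-10, abs=1e-18)

    @staticmethod
    def _classical_kv_run(g, mat, dt, n_steps, src):
        """Independent classical KV FDTD: sigma = 2 mu eps + 2 eta deps/dt."""
        mu, eta, rho = mat.shear_elastic, mat.shear_viscous, mat.density
        nr, nz = g.nr_tot, g.nz_tot
        u = np.zeros((nr, nz)); up = np.zeros((nr, nz))
        ert_p = np.zeros((nr - 1, nz)); etz_p = np.zeros((nr, nz - 1))
        rows = src.rows(g)
        u[0, rows] = src.value(0)
        out = np.zeros((n_steps + 1, nr, nz)); out[0] = u
        rn, rh = g.r_nodes, g.r_half
        for n in range(n_steps):
            ert = np.zeros((nr - 1, nz)); etz = np.zeros((nr, nz - 1))
            for i in range(nr - 1):
                for j in range(nz):
                    ert[i, j] = 0.5 * ((u[i + 1, j] - u[i, j]) / g.dr
                                       - 0.5 * (u[i + 1, j] + u[i, j]) / rh[i])
            for i in range(nr):
                for j in range(nz - 1):
                    etz[i, j] = 0.5 * (u[i, j + 1] - u[i, j]) / g.dz
            srt = 2 * mu * ert + 2 * eta * (ert - ert_p) / dt
            stz = 2 * mu * etz + 2 * eta * (etz - etz_p) / dt
            un = np.zeros((nr, nz))
            for i in range(nr - 1):
                for j in range(1, nz - 1):
                    if i == 0:
                        ddr = 2 * srt[0, j] / g.dr
                        sbar = 0.0
                    else:
                        ddr = (srt[i, j] - srt[i - 1, j]) / g.dr
                        sbar = 0.5 * (srt[i, j] + srt[i - 1, j])
                    ddz = (stz[i, j] - stz[i, j - 1]) / g.dz
                    un[i, j] = (2 * u[i, j] - up[i, j]
                                + dt**2 / rho * (ddr + ddz + 2 * sbar / rn[i]))
            un[0, rows] = src.value(n + 1)
            up, u = u, un
            ert_p, etz_p = ert, etz
            out[n + 1] = u
        return out


class TestElasticPropagation:
    def test_wave_speed_matches_sqrt_mu_over_rho_within_dispersion_bound(self):
        elastic = KVFDMaterial(1000.0, 3000.0, 0.0, 0.35, "el")
        c0 = np.sqrt(3.0)
        fc = 500.0
        dr = c0 / fc / 25           # 25 elements per wavelength
        res, radii = plane_wave_trace(
            elastic, fc, dr=dr, dt=20e-6, t_total=15e-3,
            probe_offsets=(4e-3, 10e-3), waveform="gaussian_monocycle",
        )
        v = time_to_peak_velocity(res.traces[:, 0], res.traces[:, 1],
                                  radii[1] - radii[0], 20e-6)
        assert v == pytest.approx(c0, rel=0.01)


class TestBoundariesAndReceivers:
    def test_emitter_trace_equals_waveform_and_holds_zero_after(self):
        g = small_grid(n_r=20, n_z=30, n_pml=0)
        mat = MaterialMap.homogeneous(g, NORMAL)
        solver = TorsionalSolver(g, mat, dt=20e-6, t_memory=1e-3)
        n_steps = 120
        samples = gaussian_monocycle(700.0, 0.1, g.r0, 20e-6 * np.arange(40))
        src = SourceSpec(z_center=2e-3, length=1e-3, samples=samples)
        rows = src.rows(g)
        res = solver.run(src, n_steps, probes=[Probe(0, rows[:1], "emitter")])
        np.testing.assert_allclose(res.traces[:40, 0], samples, atol=1e-18)
        assert np.all(res.traces[40:, 0] == samples[-1])

    def test_receiver_span_averages_and_single_node_sampling(self):
        g = small_grid(n_r=10, n_z=40, n_pml=0, dr=0.15e-3)
        arr = ReceiverArray.uniform(3, z_start=0.9e-3, spacing=0.8e-3,
                                    length=0.5e-3)
        probes = arr.probes(g)
        assert len(probes) == 3
        assert probes[0].j_indices.size == 3          # 0.5 mm spans 3 of 0.15 mm
        short = ReceiverArray.uniform(1, z_start=1.2e-3, spacing=1e-3,
                                      length=0.05e-3)
        assert short.probes(g)[0].j_indices.size == 1

    def test_receiver_overlapping_emitter_rejected(self):
        g = small_grid(n_r=10, n_z=40, n_pml=0, dr=0.15e-3)
        src = SourceSpec(z_center=1e-3, length=2e-3, samples=np.zeros(3))
        arr = ReceiverArray.uniform(2, z_start=1.9e-3, spacing=0.8e-3,
                                    length=0.5e-3)
        with pytest.raises(ValueError):
            arr.probes(g, src)

    def test_snapshots_recorded_at_requested_times(self):
        g = small_grid(n_pml=2)
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, NORMAL), dt=20e-6)
        t = 20e-6 * np.arange(31)
        src = SourceSpec(z_center=3e-3, length=1e-3,
                         samples=gaussian_monocycle(900.0, 0.05, g.r0, t))
        res = solver.run(src, 30, snapshot_times=(2e-4, 6e-4))
        assert set(res.snapshots) == {2e-4, 6e-4}
        assert res.snapshots[6e-4].shape == (g.nr_tot, g.nz_tot)


class TestPMLEfficacy:
    def test_reflected_amplitude_below_one_percent_of_outgoing_peak(self):
        """Truncated-domain run vs an enlarged reference whose boundaries
        cannot causally contaminate the comparison window."""
        fc = 500.0
        dr = 0.3e-3
        dt = 20e-6
        t_total = 16e-3
        ru = 3.25e-3

        def run(rd, zd, n_pml):
            g = build_grid(rd, zd, ru, dr, dr, n_pml)
            mat = MaterialMap.homogeneous(g, NORMAL)
            pml = build_pml(g, NORMAL.elastic_velocity, alpha_max=np.pi * fc)
            solver = TorsionalSolver(g, mat, dt=dt, t_memory=1e-3, pml=pml)
            n_steps = int(round(t_total / dt))
            t = dt * np.arange(n_steps + 1)
            src = SourceSpec(z_center=2e-3, length=2e-3,
                             samples=gaussian_monocycle(fc, 0.1, ru, t))
            probe = Probe(g.r_index(ru + 5e-3), np.array([g.z_index(5e-3)]), "p")
            return solver.run(src, n_steps, probes=[probe]).traces[:, 0]

        small = run(12e-3, 14e-3, 40)
        big = run(40e-3, 44e-3, 40)
        outgoing = np.max(np.abs(big))
        reflected = np.max(np.abs(small - big))
        assert reflected < 0.01 * outgoing

    def test_causality_of_the_propagating_front(self):
        """The KVFD phase velocity is unbounded in frequency, so the front
        is only sharply bounded by the discrete domain of dependence (one
        cell per step); ahead of the band-centre arrival the physical
        precursor must be attenuated to a fraction of the peak."""
        fc, dr, dt, d = 700.0, 0.2e-3, 20e-6, 10e-3
        res, radii = plane_wave_trace(
            NORMAL, fc, dr=dr, dt=dt, t_total=10e-3,
            probe_offsets=(d,), waveform="gaussian_monocycle",
        )
        trace = res.traces[:, 0]
        # exact zero before the grid cone (d/dr cells, one cell per step)
        n_cone = int(round(d / dr))
        assert np.all(trace[:n_cone] == 0.0)
        # attenuated precursor: < 0.1 % of the peak at 85 % of the
        # band-centre arrival time
        t_arr = d / phase_velocity(NORMAL, 2 * np.pi * fc)
        before = trace[res.times < 0.85 * t_arr]
        assert np.max(np.abs(before)) < 1e-3 * np.max(np.abs(trace))


class TestStability:
    def test_blowup_raises_with_step_information(self):
        g = small_grid(n_r=30, n_z=4, n_pml=0, dr=0.1e-3)
        mat = MaterialMap.homogeneous(g, NORMAL)
        solver = TorsionalSolver(g, mat, dt=500e-6, t_memory=None)  # far past CFL
        t = 500e-6 * np.arange(201)
        src = SourceSpec(z_center=0.2e-3, length=0.1e-3,
                         samples=tone_burst(700.0, 0.3, g.r0, t))
        with pytest.raises(StabilityError) as err:
            solver.run(src, 200)
        assert err.value.step > 0

    def test_unstable_run_can_return_partial_diagnostics(self):
        g = small_grid(n_r=30, n_z=4, n_pml=0, dr=0.1e-3)
        solver = TorsionalSolver(g, MaterialMap.homogeneous(g, NORMAL),
                                 dt=500e-6, t_memory=None)
        t = 500e-6 * np.arange(201)
        src = SourceSpec(z_center=0.2e-3, length=0.1e-3,
                         samples=tone_burst(700.0, 0.3, g.r0, t))
        res = solver.run(src, 200, raise_on_instability=False)
        assert not res.stable
        assert res.failed_step is not None


class TestClinicalRunProperties:
    def test_no_amplitude_growth_over_42_ms(self, clinical_run):
        """Empirical boundedness at the production discretisation: the last
        10 ms never exceed the first 10 ms."""
        res, _ = clinical_run
        per_step = res.max_u_per_step
        t = res.times
        assert per_step[t >= 32e-3].max() < per_step[t <= 10e-3].max()
        assert res.stable

    def test_direct_wave_reaches_all_receivers_before_24_ms(self, clinical_run):
        _, metrics = clinical_run
        assert metrics.direct_arrival_s.size == 32
        assert metrics.all_receivers_reached_by < 24e-3

    def test_receiver_traces_are_causal(self, clinical_run, table3_config):
        """Every receiver is exactly quiet before the discrete influence
        cone can reach it and effectively quiet before 85 % of the
        band-centre arrival time."""
        res, _ = clinical_run
        cfg = table3_config
        c_band = phase_velocity(NORMAL, 2 * np.pi * cfg.frequency)
        emitter_hi = cfg.emitter_z + cfg.emitter_length / 2
        peak = np.abs(res.traces).max()
        for k in range(res.traces.shape[1]):
            z = cfg.receiver_start + k * cfg.receiver_spacing
            d = z - cfg.receiver_length / 2 - emitter_hi
            n_cone = int(np.floor(d / cfg.dz))
            assert np.all(res.traces[:n_cone, k] == 0.0)
            early = res.traces[res.times < 0.85 * d / c_band, k]
            assert np.max(np.abs(early), initial=0.0) < 1e-3 * peak
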