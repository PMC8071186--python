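"""Displacement-stress FDTD core for torsional waves in KVFD tissue.

The axisymmetric torsional problem has a single displacement component,
the azimuthal displacement u (m), governed by

    rho d2u/dt2 = d(sig_rt)/dr + d(sig_tz)/dz + (2/r) sig_rt

with strains

    eps_rt = (du/dr - u/r) / 2,      eps_tz = (du/dz) / 2

and the KVFD constitutive law sig = 2 (mu + eta D^alpha_t) eps, where
D^alpha_t is the Grünwald-Letnikov fractional derivative evaluated over a
truncated strain history (short-memory principle).

Discretisation: staggered grid (see :mod:`kvfdwave.grid`), second-order
centred differences in space, backward second difference in time for the
acceleration, GL backward sum for the fractional term.  Per step:

1. strains at t^n from u^n (newest sample pushed onto the history ring);
2. stresses at t^n, the GL sum including the newest strain with weight 1;
3. u^{n+1} from the momentum balance with the stress divergence at t^n.

Boundaries: the lumen-wall column (i = 0) is traction free -- an
antisymmetric stress image sig_rt(r0 - dr/2) = -sig_rt(r0 + dr/2) places
the zero of the interpolated traction exactly on the wall -- except on the
emitter rows, where u is prescribed (Dirichlet, arc displacement).  The
remaining three edges carry graded unsplit PML collars: each of the four
spatial-derivative terms is stretched through one auxiliary memory
variable with the standard recursive-convolution update.

A grid with a single z row (``n_z == 1``) degenerates to the z-invariant
("plane wave") radial problem used by the verification studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gl import gl_coefficients, memory_steps
from .grid import GridSpec, MaterialMap, PMLProfile, build_pml, half_node_materials

__all__ = [
    "StabilityError",
    "SourceSpec",
    "ReceiverArray",
    "Probe",
    "FieldState",
    "SimulationResult",
    "TorsionalSolver",
    "gaussian_monocycle",
    "tone_burst",
]

log = logging.getLogger(__name__)

_CHECK_INTERVAL = 25          # steps between NaN/blow-up checks
_BLOWUP_DISPLACEMENT = 1.0    # |u| above 1 m in soft tissue means divergence


class StabilityError(RuntimeError):
    """Raised when the time stepping produces NaN/Inf or divergent values."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"instability at step {step}: {message}")


def gaussian_monocycle(fc: float, amplitude: float, ru: float, t) -> np.ndarray | float:
    """Gaussian monocycle emitter waveform (arc displacement, m).

    s(t) = a ru (t - t0)/tau exp(1/2 - (t - t0)^2 / (2 tau^2)) with
    tau = 1/(2 pi fc) and onset delay t0 = 4 tau, so the pulse starts near
    zero, peaks at |s| = a * ru (the arc length swept by a rotation of
    ``amplitude`` radians at radius ``ru``) and has its spectral peak at fc.
    """
    if fc <= 0:
        raise ValueError("centre frequency must be > 0")
    tau = 1.0 / (2 * np.pi * fc)
    t0 = 4.0 * tau
    x = (np.asarray(t, dtype=float) - t0) / tau
    out = amplitude * ru * x * np.exp(0.5 - 0.5 * x * x)
    return out if np.ndim(t) else float(out)


def tone_burst(fc: float, amplitude: float, ru: float, t, ramp_cycles: float = 2.0):
    """Continuous sine emitter waveform with a smooth squared-sine ramp.

    Used by the monochromatic verification studies; the ramp avoids the
    broadband transient of an abrupt switch-on.
    """
    if fc <= 0:
        raise ValueError("centre frequency must be > 0")
    tt = np.asarray(t, dtype=float)
    t_ramp = ramp_cycles / fc
    env = np.where(tt >= t_ramp, 1.0, np.sin(0.5 * np.pi * np.clip(tt, 0, t_ramp) / t_ramp) ** 2)
    out = amplitude * ru * env * np.sin(2 * np.pi * fc * tt)
    return out if np.ndim(t) else float(out)


@dataclass
class SourceSpec:
    """Emitter on the lumen-wall column: prescribed arc displacement.

    ``z_center``/``length`` (m) select the wall rows; ``samples`` holds the
    displacement at t = 0 .. n_steps * dt (length n_steps + 1).  After the
    sampled waveform the emitter is held at its final sample (zero for the
    packaged waveforms: the disk stays at rest in contact with the wall).
    """

    z_center: float
    length: float
    samples: np.ndarray

    def rows(self, grid: GridSpec) -> np.ndarray:
        half = self.length / 2.0
        j = np.nonzero(np.abs(grid.z_nodes - self.z_center) <= half + 1e-12)[0]
        if j.size == 0:
            j = np.array([grid.z_index(self.z_center)])
        return j

    def value(self, n: int) -> float:
        if n < len(self.samples):
            return float(self.samples[n])
        return float(self.samples[-1])


@dataclass
class Probe:
    """Averaging span of displacement nodes recorded every step."""

    i_index: int
    j_indices: np.ndarray
    label: str = ""


@dataclass
class ReceiverArray:
    """Uniform array of wall receivers (lumen-wall column, i = 0).

    Each receiver of length ``length`` centred at z records the mean u over
    the nodes it spans (a single node when the length is below dz).
    """

    z_positions: np.ndarray
    length: float

    @classmethod
    def uniform(cls, n: int, z_start: float, spacing: float, length: float) -> "ReceiverArray":
        return cls(z_positions=z_start + spacing * np.arange(n), length=float(length))

    def probes(self, grid: GridSpec, source: SourceSpec | None = None) -> list[Probe]:
        probes = []
        src_rows = set(source.rows(grid).tolist()) if source is not None else set()
        z_hi = (grid.n_z - 1) * grid.dz
        for z in self.z_positions:
            if not (0.0 <= z <= z_hi):
                raise ValueError(f"receiver at z={z * 1e3:.2f} mm lies outside the wall")
            half = max(self.length / 2.0, 0.0)
            j = np.nonzero(np.abs(grid.z_nodes - z) <= half + 1e-12)[0]
            if j.size == 0:
                j = np.array([grid.z_index(z)])
            if src_rows and set(j.tolist()) & src_rows:
                raise ValueError(
                    f"receiver at z={z * 1e3:.2f} mm overlaps the emitter rows"
                )
            probes.append(Probe(i_index=0, j_indices=j, label=f"z={z * 1e3:.3f}mm"))
        return probes


@dataclass
class FieldState:
    """All evolving arrays at one time level (quiescent start)."""

    u: np.ndarray                 # (NR, NZ) displacement at t^n
    u_prev: np.ndarray            # displacement at t^{n-1}
    eps_rt_hist: np.ndarray       # (L+1, NR-1, NZ) strain ring buffer
    eps_tz_hist: np.ndarray       # (L+1, NR, NZ-1)
    sig_rt: np.ndarray            # (NR-1, NZ)
    sig_tz: np.ndarray            # (NR, NZ-1)
    psi_dudr: np.ndarray          # PML memory: d(u)/dr
    psi_dudz: np.ndarray          # PML memory: d(u)/dz
    psi_dsr: np.ndarray           # PML memory: d(sig_rt)/dr
    psi_dsz: np.ndarray           # PML memory: d(sig_tz)/dz
    n: int = 0                    # current time level


@dataclass
class SimulationResult:
    """Receiver traces, optional snapshots and run diagnostics."""

    times: np.ndarray                      # (n_steps + 1,)
    traces: np.ndarray                     # (n_steps + 1, n_probes)
    probe_labels: list[str]
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    max_displacement: float = 0.0          # max |u| over interior, all steps
    max_u_per_step: np.ndarray | None = None   # (n_steps + 1,) interior max |u|
    max_shear_strain: float = 0.0          # max engineering gamma = 2 sqrt(ert^2+etz^2)
    max_tensor_strain: float = 0.0         # max sqrt(ert^2 + etz^2)
    stable: bool = True
    failed_step: int | None = None
    dt: float = 0.0
    grid: GridSpec | None = None

    def trace(self, k: int) -> np.ndarray:
        return self.traces[:, k]


class TorsionalSolver:
    """FDTD time stepper for one grid / material map / discretisation.

    Parameters
    ----------
    grid : GridSpec
    materials : MaterialMap
        Per-cell fields; averaged onto the staggered locations at init.
    dt : float
        Time step, s.
    t_memory : float or None
        Effective memory time t_L (s) for the GL short-memory truncation;
        ``None`` keeps the full history of the run (L = number of steps --
        set via ``prepare(n_steps)``).
    pml : PMLProfile, optional
        Defaults to a profile built from the background elastic velocity
        (m = 2, R0 = 1e-6).  Pass a zero-thickness grid for a reflecting box.
    """

    def __init__(
        self,
        grid: GridSpec,
        materials: MaterialMap,
        dt: float,
        t_memory: float | None = None,
        pml: PMLProfile | None = None,
    ):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.grid = grid
        self.materials = materials
        self.dt = float(dt)
        self.t_memory = t_memory
        if pml is None:
            pml = build_pml(grid, materials.background.elastic_velocity)
        self.pml = pml

        half = half_node_materials(materials)
        self.mu_rt = half["mu_rt"]
        self.eta_rt = half["eta_rt"]
        self.mu_tz = half["mu_tz"]
        self.eta_tz = half["eta_tz"]
        self.alpha_rt = half["alpha_rt"]
        self.alpha_tz = half["alpha_tz"]
        self.rho = half["rho"]
        self.alphas = np.unique(
            np.concatenate([self.alpha_rt.ravel(), self.alpha_tz.ravel()])
        )

        # recursive-convolution coefficients; sigma = 0 gives a = 0 (no-op)
        def _ba(sigma, alpha):
            b = np.exp(-(sigma + alpha) * self.dt)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(sigma + alpha > 0,
                             sigma / np.maximum(sigma + alpha, 1e-300) * (b - 1.0),
                             0.0)
            return b, a

        self._b_rh, self._a_rh = _ba(pml.sigma_r_half[:, None], pml.alpha_r_half[:, None])
        self._b_rn, self._a_rn = _ba(pml.sigma_r_nodes[:, None], pml.alpha_r_nodes[:, None])
        self._b_zn, self._a_zn = _ba(pml.sigma_z_nodes[None, :], pml.alpha_z_nodes[None, :])
        self._b_zh, self._a_zh = _ba(pml.sigma_z_half[None, :], pml.alpha_z_half[None, :])

        self._r_half = grid.r_half[:, None]
        self._r_nodes = grid.r_nodes[:, None]
        self._coeffs: dict[float, np.ndarray] = {}
        self._L: int | None = None
        self.state: FieldState | None = None

    # ------------------------------------------------------------------
    def prepare(self, n_steps: int) -> FieldState:
        """Allocate the field state and GL tables for an ``n_steps`` run."""
        if self.t_memory is None:
            L = n_steps
        else:
            L = min(memory_steps(self.t_memory, self.dt), n_steps)
        self._L = L
        self._coeffs = {
            float(a): gl_coefficients(float(a), L) for a in self.alphas
        }
        nr, nz = self.grid.nr_tot, self.grid.nz_tot
        lp1 = L + 1
        self.state = FieldState(
            u=np.zeros((nr, nz)),
            u_prev=np.zeros((nr, nz)),
            eps_rt_hist=np.zeros((lp1, nr - 1, nz)),
            eps_tz_hist=np.zeros((lp1, nr, max(nz - 1, 0))),
            sig_rt=np.zeros((nr - 1, nz)),
            sig_tz=np.zeros((nr, max(nz - 1, 0))),
            psi_dudr=np.zeros((nr - 1, nz)),
            psi_dudz=np.zeros((nr, max(nz - 1, 0))),
            psi_dsr=np.zeros((nr, nz)),
            psi_dsz=np.zeros((nr, nz)),
        )
        return self.state

    # ------------------------------------------------------------------
    def compute_strains(self) -> tuple[np.ndarray, np.ndarray]:
        """Strains at t^n from u^n; pushes them onto the history ring.

        Spatial derivatives inside the PML collars are stretched through
        the recursive-convolution memory variables.
        """
        st = self.state
        g = self.grid
        u = st.u
        dudr = (u[1:, :] - u[:-1, :]) / g.dr
        st.psi_dudr = self._b_rh * st.psi_dudr + self._a_rh * dudr
        ubar = 0.5 * (u[1:, :] + u[:-1, :])
        eps_rt = 0.5 * ((dudr + st.psi_dudr) - ubar / self._r_half)
        if g.nz_tot > 1:
            dudz = (u[:, 1:] - u[:, :-1]) / g.dz
            st.psi_dudz = self._b_zh * st.psi_dudz + self._a_zh * dudz
            eps_tz = 0.5 * (dudz + st.psi_dudz)
        else:
            eps_tz = st.eps_tz_hist[0]  # empty
        slot = st.n % st.eps_rt_hist.shape[0]
        st.eps_rt_hist[slot] = eps_rt
        if g.nz_tot > 1:
            st.eps_tz_hist[slot] = eps_tz
        return eps_rt, eps_tz

    def _gl_sum(self, hist: np.ndarray, alpha_map: np.ndarray) -> np.ndarray:
        """dt^-alpha weighted GL history sum at every half node."""
        lp1 = hist.shape[0]
        n = self.state.n
        out = None
        for a, c in self._coeffs.items():
            w = c[(n - np.arange(lp1)) % lp1]
            # slots not yet written hold zeros, so no elapsed-step masking
            # is needed early in the run
            s = (self.dt**-a) * np.tensordot(w, hist, axes=(0, 0))
            if len(self._coeffs) == 1:
                return s
            out = s if out is None else np.where(np.isclose(alpha_map, a), s, out)
        return out

    def compute_stresses(self) -> tuple[np.ndarray, np.ndarray]:
        """KVFD stresses at t^n: sig = 2 mu eps + 2 eta * GL(eps history)."""
        st = self.state
        slot = st.n % st.eps_rt_hist.shape[0]
        eps_rt = st.eps_rt_hist[slot]
        st.sig_rt = 2.0 * self.mu_rt * eps_rt + 2.0 * self.eta_rt * self._gl_sum(
            st.eps_rt_hist, self.alpha_rt
        )
        if self.grid.nz_tot > 1:
            eps_tz = st.eps_tz_hist[slot]
            st.sig_tz = 2.0 * self.mu_tz * eps_tz + 2.0 * self.eta_tz * self._gl_sum(
                st.eps_tz_hist, self.alpha_tz
            )
        return st.sig_rt, st.sig_tz

    def update_displacement(self) -> np.ndarray:
        """Advance u to t^{n+1} from the momentum balance at t^n.

        The lumen-wall column uses the antisymmetric stress image
        (traction-free surface); the outer edges are held at zero behind
        the PML collars.
        """
        st = self.state
        g = self.grid
        nr, nz = g.nr_tot, g.nz_tot
        sig = st.sig_rt
        div_r = np.empty((nr, nz))
        div_r[0, :] = 2.0 * sig[0, :] / g.dr          # image: sig(-1/2) = -sig(+1/2)
        div_r[1:-1, :] = (sig[1:, :] - sig[:-1, :]) / g.dr
        div_r[-1, :] = 0.0
        st.psi_dsr = self._b_rn * st.psi_dsr + self._a_rn * div_r
        rhs = div_r + st.psi_dsr

        sbar = np.empty((nr, nz))
        sbar[0, :] = 0.0                               # image average vanishes
        sbar[1:-1, :] = 0.5 * (sig[1:, :] + sig[:-1, :])
        sbar[-1, :] = 0.0
        rhs += 2.0 * sbar / self._r_nodes

        if nz > 1:
            sz = st.sig_tz
            div_z = np.zeros((nr, nz))
            div_z[:, 1:-1] = (sz[:, 1:] - sz[:, :-1]) / g.dz
            st.psi_dsz = self._b_zn * st.psi_dsz + self._a_zn * div_z
            rhs += div_z + st.psi_dsz

        u_new = 2.0 * st.u - st.u_prev + (self.dt**2 / self.rho) * rhs
        u_new[-1, :] = 0.0
        if nz > 1:
            u_new[:, 0] = 0.0
            u_new[:, -1] = 0.0
        return u_new

    def apply_boundaries(self, u_new: np.ndarray, source: SourceSpec, n_new: int) -> None:
        """Prescribe the emitter arc displacement at time level ``n_new``."""
        u_new[0, source.rows(self.grid)] = source.value(n_new)

    # ------------------------------------------------------------------
    def run(
        self,
        source: SourceSpec,
        n_steps: int,
        receivers: ReceiverArray | None = None,
        probes: list[Probe] | None = None,
        snapshot_times=(),
        raise_on_instability: bool = True,
        progress_interval: int = 0,
    ) -> SimulationResult:
        """Time-step the simulation and record probe traces.

        ``snapshot_times`` (s) are rounded to the nearest step; the full
        displacement array is stored for each.  With
        ``raise_on_instability=False`` a diverging run returns partial
        results flagged ``stable=False`` instead of raising.
        """
        g = self.grid
        st = self.prepare(n_steps)
        all_probes: list[Probe] = []
        if receivers is not None:
            all_probes.extend(receivers.probes(g, source))
        if probes:
            all_probes.extend(probes)

        times = self.dt * np.arange(n_steps + 1)
        traces = np.zeros((n_steps + 1, len(all_probes)))
        max_u_per_step = np.zeros(n_steps + 1)
        snap_steps = {int(round(t / self.dt)): float(t) for t in snapshot_times}

        ir = g.interior_r_slice()
        iz = g.interior_z_slice()
        # interior cell-centre slices for the strain diagnostic
        icr = slice(0, g.n_r - 1)
        icz = slice(g.j0, g.j0 + g.n_z - 1) if g.nz_tot > 1 else slice(0, 1)

        self.apply_boundaries(st.u, source, 0)
        for k, p in enumerate(all_probes):
            traces[0, k] = st.u[p.i_index, p.j_indices].mean()
        result = SimulationResult(
            times=times,
            traces=traces,
            probe_labels=[p.label for p in all_probes],
            dt=self.dt,
            grid=g,
        )
        if 0 in snap_steps:
            result.snapshots[snap_steps[0]] = st.u.copy()

        max_u = 0.0
        max_eps = 0.0
        try:
            for n in range(n_steps):
                st.n = n
                eps_rt, eps_tz = self.compute_strains()
                self.compute_stresses()
                u_new = self.update_displacement()
                self.apply_boundaries(u_new, source, n + 1)

                # diagnostics on the interior region only
                if g.nz_tot > 1:
                    ert_c = 0.5 * (eps_rt[icr, g.j0:g.j0 + g.n_z - 1]
                                   + eps_rt[icr, g.j0 + 1:g.j0 + g.n_z])
                    etz_c = 0.5 * (eps_tz[0:g.n_r - 1, icz]
                                   + eps_tz[1:g.n_r, icz])
                    eps_mag = np.sqrt(ert_c**2 + etz_c**2)
                else:
                    eps_mag = np.abs(eps_rt[icr, :])
                max_eps = max(max_eps, float(eps_mag.max()))
                step_max_u = float(np.abs(u_new[ir, iz]).max())
                max_u_per_step[n + 1] = step_max_u
                max_u = max(max_u, step_max_u)

                st.u_prev = st.u
                st.u = u_new
                for k, p in enumerate(all_probes):
                    traces[n + 1, k] = u_new[p.i_index, p.j_indices].mean()
                if (n + 1) in snap_steps:
                    result.snapshots[snap_steps[n + 1]] = u_new.copy()

                if (n + 1) % _CHECK_INTERVAL == 0 or n + 1 == n_steps:
                    if not np.isfinite(step_max_u) or step_max_u > _BLOWUP_DISPLACEMENT:
                        raise StabilityError(
                            n + 1,
                            f"max |u| = {step_max_u:.3g} m",
                        )
                if progress_interval and (n + 1) % progress_interval == 0:
                    log.info("step %d/%d  max|u| = %.3e m", n + 1, n_steps, step_max_u)
        except StabilityError as err:
            result.stable = False
            result.failed_step = err.step
            log.warning("%s", err)
            if raise_on_instability:
                result.max_displacement = max_u
                result.max_tensor_strain = max_eps
                result.max_shear_strain = 2.0 * max_eps
                raise
        result.max_displacement = max_u
        result.max_tensor_strain = max_eps
        result.max_shear_strain = 2.0 * max_eps
        result.max_u_per_step = max_u_per_step
        return result
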