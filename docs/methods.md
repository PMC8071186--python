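# Methods

## Constitutive model

Shear stress follows the Kelvin–Voigt fractional-derivative (KVFD) law
σ = 2(μ + η D_t^α)ε: a Hookean spring μ in parallel with a spring-pot
(η, α).  In the frequency domain G*(ω) = μ + η(iω)^α on the principal
branch, so the storage and loss moduli are G′ = μ + ηω^α cos(απ/2) and
G″ = ηω^α sin(απ/2).  For 0 < α ≤ 1 both |G*| and the plane-wave phase
velocity c(ω) — from ρc² = 2(G′² + G″²)/(G′ + √(G′² + G″²)), equivalent to
c = ω/Re k with k = ω√(ρ/G*) — are non-decreasing in ω, and the
attenuation −Im k follows a power law whose exponent interpolates between
the classical Kelvin–Voigt limits.  The spring-pot makes the phase
velocity unbounded as ω → ∞; consequences for causality testing are noted
below.

Presets: normal prostate μ = 3.0 kPa, η = 35 Pa·s^α, α = 0.35,
ρ = 1000 kg/m³; cancerous tissue scales μ and η by 1.2 (a minimum
clinically significant stiffness contrast) at unchanged α and ρ.  Over
100–1000 Hz these give c in 1.8–1.9 m/s and |G*| in 3.2–3.6 kPa when the
endpoints are *truncated* (not rounded) to one decimal — the truncation
convention is adopted deliberately because it reconciles the analytic
endpoint values (1.814/1.915 m/s, 3.289/3.658 kPa) with the
conventionally quoted ranges.

## Reduced wave problem

Axial symmetry with a purely azimuthal displacement u_θ(r, z, t) leaves a
single momentum balance,

ρ ∂²u_θ/∂t² = ∂σ_rθ/∂r + ∂σ_θz/∂z + (2/r)σ_rθ,

with ε_rθ = ½(∂u_θ/∂r − u_θ/r) and ε_θz = ½ ∂u_θ/∂z.  The domain is the
annular r–z rectangle outside the lumen (r ≥ r_u > 0), so no axis
singularity arises.  Volumetric (compressional) parameters vanish from
this reduction and are not modelled.

## Discretisation

**Staggering.**  Displacement nodes at (r_u + iΔr, jΔz); ε_rθ/σ_rθ at
radial half nodes; ε_θz/σ_θz at axial half nodes.  Spatial derivatives are
centred (second order); the acceleration uses the standard three-level
second difference.  The 1/r factors always use the exact staggered radial
coordinate of the evaluation point, and the half-node averages (ū in the
strain, σ̄_rθ in the curvature term) are arithmetic means of the two
neighbours — this combination makes the discrete rigid-rotation null
(u_θ ∝ r ⇒ zero strain, stress and acceleration) exact at machine
precision, which the tests assert.

**Fractional derivative.**  D_t^α is the Grünwald–Letnikov backward sum
Δt^{-α} Σ_k c_k ε^{n-k} with c_0 = 1, c_k = c_{k-1}(k−1−α)/k.  The newest
strain carries weight c_0 (semi-implicit in the newest strain, which is
available because strain is computed from displacement before stress).
Histories start from rest (quiescent zero) and live in a ring buffer of
depth L+1, where L = round(t_L/Δt) is capped at the elapsed step count;
coefficients are computed once per (α, L) and shared by all nodes of equal
α.  Per step the weighted sum is one tensor contraction over the ring
buffer, which keeps the 42 ms production run at ≈ 20 s on one core.

**Update ordering** per step n → n+1: strains at tⁿ from uⁿ (pushed onto
the ring); stresses at tⁿ with the GL sum ending at εⁿ; then uⁿ⁺¹ from
the momentum balance with the divergence at tⁿ.  All fields therefore
refer to a common time level, and the scheme stays fully explicit.

**Materials** are assigned per grid cell; stress half nodes take the
arithmetic mean of the two flanking cells (exact in homogeneous regions,
one half-cell transition band at interfaces), densities the mean of the
surrounding cells.  α is treated as a per-region constant: at an
interface half-node the α of the stiffer flanking cell is used rather
than an average, because the GL operator is only defined per single
order.  Both presets share α = 0.35, so this rule is inert in the
packaged scenarios.

## Boundaries

**Lumen wall (r = r_u).**  Traction free: the only traction component of
this field on an r-normal surface is σ_rθ, and it is imposed by an
antisymmetric image σ_rθ(r_u − Δr/2) = −σ_rθ(r_u + Δr/2), which zeroes
the interpolated traction exactly on the wall at second order.  On the
emitter rows the wall displacement is prescribed instead (Dirichlet): the
disk's arc displacement a·r_u with the configured waveform, held at its
final sample (zero) afterwards — the disk stays in contact at rest.

**Absorbing collars.**  PML collars of n_pml nodes are appended outside
the interior extents on the other three edges.  Each of the four spatial
derivative terms (two strain derivatives, two stress-divergence terms) is
stretched through one recursive-convolution memory variable.  The damping
profile is polynomial, σ(x) = σ_max(x/δ)^m with m = 2 and
σ_max = −(m+1)c_ref ln(R0)/(2δ), R0 = 1e−6, c_ref the background elastic
shear velocity.  A complex-frequency-shift profile
α_cfs(x) = α_max(1 − x/δ) with α_max = π·f_source accompanies it (the
customary grading).  The shift matters here: with plain real stretching
the late-time/grazing residual in the clinical echo window was ≈ 3× larger
and insensitive to σ strength or R0, i.e. absorber-pole limited, while
the causally clean physical floor is two orders lower.  The 1/r curvature
terms are left unstretched; the measured absorber quality (reflected
amplitude < 1 % of the outgoing peak against an enlarged reference domain;
echo-window residual ≈ 5·10⁻⁸ m vs a 2.3·10⁻⁴ m direct wave) is
sufficient for the packaged scenarios.

**Stability** is established empirically, mirroring trial-and-error
practice: the stability subcommand classifies candidate Δt values on the
most demanding medium (cancerous tissue, 1000 Hz, 18 elements per
wavelength); runs are monitored every 25 steps for NaN/Inf or |u| beyond
1 m and abort with the failing step.  Δt = 20 µs is stable for the
production scenario; 4× that diverges.

## Verification studies

**Numerical dispersion.**  A monochromatic wave launched from the whole
wall is z-invariant, so these studies run the exact radial reduction (one
z row) of the same solver — identical mathematics at ~1 % of the cost.
Velocity is measured by time-to-peak between probes nominally 5 and 15 mm
from the wall.  Peak picking: the first local maximum with prominence ≥
half the trace maximum identifies a common wavefront cycle at both
probes; the timing is then read four carrier cycles later (same offset at
both probes, preserving the pairing) with three-point parabolic
sub-sample refinement.  The offset is essential: on the onset ramp the
envelope slope biases carrier-peak times, and the bias (≈ +0.9 %,
resolution-independent) would otherwise swamp the grid error.  With it,
the error at 600 Hz is 0.38 % at 18 elements per wavelength and 0.13 % at
25, decreasing monotonically with resolution, and the elastic limit
(η = 0) reproduces √(μ/ρ) within 1 %.  Sub-sample refinement is needed
because the Δt = 20 µs sampling alone is ≈ 0.4 % of the 5.4 ms transit.

**Short-memory convergence.**  Relative l2 error of the receiver trace
against the full-memory (L = N) reference, swept over memory times at two
frequencies × two tissues (20 ms runs, Δt = 20 µs, ≥ 18 elements per
wavelength).  The error decreases monotonically with t_L and is exactly
zero (bitwise) at t_L = t_total.  It does **not** reach 0.1 % at
t_L ≈ 0.9 ms: for α = 0.35 the GL weights decay only as k^(−1.35), the
truncated operator symbol at L = 45 differs from (1−z⁻¹)^α by ≈ 3.6 % at
700 Hz, and the resulting |G*| perturbation, amplified by the ≈ 35 rad of
propagation phase to the measurement point, leaves an 8–10 % trace error
— confirmed both by direct symbol evaluation and by the solver, for
continuous and pulsed sources.  A figure of ≈ 0 % error at 0.9 ms has
been reported for this configuration elsewhere; it is not attainable by
plain GL truncation at these parameters, and this package reports the
honestly computed threshold instead.

**Clinical scenario.**  The packaged `prostate_table3` configuration runs
42 ms on the 150 µm grid (134 × 268 interior nodes plus collars) with
t_L = 1 ms.  Computed metrics: direct wave at all 32 receivers by
13.1 ms; maximum echo-window (26–42 ms) peak-to-peak displacement
0.126 µm, 22× the tumour-free control; maximum displacement 0.975 mm at
the emitter; maximum engineering shear strain ≈ 4.0 (γ = 2√(ε_rθ²+ε_θz²);
the tensor-strain maximum, half of it, is also reported).  Two of these
differ from previously published figures for the same setup, for reasons
the model itself makes quantitative: (i) an echo of order 2 µm is not
compatible with the preset's own attenuation (112 Np/m at 700 Hz — the
solver reproduces this to 1 % — gives e^(−5.9) ≈ 0.003 over the ≈ 52 mm
round trip *before* the ≈ 5 % amplitude reflectivity of a 1.2 stiffness
contrast); (ii) a maximum shear strain of a few percent is not compatible
with a 0.3 rad rotation of a 3.25 mm wall, since the u/r term of ε_rθ
alone contributes 30 % at the wall and the Dirichlet emitter edge is a
displacement-discontinuity singularity whose grid-limited strain at
150 µm spacing is O(1).  The computed values are reported as computed.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| Δr, Δz | 150 | µm | ≥ 18 elements per wavelength at 700 Hz in normal tissue |
| Δt | 20 | µs | empirically stable below the ≈ 25 µs threshold |
| t_total | 42 | ms | direct window (≤ 24 ms) plus echo window (26–42 ms) |
| t_L | 1.0 | ms | production memory time; L = 50 steps |
| n_pml | 60 | nodes | collar depth ≈ 3.4 wavelengths at 700 Hz |
| PML m, R0 | 2, 1e−6 | – | standard polynomial grading |
| PML α_max | π·f_src | 1/s | customary complex-frequency-shift grading |
| emitter | 700 Hz, 0.3 rad | – | Gaussian monocycle, t₀ = 4τ, peak a·r_u |
| receivers | 32 × 0.8 mm, 0.5 mm long | – | first centre at z = 3.0 mm, just beyond the 2 mm emitter (the start position is not otherwise constrained) |

Configs use TOML with explicit unit suffixes (`dr_um`, `t_total_ms`,
`mu_kpa`, ...); unknown keys are errors.  `save_config` emits base-SI
suffixes so a save/load round-trip is bit exact.

## Degenerate inputs, ties, tolerances

ω = 0 returns the elastic limit (ω^α → 0 for α > 0); η = 0 gives a purely
elastic solver; α = 1 reduces the GL sum to a backward first difference
and matches an independently coded classical Kelvin–Voigt solver to
1e−10; α = 0 adds η to the spring.  A zero-diameter inclusion is a no-op;
an inclusion touching the lumen or the collars is rejected.  Receivers
shorter than Δz sample the single nearest node.  Non-commensurate domain
extents round to the nearest node with a logged warning.  Causality tests
use the discrete domain of dependence (exact zero before one cell per
step) plus an attenuated-precursor bound, because the spring-pot's phase
velocity is unbounded and a strict frequency-independent front does not
exist.

## What the studies do and do not show

All verification inputs are generated in code; no measured data enters.
The monochromatic studies exercise the radial reduction only; the 2-D
solver's z-coupling is covered by the stencil oracle, the
Kelvin–Voigt cross-check and the clinical runs.  The tumour is a disk in
the r–z plane, i.e. a torus in 3-D — accepted for feasibility testing but
not representative of real tumour geometry.  Receiver noise, imperfect
disk–wall contact, and heterogeneity beyond a single inclusion are out of
scope, so passing tests demonstrate internal consistency of the forward
model, not clinical performance.
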