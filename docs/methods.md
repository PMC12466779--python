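# Methods

## Motional model

Orientational motion of each internuclear vector is described by a
bi-exponential correlation function

C(t)/C(0) = a₁ exp(−t/τ_c1) + (1 − a₁) exp(−t/τ_c2),  τ_c1 > τ_c2.

The fast component (τ_c2, sub-nanosecond to few-nanosecond) partially
randomizes local orientations; the slow component (τ_c1, tens to hundreds
of nanoseconds) completes the randomization. a₁ ∈ [0, 1] is the fraction
of the second-rank orientational correlation surviving the fast motion —
an order-parameter-squared in the model-free sense. C(0) is an overall
normalization and is not a free parameter.

Relaxation is assumed to be driven entirely by the stochastic modulation
of magnetic dipole-dipole couplings. Chemical-shift anisotropy and
quadrupolar mechanisms are out of scope, and cross-correlations between
distinct couplings are ignored; rates from different pairs add.

### Rate expressions

For a dipole-coupled two-spin pair with coupling constant
d = (μ₀/4π) ℏ γ_X γ_Y / r³ and spectral densities J(ω) = 1/(1 + ω²τ_c²),
the single-correlation-time rates are the Solomon longitudinal and
transverse expressions and the Jones / Bleich–Glasel rotating-frame
expressions:

* R₁(XY) = (d²τ_c/10)[J(ω_X−ω_Y) + 3J(ω_X) + 6J(ω_X+ω_Y)]
* R₁(XX) = (3d²τ_c/10)[J(ω_X) + 4J(2ω_X)]
* R₂(XY) = (d²τ_c/20)[4 + J(ω_X−ω_Y) + 3J(ω_X) + 6J(ω_Y) + 6J(ω_X+ω_Y)]
* R₂(XX) = (d²τ_c/20)[9 + 15J(ω_X) + 6J(2ω_X)]
* R₁ρ(XY) = (d²τ_c/40)[8J(ω₁) + J(ω_X−ω_Y±ω₁) + 3J(ω_X±ω₁) + 6J(ω_Y±ω₁) + 6J(ω_X+ω_Y±ω₁)]  (± terms summed separately)
* R₁ρ(XX) = (d²τ_c/40)[18J(ω₁) + 3J(ω_X±ω₁) + 12J(ω_X±2ω₁) + 3J(2ω_X±ω₁) + 3J(2ω_X±2ω₁)]

Two limits pin these down and are asserted in tests: in extreme narrowing
all three channels collapse to d²τ_c (hetero) or 1.5 d²τ_c (homo), and
R₁ρ reduces exactly to R₂ at ω₁ = 0. Lorentzians are evaluated in double
precision with no small-τ approximations (the grid spans four decades of
ωτ). Net two-timescale rates are a₁ R(τ_c1) + (1−a₁) R(τ_c2).

The coupling-constant prefactor μ₀/4π makes d come out in rad/s in SI
units; with CODATA gyromagnetic ratios it gives 1.426×10⁵ rad/s for the
one-bond ¹H–¹³C pair at 0.110 nm and 1.384×10⁵ rad/s for the geminal
¹H–¹H pair at 0.176 nm.

### Site classes

Two approximate spin topologies are analyzable as two-spin systems:

* **methine-CH** — a ¹³C relaxed by its one-bond ¹H; observables
  {T₁C, T₂C}.
* **methylene-HH+HC** — a methylene ¹H relaxed by its geminal ¹H partner
  plus the one-bond ¹³C; observables {T₁H, T₁ρH, T₂H}, each rate the sum
  of homonuclear and heteronuclear contributions.

The spectrometer context defaults to the study's field (¹H at 599.1 MHz,
i.e. B₀ = 14.095 T; the nominal "14.1 T" differs by 0.03%) with a 10 kHz
spin-lock field. Frequencies are angular internally; interfaces accept Hz.

## Decay fitting

Curves A(t_rel) are fit by weighted least squares (weights 1/σᵢ, lmfit
Levenberg–Marquardt, relative tolerance 10⁻¹⁰, ≤500 iterations per free
parameter). Build-up channels (T₁H, T₁C; inversion recovery) use
a + b exp(−t/T) with free offset; decay channels use b exp(−t/T) or the
stretched form b exp(−(t/T)^β), β ∈ (0.2, 1]. Initial values: b from the
first point, T from the t at which the amplitude crosses b/e, a from the
last point, β start 0.9. A fit hitting the β lower bound is flagged
rather than silently returned.

Model selection follows the measurement protocol: a single-exponential
fit is adequate if reduced χ² = χ²/(N − p) < 2.0; if any temperature of a
site+channel fails, all temperatures of that site+channel are refit with
the stretched model, so the model choice is uniform per site+channel.
Peak-height and peak-area amplitude modes differ only in how σ was
obtained upstream; the fitter treats them identically.

Temperature series are screened with a weighted quadratic fit; the
maximum |residual/σ| is the smoothness diagnostic, with 3 as the
conventional (configurable) outlier cut. A genuine phase transition would
produce a step that this flags; smooth Arrhenius-like trends do not.

## Grid inference

For one site and temperature, χ²(τ_c1, τ_c2) = Σ_μ [1/T_μ − a₁R_μ(τ_c1) −
(1−a₁)R_μ(τ_c2)]²/σ_μ² is evaluated on a 100×100 grid, log-uniform with
endpoints included, τ_c1 ∈ [10, 500] ns, τ_c2 ∈ [0.1, 9] ns. The model is
linear in a₁, so the minimizing a₁ is closed-form; it is deliberately not
clamped to [0, 1] (clamping would silently change χ² and the posterior),
and out-of-range values where posterior weight is non-negligible are
flagged.

Because acceptable χ² values occupy broad grid regions, the reported
parameters are probability-weighted averages and standard deviations with
weights exp(−χ²)·δ₁(j)·δ₂(k), where δ are the local linear-τ grid
spacings (centered differences, one-sided at endpoints). χ² is shifted by
its grid minimum before exponentiation — invariant under the
normalization and immune to underflow (exp(−χ²) underflows past ~700).
Degenerate grid points (identical rates at both τ values) receive zero
weight and are counted in a diagnostics field.

The two-timescale parameters of a single site are individually poorly
determined (SDs comparable to means); that is a property of the data, and
the posterior summaries carry it honestly. Off-grid continuous
optimization and temperature-coupled global fits are non-goals.

## Cone geometry

If fast motion randomizes a bond direction uniformly within a cone of
half-angle β, the surviving correlation fraction is
a₁ = cos²β(cosβ+1)²/4, the square of the first-power coupling scaling
s = cosβ(cosβ+1)/2 (the closed forms agree with direct quadrature of the
P₂ cone average to 10⁻⁸). a₁ inversion is restricted to the monotone
branch β ∈ [0°, 90°]; the echo-based scaling bound is inverted on the
large-angle branch β ∈ (120°, 180°], where |s| decreases monotonically
from 1/8 to 0 — the physically relevant branch for nearly isotropic
motion (|s| = 1/50 also occurs near 92°, which the small-residual
interpretation excludes). Note the two conventions: relaxation weights
couplings by a₁ = s², while the echo bound uses |s| to first power; both
are implemented as stated.

## Spin-echo simulation

The simulator propagates N ≤ 6 like spins under the secular homonuclear
dipolar Hamiltonian Σ b_ij f_ij(t) (2I_zi I_zj − I_xi I_xj − I_yi I_yj)
plus isotropic shift offsets, with the standard MAS time dependence
f(t) = −(√2/2) sin2β_p cos(ω_r t + γ_p) + (1/2) sin²β_p cos2(ω_r t + γ_p)
for an internuclear vector at polar angles (β_p, γ_p) in the rotor frame
(rotor at the magic angle; f averages to zero over a rotor period).
Heteronuclear couplings and ¹H CSA are excluded; finite-pulse effects and
relaxation during the echo are out of scope.

Protocol: n rotor periods — ideal π pulse about y — n rotor periods,
starting from ρ ∝ ΣI_x; the complex signal is read against the
transverse detection operators and normalized to the coupling-free echo,
so a fully refocused echo has amplitude +1. Propagation is
piecewise-constant (default 200 steps per rotor period, with a built-in
halving convergence check); one rotor-period propagator is computed per
crystallite and taken to integer powers. Powder averaging uses a
deterministic golden-ratio three-angle set (default 144 orientations,
equal weights) — reproducible without randomness.

The default four-spin system is two geminal ¹H pairs (r = 0.176 nm) with
0.25 nm closest approach. The real multi-spin geometry of the peptide is
unknown, so only scheme-independent properties are relied on: the
two-spin rotor-synchronized echo is exactly 1 (self-commuting
Hamiltonian with vanishing phase integral), λ = 0 gives amplitude 1 for
any shifts, echo decay accelerates monotonically with the global coupling
scale λ, and powder/step-size doubling changes amplitudes by <1%. At
λ = 1 with 20 kHz-scale couplings and ~1 kHz MAS the echo decays within
one rotor period, so decay-shape tests probe intermediate λ where the
decay is resolved on the sampled grid. `bound_scaling_factor` bisects in
λ for the largest λ whose simulated T₂ is at least the measured one;
1/λ is the inferred minimum coupling-reduction factor.

## Solomon cross-relaxation check

The forward rate model omits cross-relaxation. The check integrates the
coupled two-spin longitudinal Solomon equations for a ¹H–¹³C pair (auto
rates from the heteronuclear R₁ structure; cross rate
(d²τ/10)[6J(ω_H+ω_C) − J(ω_H−ω_C)]; both weighted over the two
correlation times) by exact 2×2 matrix exponential. Equilibrium
magnetizations are proportional to γ. With the ¹H spin left at
equilibrium, cross-on and cross-off ¹³C inversion-recovery curves differ
by <0.5% of the recovery range for (a₁ = 0.25, τ_c1 = 50 ns,
τ_c2 = 1 ns) at 14.1 T — cross-relaxation is negligible for the
measurement design. Inverting the ¹H spin as well produces a clear
transient overshoot, the classic cross-relaxation signature.

## Nanopore arithmetic

Porosity from areal pore density: φ = ρ_pore·π(d/2)²; gravimetric
porosity from the water mass gained on soaking. Internal area assumes
smooth cylindrical pore walls; the exterior-area convention subtracts
pore openings from the flat faces and adds the rim (this reproduces the
230 mm² figure; a plain cylinder gives 267 mm² — the convention is
inferred, not stated upstream). Tether spacing projects all molecules in
a pore onto its wall, σ = C·N_A·r/2, and reports the square-lattice mean
spacing 1/√σ (a 2-D Poisson nearest-neighbor convention, 0.5/√σ, is
exposed as an option). The loading chain uses the rounded 15% porosity
when reproducing the printed concentration figures; the measured
14.7%/16.3% values are selectable.

## Synthetic data

The generator emulates the data products of the measurements, not the
spectra: decay amplitudes with Gaussian noise whose RMS equals the quoted
per-point σ (the peak-height uncertainty convention), observation-set
rates with fractional Gaussian noise (default 5%), and temperature series
from smooth truth maps — constant a₁ and τ_c1, Arrhenius-like τ_c2 with a
12 kJ/mol apparent activation energy (a mild slope consistent with weak
observed trends) — with optional injected discontinuities as the
phase-transition counterfactual. Default t_rel schedules are 8 log-spaced
points on [T/8, 4T]. All generators are pure functions of (plan, seed).

What passing tests show is therefore internal consistency: the pipeline
recovers known truths from data with the assumed statistical structure.
Real data add multi-spin relaxation pathways, ¹H spin diffusion,
baseline/phasing artifacts, and non-Gaussian noise, none of which the
generator emulates.

## Problem sizes

Default test and demonstration sizes: 100×100 grid evaluations are fully
vectorized (~10 ms per observation set); recovery studies use 50
replicates; fit-calibration studies 200 replicates; echo simulations use
16–144 powder orientations and 100–200 steps per rotor period with echo
trains up to 24 rotor periods. These sizes give stable statistics while
keeping the full suite fast on a single CPU.

## Known limitations

* Two-spin treatment of methine/methylene sites is approximate; remote
  couplings and cross-correlations are neglected by construction.
* a₁ and τ_c1 are strongly correlated given only 2–3 observables; single
  posterior summaries should not be over-interpreted site by site.
* The four-spin echo geometry is a stand-in; only the bound logic, not
  the absolute simulated T₂, transfers to real samples.
* The stretched-exponential T is reported as-is; no moment conversion to
  a mean relaxation time is applied.
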