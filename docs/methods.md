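# Methods

## The rigid-body model and its coordinate conventions

Each motor of an MT-bound dynein dimer is treated as a rigid body that
flexes only at the stalk-stalkhead hinge, which sits a height h₀ above the
MT surface.  All axial coordinates are in nm and increase toward the MT
minus end (the stepping direction); heights are perpendicular distances
from the MT surface line in the projected side view.  Angles are degrees
at every interface and radians only inside energy and stiffness formulas.

Default motor dimensions (`MotorGeometry`): ring-centre-to-hinge distance
R = 18.8 nm, head radius 6.5 nm, hence lever length L = R − 6.5 = 12.3 nm
(the distance from the hinge to the base of the stalk, where the linker
ends and axial load is applied).  The hinge height h₀ is not directly
measurable in projection; the default 1.8 nm is fixed by requiring the
mean ring height at the 42° mean stalk angle to be the observed 14.4 nm
(14.4 − 18.8·sin 42° ≈ 1.8).  It is an ordinary parameter and can be
refit.

Deduction chain: θ = arcsin((h − h₀)/R); stalkhead position
x_sh = x_ring + R·cos θ.  Measurement noise can push the arcsin argument
marginally above 1; arguments in (1, 1.02] are clamped to 90° and flagged,
larger ones are errors.  Within a dimer the *leading* motor is the one
whose stalkhead (not ring) is further minus-end-ward; exact ties are
broken toward the lower particle id and flagged.  Ring separation is
signed and negative exactly for crossed-stalk dimers.

## Particle selection

The isolation rule works on axial distances only: two heads < 40 nm apart
form a candidate dimer if no third head lies within 40 nm of either
member; a head whose nearest neighbour is > 40 nm away is an isolated
single (superposed dimer or monomer, discriminated by intensity).
Distances equal to the exclusion disqualify.  Because any head lying
between the members of a valid pair would violate the exclusion itself,
valid pairs are adjacent in axial order and a sorted linear scan suffices;
the tests pin it to an O(n²) brute-force oracle.

Pixel-sum discrimination first shifts the image so the background ice has
zero mean, then divides the particle-region sum by the adjacent-MT-region
sum.  A ratio ≥ 1.5× the monomer reference (boundary inclusive; the
midpoint between the expected 1× and 2×) classifies the particle as a
superposed dimer.  The threshold is a parameter.

## The Boltzmann generator

For stalkheads fixed a lattice separation x apart, the dimer energy is

    E(θ_t, θ_l) = ½κ_t(θ_t − θ₀)² + ½κ_l(θ_l − θ₀)²
                  + ½k_tether(ext − d₀)²,
    ext = x − L_a·cos θ_l + L_a·cos θ_t,

with θ₀ = 42°, κ_t/κ_l/κ_sup defaulting to 71/72/101 pN nm rad⁻², tether
stiffness 0.035 pN nm⁻¹ and rest extension d₀ = 0 (the superposed
configuration, with the linker ends stacked, is the zero-strain state of
the head–head linkage).

The tether attachment length L_a defaults to the lever length (12.3 nm),
i.e. the tether connects the linker ends at the base of the stalks, where
the GST dimeriser is actually seen, close to the MT surface.  This choice
is forced by self-consistency: torque balance at the hinge gives
dF/dx = κ·|dθ/dx|/(L_a·sin θ), so with L_a = 12.3, the default κ ≈ 71 and
k_tether = 0.035 reproduce angle-vs-separation slopes of ≈ ±0.22° nm⁻¹ —
the observed values — whereas attaching the tether at the ring centres
(18.8 nm) would predict ±0.35° nm⁻¹ and break the recovery of k_tether by
the analysis chain (which uses the 12.3-nm lever) by a fixed factor of
18.8/12.3.  L_a is exposed as a parameter.

Sampling: the coupled density is non-Gaussian (through the cosine terms),
so angle pairs are drawn by a Metropolis random walk with isotropic 5°
Gaussian proposals, 1,000-sweep burn-in and thinning of 10, run as up to
256 parallel chains initialised at the rest angle; tests compare moments
against 400×400 grid quadrature of exp(−E/k_BT) using block-resampled
standard errors.  The single-hinge (superposed) density is exactly
Gaussian with s.d. √(k_BT/κ) and is sampled directly.  k_BT is computed
from the Boltzmann constant at T = 293 K (4.0453 pN nm); a user-supplied
thermal energy must agree within 0.1%.

Forward projection: ring height h = h₀ + R·sin θ, ring axial position
x_ring = x_sh − R·cos θ, plus independent Gaussian measurement noise on
both coordinates (default s.d. 1.0 nm, a plausible single-particle
alignment error; at zero noise the table round-trips exactly).  Sampled
angles occasionally leave (0°, 90°): past vertical the projected height
folds (the deduction returns 180° − θ, as it would on a real micrograph),
and below 0° the ring drops under the hinge and the measurement stage
discards the particle as unmeasurable.  Both behaviours are the honest
projection physics rather than clipping.

Generator defaults for the particle field: 2,000 dimers, half superposed;
offset separations drawn from {0.9: 0.10, 8.3: 0.55, 16.6: 0.25,
24.9: 0.10} (most stalkheads ~8 nm apart, fewer ~16 nm, few ~25 nm);
crowding density 1 molecule per 100 nm of a 2,000-nm MT, which leaves a
realistic fraction of molecules failing the ±40-nm isolation rule.

The toy renderer draws the MT as a uniform band, each ring as an annulus
of outer radius 6.5 nm (drawn twice for superposed dimers, so intensities
are exactly additive) and the stalk as a line segment, protein pale on a
zero-mean background; optional white Gaussian noise sets the SNR.  It
supports the pixel-sum tests, not image realism: there is no CTF, ice
gradient or projection physics.

Run-length simulation: per mechanical cycle a run terminates with
probability (1 − r)² (both heads detached); completed cycles are
geometric and the run length is cycles × step.

## The estimation chain

Equipartition uses the raw angle s.d. with denominator n − 1.  OLS is
unweighted (`scipy.stats.linregress`).  Running averages slide a
100-point window over the data sorted by stalkhead separation, advancing
one point at a time (n − window + 1 outputs), each window reduced with
plain mean/s.d. so the result equals naive recomputation exactly.

Per-class mean angles (not a generic 42°) enter the cantilever and
tension formulas: with the printed κ and σ values this yields the
cantilever triplet 1.07/1.03/1.53 pN nm⁻¹ and tensions per nm of 0.033
(trailing) and 0.031 (leading), averaging 0.032 pN nm⁻¹, hence 0.26/0.53/
0.79 pN at the 8.3/16.6/24.9-nm separation classes.

Ring separation from the two regression lines is provided in two modes
that deliberately disagree and are never silently reconciled:

* `as_published` — the linearized form
  ring_sep(x) = x·[1 − L·(sin b_t·|m_t| + sin b_l·|m_l|)_rad] +
  L·(cos b_l − cos b_t), which reproduces the published −0.1/6.6/14.2/
  21.7 nm at the four separation classes;
* `geometric` — the self-consistent rigid-body evaluation
  x − R·cos θ_l(x) + R·cos θ_t(x), which gives ≈ +0.9 nm at x = 0 and is
  the convention the generator itself obeys (used by the closure tests).

The tether stiffness divides the tension increment between the 8.3- and
16.6-nm classes by the corresponding ring-separation increment.  The
head–head equilibrium constant is the ratio of superposed-ring to
offset-ring counts among molecules with superposed stalkheads (318/31 ≈
10 under no load).

Duty ratio: the median-run criterion (1 − (1 − r)²)^N = ½ is solved by
bisection to 10⁻⁸; it reproduces 0.86/0.90/0.93 for N = 36/72/144 (600-nm
runs at 16.6/8.3/4.15-nm steps).  Whether the underlying formalism pins
the median or the mean run is not decidable from the available
description; the mean criterion N = 1/(1 − r)² is provided behind a flag
and the choice is recorded in the kinetics report.

CDF fits evaluate the empirical CDF at the sorted data points with the
Hazen plotting position (i − ½)/n — this keeps the fit invariant under
re-ordering and under duplication of the whole sample — and fit
F(l) = 1 − exp(−(l − l₀)/l_mean) (runs, durations; l₀ a detection floor
bounded by the sample minimum) or the erf Gaussian CDF (velocities) by
nonlinear least squares.  Fits refuse fewer than 20 events or degenerate
(constant) samples.

The ATP budget check evaluates the Michaelis–Menten per-head rate
k_cat·[MT]/([MT] + K_m) (defaults 15 s⁻¹, 2.5 μM) and confirms that 0.66
μM heads on 3.7 μM MT over 46 s consume < 0.3 mM of 3.6 mM ATP.

## What passing tests do and do not show

The generator emulates: angle distributions with the observed means and
spreads, ring heights 14.4 ± 3 nm, the discrete lattice separations and
the tether-induced ±0.2° nm⁻¹ angle–separation coupling, crowded/sparse
placement, additive two-ring intensities, and geometric run lengths.  It
does not emulate alignment pseudo-correlations, CTF effects, azimuthal
(around-MT) geometry, flexibility outside the one hinge, or
force-dependent detachment.  Consequently the closure tests demonstrate
that the estimation chain inverts the stated mechanical model — not that
the model is the correct description of any particular data set.  At the
default 1-nm measurement noise the apparent angle spread is inflated
(biasing κ low ~10%) and the regression errors become correlated between
axes; the parameter-recovery tests therefore run the generator at zero
noise, and a real analysis would need a noise deconvolution that is out
of scope here.

## Problem sizes and numerical choices

Closure tests use n = 10⁵ samples for equipartition recovery (χ²
sampling error < 1%; 5% assertion bound), 10⁴ per separation class for
the tether chain (25% bound, dominated by the chain's linearization bias,
empirically ~5%), 10⁵ simulated runs for the duty-ratio closure (3%
bound; the discrete geometric median at N = 36 sits on the 35/36-step
boundary, worst case 2.8%), and 200 noisy renders at SNR 2 for the
pixel-sum discrimination ([1.8, 2.2] band).  Bisection and curve fits use
scipy defaults with explicit bounds; Metropolis chains are seeded with
`numpy.random.default_rng` and all derived seeds stay below 2³¹.
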