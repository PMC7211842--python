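# Methods

`fimpull` analyzes single-molecule pulling experiments on the FimG subunit
of the type 1 pilus: AFM force–extension traces of a polyprotein construct
(four I91 titin marker domains flanking one FimG domain, which carries the
donated β-strand of the neighbouring subunit FimF), and steered-MD-style
pull curves of the same protein. Its purpose is to extract the unfolding
work distribution of FimG from both routes and to estimate the free-energy
difference of unfolding from those distributions. Since the deposited raw
datasets are not bundled, a synthetic generator with exactly known ground
truth reproduces the statistical structure of both kinds of data; all tests
and the acceptance script run against it.

## Polymer models

Branch elasticity of the AFM traces uses the worm-like chain in the
Bouchiat et al. interpolation,

    F(x) = (kB T / P) [ z − 1/4 + 1/(4(1−z)²) + Σ_{i=2..7} a_i z^i ],
    z = x/L,

with the published correction coefficients a₂…a₇ (= −0.5164228, −2.737418,
16.07497, −38.87607, 39.49944, −14.17718). Free parameters per branch are
the persistence length `P` (nm) and contour length `L` (nm). The stretch
free energy ∫₀ˣ F dx′ is evaluated in closed form — every term of the
bracket has an elementary antiderivative — and cross-checked against
adaptive quadrature to 1e−8 relative in the test suite.

The post-unfolding baseline of SMD traces uses the extensible freely
jointed chain of Smith et al.,

    x(F) = L [ coth(u) − 1/u ] (1 + F/K),   u = F·b / kB T,

with Kuhn length `b`, contour length `L` and stretch modulus `K` (pN); the
(1 + F/K) factor captures the non-entropic backbone stretching that
dominates once the chain is held only by its disulfide loop. The force at
given extension is obtained by monotone bracketing (Brent) to 1e−9
relative.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective). WLC fits use force residuals with initial guess
P = 0.4 nm, L = 1.05 × max extension, and L constrained above the largest
extension in the branch. FJC fits use force-space residuals computed by
inverse interpolation of the closed-form x(F) on a dense grid; residuals in
extension space proved badly weighted when noise sits on the force channel,
because the compliant low-force region converts small force noise into
large extension discrepancies. A fit that lands on a parameter bound is
reported `converged=False`: bound-stuck solutions are untrustworthy and
must stay visible to the acceptance filters.

Constants: kB·T at 300 K = 4.1419 pN·nm; 1 kcal/mol = 6.9477 pN·nm. The
default temperature everywhere is 300 K (the simulation temperature; the
experimental lab temperature is not separately specified), configurable on
every interface.

## AFM trace analyzer

Each raw trace passes through a deterministic pipeline:

1. **Downsampling.** Points are averaged in consecutive 1-nm extension
   bins, taken in time order (a bin revisited later starts a new group), to
   remove fast oscillations around transitions.
2. **Origin.** The first negative-to-non-negative force crossing after the
   pushed contact region defines the extension origin; all downstream
   extensions are re-referenced to it. Traces with no contact region are
   auto-rejected.
3. **Extrema.** Transition midpoints are adjacent-bin force drops steeper
   than the derivative threshold (default 50 pN per 1-nm bin-step;
   consecutive drop steps merge into one transition). Each transition
   yields the preceding region maximum and the following region minimum;
   drops whose preceding peak force is below the threshold — derivative
   excursions of post-detachment noise — are ignored. The final drop's end
   marks the start of the flat tail.
4. **Endpoint refinement.** Within the raw samples bracketed by a detected
   maximum/minimum pair, the largest single-step force drop marks the rip;
   its flanking raw extensions are the transition endpoints (x₁, x₂).
   Bin-centre endpoints would carry a half-bin bias (several pN through the
   steep end of a branch); the refinement removes it.
5. **Branch fits.** Every branch (origin → first maximum, each minimum →
   next maximum) is fitted independently to the WLC on its binned points.
   Contour-length increments are differences of consecutive fitted `L`; the
   increment of a peak is the contour gained by the *following* branch.
6. **Classification.** The last maximum is the detachment candidate; among
   the rest, peaks below 300 pN are I91, at or above it FimG (the barrier
   sits near the minimum-overlap point of the two force distributions).
   The peak force is the fitted branch model evaluated at x₁ — unbiased
   under additive force noise, unlike the binned maximum (biased low by
   bin averaging) or the raw maximum (biased high by noise selection).
   When a branch fit is missing or unconverged, the binned force at x₁ is
   used so grouping stays meaningful on traces the fit-quality criterion
   will reject.
7. **Acceptance.** In order: flat tail after the final peak (length ≥ 20 nm
   and OLS |slope| < 0.01 pN/nm); 2–8 alternating maxima; 3–5 I91 peaks,
   exactly one FimG peak, detachment taller than all previous peaks; all
   branch fits converged with rmse < 100 pN (an unconverged fit fails this
   criterion regardless of its nominal residual); 0.01 < P < 1 nm for all
   branches; I91 increments in (25, 45) nm and the FimG increment < 100 nm
   (no lower bound is imposed on the FimG increment). Every criterion's
   outcome is recorded; the first failure is the primary rejection reason.

All thresholds live in `AnalyzerConfig` (YAML-serializable, defaults as
above); nothing in the analyzer is stochastic, so identical input and
config give identical output.

## Work and free energy

For a transition between branches fitted as f₁, f₂, from extension x₁ to
x₂, the unfolding work is

    W_unfold = W_rip − ΔG_s,
    W_rip  = (f₁(x₁) + f₂(x₂)) (x₂ − x₁) / 2,
    ΔG_s   = ∫₀^{x₂} f₂ dx − ∫₀^{x₁} f₁ dx,

i.e. the quasi-static work across the connecting segment minus the change
in stretch free energy of the whole chain, both from the fitted models
(closed-form integrals). The identity W_unfold = W_rip − ΔG_s holds exactly
by construction and is asserted on every transition.

For an SMD trace the unfolding work profile is

    W_unfold(x) = ∫₀ˣ F dx′ − ∫₀ˣ f_FJC dx′,

with the first integral accumulated by trapezoid in *time order* — the
extension fluctuates thermally, and signed increments let fluctuations
cancel where sorting by extension would bias the work upward — and the FJC
baseline fitted to the stretch tail (all samples beyond the last detected
force drop plus a 2-nm margin). Profiles are resampled onto a uniform
0.1-nm extension grid via the running-maximum envelope of the extension.

Free energies from a work sample {W_i} (kcal/mol):

* mean-work estimator: the sample mean (upward-biased by dissipation),
  with SD (n−1) and standard error;
* Jarzynski estimator: −kB T ln[(1/n) Σ exp(−W_i/kB T)], computed with a
  log-sum-exp shift by the sample minimum. It never exceeds the mean
  (Jensen), and for our wide distributions (SD ≫ kB T ≈ 0.6 kcal/mol) it is
  dominated by the lowest work values — reported alongside the mean-work
  estimate, not in place of it.

Ensemble profiles interpolate per-trace profiles onto the intersection of
their extension ranges and report pointwise mean and sample SD. The
experimental analogue of the SMD profile sums each accepted trace's
transition works in extension order (a step profile anchored at zero);
this construction is this package's own, chosen for comparability with the
continuous simulation profile.

## Synthetic data generator

**AFM traces.** The generator emulates the experimental campaign: cantilever
spring constant 15 pN/nm, retraction at 400 nm/s, sampling every 0.2 ms.
Per-domain unfolding forces and contour increments are drawn from the
measured distributions — I91: N(219, 33) pN and N(34, 3) nm; FimG:
N(422, 69) pN and N(48, 11) nm — with four I91 markers and one FimG domain
per trace. Unfolding is placed by force threshold: each branch follows its
WLC until the force reaches the weakest remaining domain's sampled
strength, then the contour length grows by that domain's increment. This
makes every branch model, peak force, increment and quasi-static transition
work exact ground truth (a kinetic Bell–Evans placement would trade that
exactness for loading-rate physics that the downstream statistics never
use). The recorded extension is the stage position minus F/k (cantilever
convolution), solved on a dense per-branch grid and interpolated onto the
uniform stage grid. Traces carry a pushed contact ramp (−200 pN over 5 nm)
before the origin, a detachment peak at 1.3 × the tallest unfolding peak,
a flat zero-force tail, and additive white Gaussian force noise.

Values the study conditions do not fix were chosen once, a priori:
persistence length 0.4 nm for all branches (mid-range of the accepted
0.01–1 nm window); folded-chain contour 60 nm for the first branch; raw
force noise σ = 8 pN (≈ 2.3 pN after 1-nm binning, the scale of a
low-noise AFM at this bandwidth); tail length 150 nm, set so the OLS
tail-slope standard error (≈ 0.0043 pN/nm) sits well inside the 0.01 pN/nm
criterion. Expected losses at these conditions are dominated by genuine
boundary draws: a FimG force below the 300-pN barrier (≈ 3.9%, the
misattribution mode — such traces are rejected for having no FimG peak,
never silently accepted), an I91 force above it (≈ 2.8%, the mirror mode),
tail-slope noise (≈ 2%) and I91 increments outside (25, 45) nm (≈ 1%);
acceptance therefore sits near 90% and fluctuates a few percent between
200-trace campaigns.

A defect catalogue produces traces violating exactly one criterion each
(short or sloped tail, 2 or 6 markers, sub-barrier FimG, weak detachment,
a non-WLC branch artifact, out-of-range persistence length or increment).
Defect probes are generated noise-free so no stochastic boundary draw can
preempt the probed criterion; the branch artifact is a sawtooth spike whose
instantaneous rise never registers as a transition (only drops do) and
whose 40 pN/nm decay stays below the derivative threshold, leaving the
fit-quality criterion as the only violation.

**SMD traces.** Pulls ride the extensible-FJC backbone of the unravelled
chain (b = 0.8 nm, L = 40 nm, K = 15 000 pN) with three Gaussian rip
excursions in extension whose areas are the injected works — 2000, 1730 and
3600 pN·nm at 5.5, 9 and 22 nm, reproducing the observed rip sequence (a
double peak from the two linker-strand rips, then the intra-sheet rip) and
profile shape: a sharp rise, a plateau near 540 kcal/mol (the
linker-free detachment free energy), a second rise, and a final value near
1060 kcal/mol. Per-trace work spread is a 9% multiplicative factor per rip;
force noise is Ornstein–Uhlenbeck (SD 30 pN, τ = 0.1 ns) and the extension
carries a small OU jitter so signed integration is actually exercised.
Because the force field is conservative in extension, the injected work of
each rip equals its bump area over the trace range exactly, jitter or not.
Sampling is every 0.01 ns at 1 nm/ns — the time resolution of
block-averaged pull-code output rather than the raw integration step.

**What the generator does not emulate.** Loading-rate-dependent (kinetic)
unfolding, so peak forces within a trace are ordered; instrument drift and
baseline curvature beyond the origin offset; correlated (1/f) force noise;
multiple tethers or missed adhesion events other than the explicit defect
kinds; solvent or atomistic detail on the SMD side. Passing tests therefore
demonstrate the correctness of segmentation, fitting, filtering and work
bookkeeping under the stated statistical structure — not robustness to
every pathology of real instrument data.

## Numerical choices and degenerate inputs

* WLC evaluations clamp nothing: extensions at or beyond `L` raise; fits
  keep `L` strictly above the data range instead.
* Transition refinement falls back to bin positions if the raw window is
  pathological (fewer than two samples, or reversed endpoints).
* A branch with fewer than 3 points is left unfit and fails the
  fit-quality criterion; a degenerate transition with x₂ = x₁ and identical
  branches yields zero work.
* Downsampled traces keep per-bin means of time, extension and force; bins
  are never interpolated across rip gaps (extension jumps leave empty
  bins).
* Trace TSVs store 17 significant digits, so write→read round-trips are
  bit-exact (`float_precision="round_trip"` on the reader).
* Problem sizes in the test suite and acceptance script — 200 AFM traces,
  10 SMD pulls — are the campaign sizes at which the statistical checks
  (2-SE recovery, ≥90% acceptance, 2% work recovery) were designed; the
  10-pull ensemble deliberately matches the size of a typical simulated
  dataset.

## Known limitations

* The Jarzynski estimator is reported but, at SD/kBT ratios of order 100,
  it is far from converged at these sample sizes; the mean-work estimator
  is the operative free-energy estimate, as its bias analysis (dissipation)
  must be argued physically rather than statistically.
* Peak forces recovered from accepted traces estimate the *post-selection*
  means: the 300-pN barrier truncates both force distributions, so the
  accepted-FimG mean sits slightly above the input mean. This mirrors the
  experimental analysis, which can only ever report barrier-conditioned
  statistics.
* Binned branch fits carry a small convexity bias in (P, L) (≈1% on the
  first branch); increments, being differences of consecutive `L`, cancel
  almost all of it.
* The experimental ensemble profile construction (cumulative transition
  works) is defined on transition landing points and interpolated between
  them; it is a step-function summary, not a continuous work integral.
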