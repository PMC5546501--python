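# Methods

## Point patterns and coordinate conventions

Input patterns are continuous (x, y) coordinates in nanometres inside a
rectangular observation window, by default 1000 x 1000 nm (a 1 um^2
membrane sheet). The origin is the window's lower-left corner with y
increasing upward; digitisation tools do not agree on an origin convention,
so ours is fixed and documented rather than inferred. Points outside the
window are rejected by default because the estimator's study-area premise
requires them inside; a clip mode tolerates digitisation slop of up to 1 nm
(configurable) by snapping to the boundary. Duplicate coordinates are legal
for the estimator but physically impossible for 4.5 nm gold particles, so
validation can flag (never remove) pairs closer than a minimum separation.

## K-function estimator

The estimator follows the ordered-pair definition with an n^-2 prefactor:
K(r) = A n^-2 sum_{i != j} w_ij 1(d_ij <= r). Choices that matter:

- **Edge correction.** `isotropic` (default) uses Ripley's correction for a
  rectangle: w_ij is the reciprocal of the fraction of the circle centred
  at x_i with radius d_ij lying inside the window. The fraction is closed
  form — each side closer than r removes an arc of half-angle acos(d/r),
  and arcs of adjacent sides overlap by acos(d1/r) + acos(d2/r) - pi/2 when
  the shared corner is inside the circle. Opposite-side arcs can never
  overlap (each half-angle is at most pi/2) and no triple overlaps exist,
  so this inclusion-exclusion is exact at every radius, degrading to
  fraction 0 (an error) when the circle lies wholly outside. `toroidal`
  wraps distances; `none` disables correction. The closed form is verified
  in the test suite against an independent numeric procedure that locates
  the boundary-crossing angles by bisection.
- **Weight cap.** Individual weights are capped at 10 (configurable) to
  bound variance inflation for extreme corner points at large radii; within
  the default geometry (r <= 240 nm in a 1000 nm window) the largest
  attainable weight is 4, so the cap never binds there.
- **Denominator.** The printed n^-2 form is the default, which makes
  E[K(r)] = ((n-1)/n) pi r^2 under CSR conditioned on n — a deliberate
  -0.5%/n bias kept for fidelity; an `unbiased_n` flag switches to n(n-1).
- **Radius grid.** Default 1, 2, ..., 240 nm inclusive (the printed range
  "1 < r < 240" has ambiguous endpoints; we take the inclusive integer
  grid) with configurable endpoints and step.
- **L transform.** L(r) - r = sqrt(K(r)/pi) - r, elementwise, rejecting
  negative K. Note the transform is concave: at radii where pairs are rare
  the per-pattern L is biased below zero even though K is (essentially)
  unbiased; group summaries should therefore be read on K or on averaged
  curves, not on per-pattern L at r of a few nm.

Implementation: pairwise distances via `scipy.spatial.distance.cdist`,
pairs beyond the largest radius dropped, cumulative weight sums evaluated
once per grid by binary search. One n = 200 pattern over the full 240-point
grid takes ~1 ms, which is what makes the Monte-Carlo layers cheap.

## CSR envelopes

Envelopes condition on the observed point count: each simulation draws
exactly n uniform points (binomial process), the usual practice when
testing a single observed pattern. Bounds at confidence level `level` are
the k-th smallest/largest simulated L(r)-r per radius with
k = floor((B+1)(1-level)/2), so a fresh CSR curve falls inside with
probability exactly (B+1-2k)/(B+1) pointwise; B must be at least
ceil(2/(1-level)) - 1 (39 at 95%, 199 at 99%) or the requested quantiles
are unresolvable and the call errors with that minimum. The envelope is
pointwise, not simultaneous; a max-standardised-deviation global variant is
available behind a flag for sensitivity analysis. Classification against an
envelope is strict: a curve is `clustered` only if it strictly exceeds the
upper bound somewhere in the report band (default 5-100 nm, where
nanocluster signal lives), `dispersed` if strictly below, else `random`;
ties at the boundary count as inside.

## Group averaging and the bootstrap test

Per-condition curves are averaged pointwise, weighted by each image's gold
count by default (patterns with more particles carry less noise); equal
weighting is available. The two-condition test uses the statistic

    T = integral over the r-band of (mean_a L(r)-r - mean_b L(r)-r)^2 dr

(trapezoid rule on the grid, default band 5-100 nm). The null distribution
pools all per-image curves and resamples two groups of the original sizes
with replacement; p = (1 + #{T* >= T_obs}) / (1 + B), so p is never below
1/(1+B). The resampling unit is the per-image curve — images, not
individual gold particles, are the independent replicates of this design.
The statistic is symmetric in the group labels, so swapping groups leaves
T unchanged exactly. Measured operating characteristics (fixed in the test
suite): CSR-vs-CSR rejection at the 0.05 threshold is ~0.05-0.065 over 200
replicate experiments with 15 images per group, and power against a
moderately clustered alternative (20 clusters of mean 15 at sigma = 15 nm)
is ~100%.

## FLIM-FRET

Single-frequency homodyne model at modulation frequency f (default 40 MHz,
omega = 2 pi f): a mono-exponential lifetime tau produces phase
atan(omega tau) and modulation 1/sqrt(1 + (omega tau)^2). Calibration
against a reference standard of known lifetime tau_ref removes the
instrument phase offset and modulation scale exactly, by construction:
phase_offset = phi_meas - atan(omega tau_ref) and modulation_scale =
m_meas sqrt(1 + (omega tau_ref)^2). The reference lifetime is a required
input — fluorescein's literature value of 4.0 ns is the documented default
in configuration, never silently hard-coded. After calibration, pixels with
modulation outside (0, 1] or phase outside [0, pi/2) are physically
impossible for a decay and are excluded and counted, never clamped. Both
tau_phase and tau_mod are always computed; they agree for mono-exponential
pixels and split (tau_phase < tau_mod) for mixtures, so the per-cell
estimator choice (default: phase) only matters for heterogeneous fields and
is surfaced as an explicit option. Apparent FRET efficiency is computed per
cell against the mean donor-only lifetime: E_app = (1 - tau_DA/tau_D) x
100%, reported with its mean and standard error over cells (designs
typically use >30 cells per condition).

Raw multi-phase image demodulation is out of scope: the package boundary is
(phase, modulation) maps, which the synthetic generator produces directly
from decay parameters.

## Phenotype threshold rules

Neurite scoring is strict (`length > 1.5 x soma diameter`); sphere counting
is inclusive (`size >= 50 um`); treated sphere counts are expressed as a
percentage of the vehicle control (and may exceed 100%); densitometry
reports band/loading and phospho/total ratios. Differentiation percentages
are computed over GFP-positive (transfected) cells only, warning below the
assay's 100-cell minimum. All rules are pure and order-independent;
downstream significance testing (t-test, ANOVA) is deliberately delegated
to standard statistics libraries on the tidy tables these functions emit.
Whether sphere "size" is a diameter or a longest axis is not specified by
the assay definition; it is treated as a single diameter-like scalar.

## Synthetic data

The generators emulate the statistical structure of the real inputs, not
their imaging physics:

- **CSR**: exactly n uniform points (the envelope's null).
- **Thomas process** (default clustered alternative): Poisson(kappa A)
  parents uniform in the window, Poisson(mu) offspring per parent with
  isotropic Gaussian(sigma) scatter, offspring outside the window
  discarded. Thomas is preferred over Matern because its Gaussian scatter
  gives closed-form expectations for tests (e.g. extra K of
  (1/kappa)(1 - exp(-r^2/4 sigma^2))); a Matern variant (uniform-disc
  scatter) exists behind a flag. Typical nanocluster-like settings used
  throughout the tests: 20 expected clusters per window, mu = 15,
  sigma = 10-15 nm, giving n ~ 300 per sheet.
- **Labelling model**: binomial detection at a given efficiency, Gaussian
  linker jitter (clipped to the window), then hard-core thinning at the
  4.5 nm gold diameter — violating pairs are resolved nearest-pair-first,
  removing one member chosen by the seeded generator, so runs are exactly
  reproducible.
- **FLIM frames**: the forward homodyne model plus optional Gaussian phase
  and modulation noise (modulation clipped to [0, 1]); zero-noise frames
  invert exactly.
- **FRET experiments**: per-cell donor and donor+acceptor lifetimes as
  truncated-positive normals around tau_D and tau_D (1 - E/100).

Per-sheet gold counts are not published for the real study; the default
n ~ 200-400 used across tests and examples is a synthetic choice made to
exercise the estimator at realistic densities, and is labelled as such.
What passing tests show is that the pipeline recovers known structure from
data generated under its own assumptions; real immunogold data additionally
carry segmentation errors, non-uniform labelling and membrane topography
that these generators deliberately do not model.

## Problem sizes and numerical choices

The statistical checks in the test suite run at sizes chosen as the
smallest that leave the target properties comfortably resolvable: 500
patterns for null-centring checks, 999 envelope simulations + 2000 fresh
patterns for coverage (binomial 99% CI half-width ~0.6 percentage points),
60 seeds for detection rates, 200 replicate experiments for test size, 30
for power, 199 bootstrap/envelope resamples inside replicated loops (the
minimum resolving a 99% envelope) and 1000 where a single test is run.
Floating-point ties at envelope bounds and indicator thresholds
(d_ij <= r) are resolved by inclusive comparison on the K side and strict
comparison at envelope bounds, both stated in the docstrings. Degenerate
inputs (n < 2 patterns, empty masks, zero denominators) raise immediately
with messages naming the violated precondition.

## Known limitations

- The homogeneous univariate K-function only: no bivariate/cross-K, no
  inhomogeneous intensity surface, no anisotropy.
- Pointwise envelopes understate simultaneous coverage across radii; use
  the global variant when making claims over the whole r range.
- The bootstrap test's pooled resampling assumes per-image curves are
  exchangeable under the null; systematic per-sheet intensity differences
  between conditions would violate this.
- Frequency-domain FLIM at a single frequency cannot resolve
  multi-component decays; tau_phase/tau_mod disagreement is surfaced as a
  heterogeneity diagnostic, not resolved.
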