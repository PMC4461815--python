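# Methods

## Model

A texture set is a shift-invariant pairwise Markov random field on a cyclic
`H × W` lattice of discrete amplitude indices (3 states by default).  The
set is specified by interaction offsets `(dy, dx)` — each unordered pair
counted exactly once, so an offset and its negation may not both appear —
and one `n_states × n_states` potential matrix per offset.  Coordinates are
(row, col), 0-based, row increasing downward, with modular wrapping.  The
energy `U(I)` sums the pair potential over every site and offset, and
configurations are distributed as `P(I) ∝ exp(−β U(I))`.

Assumptions inherited from this design: interactions are strictly pairwise
(no higher-order cliques), the potential is the same everywhere on the
lattice, and the state alphabet is small and discrete.  Potentials are
configuration, not code: texture sets round-trip through YAML/JSON files.
Three canonical sets ship with the package — a ferromagnetic 3-state Potts
set (uniform ground state), an antiferromagnetic checkerboard set coupling
the lowest and highest amplitudes (period-2 ground state), and an
anisotropic stripe set (vertical stripes alternating two amplitudes).  All
use coupling magnitude 1, which places the interesting β range roughly in
[0.02, 1] on 32 × 32 lattices; the shared default β grid
(0, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0) spans chance through ceiling for
every builtin observer.

## Sampling

Equilibrium draws use chromatic (parallel) Gibbs sampling.  Sites are
partitioned so that no two sites in a group interact; groups are updated in
a fixed order, and within a group every site is resampled simultaneously
from its full conditional — a valid systematic-scan Gibbs sampler because
conditionals within a group are mutually independent given the rest.  For
near-neighbour offsets on even lattices the partition is the four parity
sub-grids (even, even), (even, odd), (odd, even), (odd, odd); whenever an
offset connects equal parities (long offsets, or odd lattice dimensions
where the cyclic wrap breaks parity) a greedy colouring of the interaction
graph is used instead (networkx `greedy_color`).

Chains initialise i.i.d. uniform (the β = 0 limit).  Defaults for 32 × 32
lattices: burn-in 2000 sweeps, thinning 5.  These are conservative for the
disordered side of the transition and adequate through β = 1 on the builtin
sets; like any single-site sampler the chain coarsens slowly deep in the
ordered phase, so samples at large β on large lattices should be read as
"equilibrated from disorder for a fixed budget" rather than perfectly
equilibrium draws.  This affects none of the package's comparisons, which
always evaluate all observers on the same samples.

`sample_texture` runs one seeded chain; `sample_texture_ensemble` runs many
chains as one vectorised batch (default 100) and collects thinned states
round-robin — statistically equivalent, far cheaper per sample, and the
workhorse for observer training and simulated trials.  All randomness flows
from explicit `numpy` generators; per-condition seeds are derived from a
master seed and the condition identifiers (CRC mixing, kept below 2³¹), so
any single β of a curve is reproducible in isolation.

### Exact enumeration oracle

For lattices with at most 10⁶ configurations, `enumerate_boltzmann` computes
the full Boltzmann table (explicit Z).  The sampler is validated by χ²
goodness-of-fit of binned Gibbs samples against this table; cells are pooled
smallest-expectation-first until the pooled cell reaches expectation 5, the
standard remedy for sparse multinomial tables.  On the 3 × 3 Potts lattice
(19 683 configurations) with 5 × 10⁵ thinned samples the fit passes at
α = 0.001 across β ∈ {0, 0.25, 0.5}; the mean energy of Gibbs samples also
matches the exact Boltzmann mean within Monte Carlo error.

## Order parameter

The ground-state orbit of a set is generated from its canonical periodic
tile by cyclic translations and by the state relabelings that leave every
potential matrix invariant; all members share the minimal energy, and an
exhaustive search over small-period tilings (period ≤ 2 by default) checks
minimality for the builtin sets.

A site's interacting pair (the site with one offset partner, forward or
backward) *conforms* when its joint state equals the corresponding joint
state in **some** orbit member.  The order field assigns each site the
conforming fraction of its incident pairs; the order parameter is the field
mean.  Measuring conformance against the whole orbit, rather than one
best-matching phase, makes the statistic a function of the symmetry class —
the analogue of a magnetisation magnitude, indifferent to which ordered
phase the system chose.  Two consequences fix its calibration exactly:
the value is 1 precisely on orbit members (verified exhaustively on 2 × 2
lattices for every builtin set), and the expectation under i.i.d. uniform
states has the closed form

    baseline = mean over pair slots of (#conforming joints) / n_states²,

which is 1/3 for the Potts set and 2/9 for the checkerboard and stripe
sets.  The baseline is reported alongside the value but never subtracted;
the Order observer learns the statistic's distribution anyway.

One property of the builtin sets is worth flagging: their conforming joints
coincide exactly with the potential entries that carry the −1 coupling, so
the order parameter is an affine function of the energy and the Order
observer carries the same information as the Ideal observer.  Sets whose
potentials mix "structural" terms with terms irrelevant to the ground-state
symmetry would separate the two; the framework supports them through the
config mechanism.

## Observers and density estimation

Each observer reduces a quadrant's lattice to a statistic: per-amplitude
counts (Luminance, 3-d), per-offset joint-amplitude counts (Ideal, 9 per
interacting pair — the sufficient statistics: `U(I)` is their inner product
with the potentials, an identity asserted in the tests), the scalar order
parameter (Order), and summed quadrature-pair Gabor energy of the rendered
quadrant (Channel energy).

Decisions follow signal detection theory.  Densities of each statistic under
the target (per β) and under the distractor are estimated from training
samples — 1000 per class by default — and the chosen quadrant maximises
`f_t(s_q) · Π_{q′≠q} f_d(s_{q′})`, computed as the argmax of the
per-quadrant log-likelihood ratio.  Ties (exact score equality within 1e−9
relative) are broken uniformly at random.

Density families, by statistic:

* **Scalar statistics** (Order, Channel energy): a two-moment Gaussian fit —
  the statistic's mean and variability at each temperature.
* **Luminance counts** (3-d): product-Gaussian-kernel KDE with per-dimension
  Scott bandwidths (`σ_d · n^(−1/(d+4))`); zero-variance dimensions get a
  floored bandwidth with a warning.
* **Pair counts** (9 × P-d): Gaussian kernels sharing one covariance — the
  pooled within-class covariance of the two training sets — restricted to
  its non-degenerate principal subspace, with a deliberately oversmoothed
  bandwidth of 4.0 in whitened units (`fit_density_pair`).  Count statistics
  satisfy exact linear constraints (each offset's table sums to H·W, its
  margins equal the amplitude counts), so the raw 18-d distribution is
  supported on a ~10-d subspace; the discarded directions are common to
  both classes and cancel from every likelihood ratio.  The oversmoothing is
  the important choice: bandwidths tuned for pointwise density error make
  likelihood-ratio *rankings* nearest-neighbour-dominated and noisy once
  the statistic has more than a handful of effective dimensions, while in
  the wide-kernel limit the ratio approaches the pooled-metric linear
  discriminant, which is near-optimal for an exponential-family mean shift.
  With this estimator the trained Ideal observer tracks the exact rule
  within ≈ 2 points everywhere on the builtin Potts grid.

The exact maximum-likelihood rule is also provided (`ideal_analytic`):
because `log P_β(I) − log P_0(I) = −β U(I) + const`, the target is the
minimum-energy quadrant for β > 0.  At β = 0 the rule is undefined — target
and distractor distributions coincide — and callers fall back to chance.
Density models serialise to JSON (kind, moments or kernel data, training
metadata).

### Channel energy details

The filters are an even/odd Gabor quadrature pair,
`exp(−(x²+y²)/2σ²)·{cos,sin}(2πf(x cosθ + y sinθ))`, sampled at the render
pixel scale and truncated at ±3σ; the odd kernel is antisymmetric on the
symmetric grid, so its DC response vanishes by construction.  The energy
map is `M = (I∗G_even)² + (I∗G_odd)²` with zero padding at borders, and the
decision variable is the sum of `M` over the quadrant, computed on each
quadrant's own rendered texture (no cross-border contamination; a composed
64 × 64-blob display can still be assembled and measured through
`quadrant_energy`).  The shipped per-set parameter table stores spatial
frequency in cycles/degree (the carrier phase is `2πf(…)`), and each
builtin set carries a default filter tuned to the fundamental of its
ordered pattern.  For observer simulations the quadrant render uses
80 px/degree — the 1.5-arcmin blob is still 2 px — and the FFT pipeline
precomputes blob-convolved kernel transforms and runs in single precision
(relative error ~1e−7 on a statistic summed over ~10⁵ pixels).

## Rendering

Blobs are circularly symmetric Gaussians (σ = 1.5 arcmin) at grid spacing
4.84°/32 ≈ 0.151°, added to a uniform background (14 cd/m²), with peak
luminances (26, 56, 91) cd/m² for the three amplitude states and a default
scale of 120 px/degree (σ = 3 px).  Blob tails are truncated at ±3σ;
neighbouring blobs overlap negligibly at this geometry (spacing ≈ 6σ).
Displays are composed either `attached` (2 × 2 tiling, a 64 × 64 blob grid
for 32 × 32 quadrants, fixation at the centre) or `gapped` (quadrant
centres at 4° eccentricity on uniform background).  Images are kept as
float luminance; 8-bit PNG export uses explicit max scaling.  No gamma or
monitor model.

## Psychophysics

A trial places one equilibrium target at β in a uniformly random quadrant
and three distractors in the others — i.i.d. uniform lattices
(`uniform_distractor`) or random spatial permutations of that trial's
target (`permuted_distractor`, which preserves the amplitude histogram
exactly and therefore blinds the Luminance observer: all four statistics
tie and the decision is pure guessing).  Curves default to 1000 trials per
β after 1000 training samples; the channel-energy observer, whose scalar
statistic needs no high-dimensional density, uses a 100-trial budget.

Thresholds are the smallest β at which the curve crosses a criterion level,
0.625 by default (halfway between chance 0.25 and 1).  Interpolation is
linear in log β — the grid spans orders of magnitude — so a level halfway
between two adjacent proportions maps to the geometric mean of their βs; a
grid point exactly at the level is returned as-is, and the single segment
starting at β = 0 is interpolated linearly in β.  A curve that never
reaches the level yields an explicit "undefined" (None), not an error.

Curves are compared level-by-level: each β contributes the pooled
two-proportion χ² of its 2 × 2 outcome table, contributions are summed, and
the degrees of freedom default to the number of β levels but are exposed as
a parameter (conventions with one fewer dof exist in the literature and the
choice is not forced by the construction).

## What the generator emulates — and what it does not

The synthetic pipeline reproduces the *stimulus* side of an order-detection
experiment faithfully: exact Boltzmann statistics (validated by
enumeration), the display geometry, and the two distractor modes.  It does
not model human observers — no internal noise, no spatial-frequency
filtering before the decision statistic, no attention, no learning across
trials — so simulated observer performance bounds, rather than predicts,
human performance.  Passing tests therefore show the machinery is correct
(samplers match exact distributions, observers match their defining rules,
thresholds are recovered from known curves), not that any particular human
dataset would be reproduced.

## Numerical choices and problem sizes

* Conditional distributions and KDE scores are computed in log space with
  max-subtraction / `logsumexp`; categorical sampling uses inverse-CDF on
  vectorised cumulative sums.
* The acceptance-style checks run at deliberately moderate scale, chosen as
  a sensible desk-scale budget: 5 × 10⁵ oracle samples per β on 3 × 3;
  2000 lattices per β (1000 training + 1000 trials) on the full 32 × 32
  Potts set; 900 per β (500 + 400) for the other builtin sets; channel
  training uses 300 samples for its two-moment fit.
* Statistical margins use 3 standard errors (binomial or pooled) for
  point comparisons and monotonicity, matching the calibration of one-off
  scientific checks.

## Limitations

* Single-site Gibbs mixes slowly below the transition; cluster samplers are
  out of scope, so very-large-β samples on large lattices are budgeted, not
  perfectly equilibrated.
* The ground-state orbit machinery assumes a known (or small-period
  searchable) periodic tile; incommensurate or aperiodic ground states are
  unsupported.
* The order parameter's pair-template form is one principled instantiation
  of "mean conformance of local configuration to global symmetry"; sets
  defined with other local order measures would need their own statistic.
* The channel-energy observer uses a single filter; no multi-channel bank
  or cross-channel integration.
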