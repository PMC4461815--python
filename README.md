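# ordertex

Tools for studying the **visual perception of order** with the formalism of
statistical physics: synthesize discrete-amplitude blob textures from a
Boltzmann distribution at controlled temperature, quantify their order with a
symmetry-specific order parameter, and simulate theoretical observers in a
spatial four-alternative forced-choice (4AFC) task.

The package is aimed at visual psychophysicists and computational
neuroscientists who want stimuli whose *amount of structure* is controlled by
a single physical parameter, together with the ideal-observer machinery
needed to interpret discrimination performance against those stimuli.

## The model

A texture is an `H × W` lattice `I` of amplitude indices `A_{p,q} ∈ {0, 1, 2}`,
each driving the peak luminance of one Gaussian blob in the rendered image.
A *texture set* defines pairwise interaction rules: a list of displacement
offsets `o` and, per offset, a 3 × 3 shift-invariant potential matrix `U_o`.
The total energy and the sampling distribution are

    U(I) = Σ_{(p,q)} Σ_o U_o(A_{p,q}, A_{(p,q)+o}),      P(I) = e^{−β U(I)} / Z,

with cyclic boundary conditions.  The inverse temperature β is the single
knob: β = 0 gives i.i.d. uniform noise, large β concentrates on the
minimum-energy (periodic, symmetric) configurations, and the order–disorder
transition lies in between.  Sampling uses chromatic parallel Gibbs updates
(parity sub-grids updated simultaneously, or a greedy graph colouring when
parity is invalid), validated against exact enumeration of all `3^(H·W)`
configurations on tiny lattices.

The **order parameter** is the mean conformance of local interacting pairs to
the ground-state symmetry: a pair conforms when its joint state matches the
corresponding joint state in some member of the ground-state orbit
(translations and energy-preserving relabelings of the canonical tile).  It
is exactly 1 on ground states and has a closed-form baseline under uniform
noise (1/3 for the ferromagnetic Potts set).

Four theoretical observers decide which display quadrant holds the structured
target among three distractors, by maximum likelihood over densities
estimated from training samples:

| observer        | statistic                                   |
|-----------------|---------------------------------------------|
| Luminance       | 3-vector of per-amplitude blob counts       |
| Ideal           | 9 joint-amplitude counts per interacting pair (sufficient statistics) |
| Order           | scalar order parameter                      |
| Channel energy  | summed quadrature-pair (even/odd Gabor) energy of the rendered quadrant |

Because `log P_β(I) = −β U(I) − log Z`, the exact maximum-likelihood rule is
"choose the minimum-energy quadrant"; this analytic rule ships alongside the
trained Ideal observer as its reference.

## Worked example

```python
import ordertex as ot

spec = ot.get_builtin("potts")                      # 3-state ferromagnetic set
samples = ot.sample_texture_ensemble(spec, beta=0.4, n_samples=200, seed=0)

stat = ot.order_parameter(samples[0], spec)
print(f"order parameter at beta=0.4: {stat.value:.3f} (noise baseline {stat.baseline:.3f})")

curve = ot.performance_curve(
    spec.with_shape((16, 16)), "ideal_analytic",
    beta_grid=[0.0, 0.1, 0.2, 0.4, 0.8], n_trials=400, seed=0,
    burn_in=500, thin=2, n_chains=100,
)
for b, p in zip(curve.beta_grid, curve.p_correct):
    print(f"  beta={b:<4g} proportion correct = {p:.3f}")
print(f"62.5%-correct threshold: beta* = {ot.estimate_threshold(curve):.3f}")
```

prints

```
order parameter at beta=0.4: 0.429 (noise baseline 0.333)
  beta=0    proportion correct = 0.255
  beta=0.1  proportion correct = 0.625
  beta=0.2  proportion correct = 0.873
  beta=0.4  proportion correct = 0.998
  beta=0.8  proportion correct = 1.000
62.5%-correct threshold: beta* = 0.100
```

The sample at β = 0.4 is measurably more ordered than noise (0.429 vs the
1/3 baseline); the exact-rule observer's psychometric curve rises from
chance (25%) to perfect discrimination, and the β at which it crosses 62.5%
correct — halfway between chance and perfect — is its detection threshold.

A command-line interface wraps the same operations; see `ordertex --help`
(subcommands `synth`, `render`, `observe-train`, `curve`, `threshold`,
`compare`, `oracle-check`, `demo`).

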