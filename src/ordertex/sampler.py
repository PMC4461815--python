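"""Equilibrium sampling from P(I) ∝ exp(-beta U(I)).

Configurations are drawn by chromatic (parallel) Gibbs sampling: lattice
sites are partitioned into colour groups such that no two interacting sites
share a group, and within one sweep each group is resampled simultaneously
from the single-site conditional distribution given the current state of the
other groups.  On even lattices with the usual near-neighbour offsets the
partition is the four parity sub-grids (even, even), (even, odd), (odd,
even), (odd, odd); whenever that scheme would place two interacting sites in
one group (long offsets, or odd lattice dimensions where the cyclic wrap
breaks parity), a valid colouring of the offset-interaction graph is
computed instead by greedy graph colouring.

Exact enumeration of the Boltzmann distribution on tiny lattices is provided
as an independent oracle for the sampler, and distractor generators cover
the two distractor modes used in the 4AFC task (i.i.d. uniform amplitudes,
and random spatial permutation of the target's amplitudes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .texture_model import (
    Lattice,
    TextureSetSpec,
    energy_batch,
    validate_lattice,
    validate_spec,
)

__all__ = [
    "SamplingRequest",
    "conditional_distribution",
    "color_classes",
    "gibbs_sweep",
    "sample_texture",
    "sample_texture_ensemble",
    "enumerate_boltzmann",
    "encode_configs",
    "make_distractor",
    "chi2_gof",
]

# Defaults for 32x32 lattices; conservative, validated by the energy-trace
# convergence checks in the test suite.  The mixing time grows deep in the
# ordered phase, as for any single-site sampler.
DEFAULT_BURN_IN = 2000
DEFAULT_THIN = 5


@dataclass(frozen=True)
class SamplingRequest:
    """Parameters of one reproducible sampling run."""

    spec: TextureSetSpec
    beta: float
    n_sweeps: int
    burn_in: int = DEFAULT_BURN_IN
    thin: int = DEFAULT_THIN
    seed: int = 0

    def __post_init__(self) -> None:
        validate_spec(self.spec)
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n_sweeps < 0 or self.burn_in < 0:
            raise ValueError("n_sweeps and burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")


# ---------------------------------------------------------------------------
# Conditional distribution and colour classes
# ---------------------------------------------------------------------------

def conditional_distribution(
    site: tuple[int, int],
    config: Lattice,
    spec: TextureSetSpec,
    beta: float,
) -> np.ndarray:
    """Single-site Gibbs conditional P(state | rest of lattice).

    P(s) ∝ exp(-beta * sum of pair potentials between the site in state s
    and each of its interacting partners), normalised over the state
    alphabet.  At beta=0 this is uniform.
    """
    config = validate_lattice(config, spec)
    H, W = spec.lattice_shape
    p, q = site
    if not (0 <= p < H and 0 <= q < W):
        raise ValueError(f"site {site} out of range for lattice {(H, W)}")
    S = spec.n_states
    e = np.zeros(S)
    for (dy, dx), U in zip(spec.offsets, spec.potentials):
        e += U[:, config[(p + dy) % H, (q + dx) % W]]
        e += U[config[(p - dy) % H, (q - dx) % W], :]
    logp = -beta * e
    logp -= logp.max()
    w = np.exp(logp)
    return w / w.sum()


def _parity_groups(shape: tuple[int, int]) -> list[np.ndarray]:
    H, W = shape
    rows = np.arange(H)[:, None] % 2
    cols = np.arange(W)[None, :] % 2
    gid = 2 * rows + cols
    return [gid == g for g in range(4)]


def color_classes(spec: TextureSetSpec) -> list[np.ndarray]:
    """Partition of lattice sites into simultaneously updatable groups.

    Returns boolean masks over the lattice, one per group, such that no two
    sites connected by an interaction offset (or its negation, with cyclic
    wrapping) fall in the same group.  The four parity sub-grids are used
    whenever they are valid; otherwise a greedy colouring of the
    offset-interaction graph is computed.
    """
    H, W = spec.lattice_shape
    gid = 2 * (np.arange(H)[:, None] % 2) + (np.arange(W)[None, :] % 2)
    parity_ok = True
    for dy, dx in spec.offsets:
        if np.any(gid == np.roll(gid, shift=(-dy, -dx), axis=(0, 1))):
            parity_ok = False
            break
    if parity_ok:
        return _parity_groups((H, W))

    # Fall back to greedy colouring of the interaction graph on the torus.
    G = nx.Graph()
    G.add_nodes_from(range(H * W))
    for dy, dx in spec.offsets:
        for p in range(H):
            for q in range(W):
                a = p * W + q
                b = ((p + dy) % H) * W + (q + dx) % W
                if a != b:
                    G.add_edge(a, b)
                else:
                    raise ValueError(
                        f"offset {(dy, dx)} wraps onto the same site on lattice {(H, W)}"
                    )
    coloring = nx.greedy_color(G, strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    labels = np.array([coloring[i] for i in range(H * W)]).reshape(H, W)
    return [labels == c for c in range(n_colors)]


def _check_coloring(groups: list[np.ndarray], spec: TextureSetSpec) -> bool:
    """True iff no interaction offset connects two sites of one group."""
    labels = np.zeros(spec.lattice_shape, dtype=int)
    for g, mask in enumerate(groups):
        labels[mask] = g
    for dy, dx in spec.offsets:
        if np.any(labels == np.roll(labels, shift=(-dy, -dx), axis=(0, 1))):
            return False
    return True


# ---------------------------------------------------------------------------
# Sweeps and sampling
# ---------------------------------------------------------------------------

class _SweepPlan:
    """Precomputed gather indices for chromatic sweeps.

    For each colour group: the flat indices of its sites and, per offset,
    the flat indices of the forward and backward partners (cyclic).  Lets a
    sweep touch only the sites being resampled.
    """

    def __init__(self, spec: TextureSetSpec, groups: list[np.ndarray] | None = None):
        if groups is None:
            groups = color_classes(spec)
        H, W = spec.lattice_shape
        self.spec = spec
        self.S = spec.n_states
        self.U = [np.ascontiguousarray(U) for U in spec.potentials]
        self.UT = [np.ascontiguousarray(U.T) for U in spec.potentials]
        rows, cols = np.indices((H, W))
        self.groups: list[tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]] = []
        for mask in groups:
            r, c = rows[mask], cols[mask]
            idx = r * W + c
            fwd = [((r + dy) % H) * W + (c + dx) % W for dy, dx in spec.offsets]
            bwd = [((r - dy) % H) * W + (c - dx) % W for dy, dx in spec.offsets]
            self.groups.append((idx, fwd, bwd))


def _sweep_flat(
    flat: np.ndarray,
    plan: _SweepPlan,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One chromatic sweep over flattened chains ``(n, H*W)``, in place.

    Groups are updated in fixed order; within a group every site is
    resampled simultaneously from its conditional given the pre-update
    state of the other groups (valid because groups are non-interacting).
    """
    n = flat.shape[0]
    for idx, fwd, bwd in plan.groups:
        e = np.zeros((plan.S, n, len(idx)))
        for i in range(len(plan.U)):
            e += plan.U[i][:, flat[:, fwd[i]]]
            e += plan.UT[i][:, flat[:, bwd[i]]]
        logp = -beta * e
        logp -= logp.max(axis=0, keepdims=True)
        w = np.exp(logp)
        w /= w.sum(axis=0, keepdims=True)
        cum = np.cumsum(w[:-1], axis=0)
        u = rng.random((n, len(idx)))
        flat[:, idx] = (u[None, ...] > cum).sum(axis=0)
    return flat


def gibbs_sweep(
    config: Lattice,
    spec: TextureSetSpec,
    beta: float,
    rng: np.random.Generator,
    groups: list[np.ndarray] | None = None,
) -> Lattice:
    """One full chromatic Gibbs sweep; returns a new configuration."""
    config = validate_lattice(config, spec)
    plan = _SweepPlan(spec, groups)
    flat = config.reshape(1, -1).copy()
    _sweep_flat(flat, plan, float(beta), rng)
    return flat.reshape(config.shape)


def sample_texture(req: SamplingRequest) -> list[Lattice]:
    """Draw equilibrium configurations from a single seeded chain.

    The chain starts from an i.i.d. uniform configuration (the beta=0
    limit), runs ``burn_in`` sweeps, then keeps every ``thin``-th of the
    following ``n_sweeps`` sweeps.  Bitwise reproducible given the seed.
    """
    rng = np.random.default_rng(req.seed)
    spec = req.spec
    plan = _SweepPlan(spec)
    H, W = spec.lattice_shape
    flat = rng.integers(0, spec.n_states, size=(1, H * W), dtype=np.int64)
    for _ in range(req.burn_in):
        _sweep_flat(flat, plan, req.beta, rng)
    out = []
    for i in range(req.n_sweeps):
        _sweep_flat(flat, plan, req.beta, rng)
        if (i + 1) % req.thin == 0:
            out.append(flat[0].reshape(H, W).copy())
    return out


def sample_texture_ensemble(
    spec: TextureSetSpec,
    beta: float,
    n_samples: int,
    seed: int,
    n_chains: int = 100,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
) -> np.ndarray:
    """Draw ``n_samples`` configurations from many independent chains.

    Runs ``n_chains`` chains in one vectorised batch (each initialised
    i.i.d. uniform), burns in, then collects thinned states round-robin
    across chains until ``n_samples`` are gathered.  Statistically
    equivalent to repeated single-chain sampling but far cheaper per
    sample, since burn-in is shared across the batch dimension.

    Returns an array of shape ``(n_samples, H, W)``.
    """
    validate_spec(spec)
    if n_samples <= 0:
        return np.empty((0,) + tuple(spec.lattice_shape), dtype=np.int64)
    n_chains = max(1, min(n_chains, n_samples))
    rng = np.random.default_rng(seed)
    plan = _SweepPlan(spec)
    H, W = spec.lattice_shape
    flat = rng.integers(0, spec.n_states, size=(n_chains, H * W), dtype=np.int64)
    for _ in range(burn_in):
        _sweep_flat(flat, plan, float(beta), rng)
    chunks = []
    collected = 0
    while collected < n_samples:
        for _ in range(thin):
            _sweep_flat(flat, plan, float(beta), rng)
        take = min(n_chains, n_samples - collected)
        chunks.append(flat[:take].reshape(take, H, W).copy())
        collected += take
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

MAX_ENUMERATION = 10**6


def _all_configs(spec: TextureSetSpec) -> np.ndarray:
    """All configurations as an array of shape (S**(H*W), H, W)."""
    H, W = spec.lattice_shape
    S = spec.n_states
    n_sites = H * W
    n_conf = S**n_sites
    codes = np.arange(n_conf)
    digits = np.empty((n_conf, n_sites), dtype=np.int64)
    for k in range(n_sites - 1, -1, -1):
        digits[:, k] = codes % S
        codes = codes // S
    return digits.reshape(n_conf, H, W)


def encode_configs(states: np.ndarray, n_states: int) -> np.ndarray:
    """Mixed-radix code of each configuration in a batch (inverse of
    enumeration order): site (0,0) is the most significant digit."""
    n = states.shape[0]
    flat = states.reshape(n, -1)
    codes = np.zeros(n, dtype=np.int64)
    for k in range(flat.shape[1]):
        codes = codes * n_states + flat[:, k]
    return codes


def enumerate_boltzmann(spec: TextureSetSpec, beta: float) -> np.ndarray:
    """Exact Boltzmann probabilities over all configurations of a tiny
    lattice, indexed by the mixed-radix configuration code.

    P(I) = exp(-beta U(I)) / Z with Z summed over every configuration.
    Requires n_states ** (H * W) <= 10**6.
    """
    validate_spec(spec)
    H, W = spec.lattice_shape
    n_conf = spec.n_states ** (H * W)
    if n_conf > MAX_ENUMERATION:
        raise ValueError(
            f"lattice too large to enumerate: {spec.n_states}^{H * W} = {n_conf} "
            f"> {MAX_ENUMERATION} configurations"
        )
    configs = _all_configs(spec)
    E = energy_batch(configs, spec)
    logw = -beta * E
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Distractors
# ---------------------------------------------------------------------------

def make_distractor(
    spec: TextureSetSpec,
    mode: str,
    rng: np.random.Generator,
    target: Lattice | None = None,
) -> Lattice:
    """Draw one distractor lattice.

    ``"uniform"`` — i.i.d. uniform amplitudes (the noise images of the main
    task).  ``"permuted"`` — a uniformly random spatial permutation of the
    target's amplitudes, which preserves the marginal amplitude counts
    exactly while destroying all geometric structure (the control task).
    """
    if mode == "uniform":
        return rng.integers(0, spec.n_states, size=spec.lattice_shape, dtype=np.int64)
    if mode == "permuted":
        if target is None:
            raise ValueError("permuted mode requires a target lattice")
        target = validate_lattice(target, spec)
        flat = target.ravel().copy()
        rng.shuffle(flat)
        return flat.reshape(spec.lattice_shape)
    raise ValueError(f"unknown distractor mode {mode!r}")


# ---------------------------------------------------------------------------
# Goodness-of-fit helper
# ---------------------------------------------------------------------------

def chi2_gof(
    observed: np.ndarray,
    probs: np.ndarray,
    min_expected: float = 5.0,
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of observed category counts to exact
    probabilities, pooling the smallest-expectation cells.

    Cells whose expected count falls below ``min_expected`` are pooled
    (smallest first) into a single cell, the standard remedy for sparse
    multinomial tables.  Returns ``(chi2, dof, p_value)``.
    """
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if observed.shape != probs.shape:
        raise ValueError("observed and probs must have the same length")
    n = observed.sum()
    expected = probs * n
    order = np.argsort(expected)
    obs, exp = observed[order], expected[order]
    csum = np.cumsum(exp)
    # pool the leading cells whose running expectation is still small
    k = int(np.searchsorted(csum, min_expected, side="left"))
    k = min(k + 1, len(exp) - 1)
    while k < len(exp) - 1 and exp[k] < min_expected:
        k += 1
    if k > 0:
        obs = np.concatenate([[obs[:k].sum()], obs[k:]])
        exp = np.concatenate([[exp[:k].sum()], exp[k:]])
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    if len(exp) < 2:
        warnings.warn("chi2_gof: fewer than 2 usable cells; returning p=1")
        return 0.0, 0, 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p
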