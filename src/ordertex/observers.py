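"""Theoretical observers for the 4AFC order-detection task.

Four observers, each reducing a quadrant's texture to a decision statistic:

* **Luminance** — the 3-vector of per-amplitude blob counts; blind to all
  geometric structure.
* **Ideal** — the per-offset 3x3 joint-amplitude contingency counts
  (9 numbers per interacting pair), which are the sufficient statistics of
  the pairwise Boltzmann model: the energy is a linear functional of them.
* **Order** — the scalar order parameter (mean conformance of local pairs
  to the ground-state symmetry).
* **Channel energy** — the summed local energy of a quadrature pair of
  even/odd Gabor filters applied to the rendered quadrant image.

Decisions follow signal detection theory: probability densities of the
statistic under the target (at each beta) and under the distractor are
estimated from training samples — kernel density estimation for the
multidimensional statistics, a moment-matched Gaussian for the scalar
ones — and the chosen quadrant maximises the likelihood of the display,
equivalently the per-quadrant likelihood ratio.

Because log P_beta(I) = -beta U(I) - log Z, the exact maximum-likelihood
rule for the Ideal observer reduces to picking the minimum-energy quadrant
(for beta > 0); that analytic rule is provided as the reference against
which the KDE-based Ideal observer is validated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as sfft
from scipy import signal
from scipy.special import logsumexp

from . import order as order_mod
from .render_io import ARCMIN, RenderSpec
from .texture_model import Lattice, TextureSetSpec, energy, validate_lattice

__all__ = [
    "QuadrantStatistic",
    "DensityModel",
    "GaborSpec",
    "luminance_statistic",
    "pair_statistic",
    "luminance_statistic_batch",
    "pair_statistic_batch",
    "gabor_kernels",
    "channel_energy_map",
    "quadrant_energy",
    "fit_density",
    "fit_density_pair",
    "decide_4afc",
    "analytic_ideal_decide",
    "Observer",
    "LuminanceObserver",
    "IdealObserver",
    "OrderObserver",
    "ChannelEnergyObserver",
    "AnalyticIdealObserver",
    "make_observer",
    "OBSERVER_NAMES",
    "default_gabor",
    "published_gabor_table",
]


@dataclass(frozen=True)
class QuadrantStatistic:
    """Decision statistic of one quadrant."""

    kind: str  # luminance | pair | order | channel_energy
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.atleast_1d(np.asarray(self.values, dtype=float)))


# ---------------------------------------------------------------------------
# Count statistics
# ---------------------------------------------------------------------------

def luminance_statistic(config: Lattice, n_states: int = 3) -> QuadrantStatistic:
    """Per-amplitude blob counts (sums to H*W); invariant under any spatial
    rearrangement, so a permuted distractor has exactly the target's value."""
    config = np.asarray(config)
    counts = np.bincount(config.ravel(), minlength=n_states).astype(float)
    return QuadrantStatistic("luminance", counts)


def pair_statistic(config: Lattice, spec: TextureSetSpec) -> QuadrantStatistic:
    """Joint-amplitude counts over all sites for each interaction offset,
    flattened to 9 numbers per offset (cyclic wrapping; each unordered pair
    once, consistent with the energy sum)."""
    config = validate_lattice(config, spec)
    return QuadrantStatistic("pair", pair_statistic_batch(config[None], spec)[0])


def luminance_statistic_batch(states: np.ndarray, n_states: int) -> np.ndarray:
    """Luminance counts for a stack of lattices, shape (n, S)."""
    n = states.shape[0]
    flat = states.reshape(n, -1)
    out = np.zeros((n, n_states))
    for s in range(n_states):
        out[:, s] = (flat == s).sum(axis=1)
    return out


def pair_statistic_batch(states: np.ndarray, spec: TextureSetSpec) -> np.ndarray:
    """Pair contingency counts for a stack of lattices, shape (n, 9*P)."""
    n = states.shape[0]
    S = spec.n_states
    parts = []
    for (dy, dx), _ in zip(spec.offsets, spec.potentials):
        partner = np.roll(states, shift=(-dy, -dx), axis=(1, 2))
        joint = (states * S + partner).reshape(n, -1)
        counts = np.zeros((n, S * S))
        for j in range(S * S):
            counts[:, j] = (joint == j).sum(axis=1)
        parts.append(counts)
    return np.concatenate(parts, axis=1)


def energy_from_pair_statistic(stat: np.ndarray, spec: TextureSetSpec) -> float:
    """Reconstruct U(I) as the inner product of pair counts with the
    potential matrices (the linearity that makes them sufficient)."""
    stat = np.asarray(stat, dtype=float).ravel()
    S = spec.n_states
    total = 0.0
    for i, U in enumerate(spec.potentials):
        total += float(stat[i * S * S : (i + 1) * S * S] @ U.ravel())
    return total


# ---------------------------------------------------------------------------
# Gabor channel energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborSpec:
    """Quadrature Gabor filter parameters.

    ``sigma`` (degrees) is the envelope width, ``theta`` (degrees) the
    orientation of the carrier wavevector, ``freq`` the spatial frequency
    in cycles/degree, ``pixel_scale`` the sampling rate in pixels/degree.
    """

    sigma: float
    theta: float
    freq: float
    pixel_scale: float = 120.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.freq <= 0 or self.pixel_scale <= 0:
            raise ValueError("sigma, freq and pixel_scale must be positive")
        if not 0 <= self.theta < 180:
            raise ValueError(f"theta must be in [0, 180), got {self.theta}")


def gabor_kernels(g: GaborSpec) -> tuple[np.ndarray, np.ndarray]:
    """Even (cosine) and odd (sine) Gabor kernels.

    G_even(x, y) = exp(-(x^2+y^2) / 2 sigma^2) cos(2 pi f (x cos th + y sin th))
    G_odd  (x, y) = same with sine.

    Sampled at ``pixel_scale``, truncated at +-3 sigma.  The odd kernel is
    antisymmetric on the symmetric grid, so its DC response is zero by
    construction.
    """
    sigma_px = g.sigma * g.pixel_scale
    r = int(np.ceil(3 * sigma_px))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float) / g.pixel_scale
    envelope = np.exp(-(x**2 + y**2) / (2 * g.sigma**2))
    th = np.deg2rad(g.theta)
    phase = 2 * np.pi * g.freq * (x * np.cos(th) + y * np.sin(th))
    even = envelope * np.cos(phase)
    odd = envelope * np.sin(phase)
    return even, odd


def channel_energy_map(image: np.ndarray, g: GaborSpec) -> np.ndarray:
    """Local energy map M = (I * G_odd)^2 + (I * G_even)^2.

    ``*`` is convolution with zero padding at the borders; M >= 0
    everywhere, phase-invariant for a matched grating.
    """
    image = np.asarray(image, dtype=float)
    even, odd = gabor_kernels(g)
    if image.shape[0] < even.shape[0] or image.shape[1] < even.shape[1]:
        raise ValueError(
            f"image {image.shape} smaller than the truncated filter {even.shape}"
        )
    re = signal.fftconvolve(image, even, mode="same")
    ro = signal.fftconvolve(image, odd, mode="same")
    return re**2 + ro**2


def quadrant_energy(display_image: np.ndarray, quadrant: int, g: GaborSpec) -> float:
    """Sum of the channel-energy map over one quadrant of a display,
    computed on the quadrant sub-image alone (no cross-border leakage)."""
    from .render_io import quadrant_slices

    h, w = display_image.shape
    if not 0 <= quadrant < 4:
        raise ValueError(f"quadrant {quadrant} out of range")
    sy, sx = quadrant_slices(h, w)[quadrant]
    return float(channel_energy_map(display_image[sy, sx], g).sum())


_GABOR_TABLE_PATH = Path(__file__).parent / "data" / "gabor_table.yaml"


def published_gabor_table() -> dict[int, GaborSpec]:
    """Published per-set Gabor parameters, read from the shipped config."""
    import yaml

    raw = yaml.safe_load(_GABOR_TABLE_PATH.read_text())
    return {
        int(k): GaborSpec(sigma=v["sigma"], theta=v["theta"], freq=v["freq"])
        for k, v in raw["sets"].items()
    }


# Per-builtin defaults: carrier frequency at the fundamental of the ordered
# pattern (half-period of 2 blob spacings ~ 0.3 deg), orientation along the
# pattern's modulation axis.
_BUILTIN_GABORS = {
    "potts": GaborSpec(sigma=0.085, theta=45.0, freq=3.31),
    "checkerboard": GaborSpec(sigma=0.085, theta=45.0, freq=2.34),
    "stripes": GaborSpec(sigma=0.085, theta=0.0, freq=3.31),
}


def default_gabor(spec_name: str) -> GaborSpec:
    try:
        return _BUILTIN_GABORS[spec_name]
    except KeyError:
        return GaborSpec(sigma=0.085, theta=45.0, freq=3.31)


class _ChannelEnergyPlan:
    """Cached FFT pipeline for per-quadrant channel energy of lattices.

    The rendered image is background + deltas (x) blob, so the filter
    responses decompose into a fixed background response plus the
    convolution of the amplitude delta grid with the blob-convolved Gabor
    kernels; both kernels' transforms are precomputed once per geometry.
    """

    def __init__(self, spec: TextureSetSpec, render: RenderSpec, gabor: GaborSpec):
        from .render_io import _blob_kernel

        self.spec = spec
        self.render = render
        self.gabor = gabor
        H, W = spec.lattice_shape
        s = render.spacing_px
        self.h_px = int(round(H * s))
        self.w_px = int(round(W * s))
        self.rows = np.clip(
            np.round((np.arange(H) + 0.5) * s - 0.5).astype(int), 0, self.h_px - 1
        )
        self.cols = np.clip(
            np.round((np.arange(W) + 0.5) * s - 0.5).astype(int), 0, self.w_px - 1
        )
        blob = _blob_kernel(render.sigma_px)
        even, odd = gabor_kernels(GaborSpec(gabor.sigma, gabor.theta, gabor.freq, render.pixel_scale))
        if self.h_px < even.shape[0] or self.w_px < even.shape[1]:
            raise ValueError("rendered quadrant smaller than the Gabor kernel")
        k_even = signal.fftconvolve(blob, even, mode="full")
        k_odd = signal.fftconvolve(blob, odd, mode="full")
        bg = np.full((self.h_px, self.w_px), render.background)
        self.bg_even = signal.fftconvolve(bg, even, mode="same")
        self.bg_odd = signal.fftconvolve(bg, odd, mode="same")
        kh, kw = k_even.shape
        self.fh = sfft.next_fast_len(self.h_px + kh - 1)
        self.fw = sfft.next_fast_len(self.w_px + kw - 1)
        # single precision: the statistic is a sum of ~1e5 squared filter
        # responses, so float32's ~1e-7 relative error is negligible
        self.K_even = sfft.rfft2(k_even.astype(np.float32), s=(self.fh, self.fw))
        self.K_odd = sfft.rfft2(k_odd.astype(np.float32), s=(self.fh, self.fw))
        self.bg_even = self.bg_even.astype(np.float32)
        self.bg_odd = self.bg_odd.astype(np.float32)
        # 'same' crop offsets for a full linear convolution
        self.y0, self.x0 = (kh - 1) // 2, (kw - 1) // 2

    def statistics(self, lattices: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Summed quadrant energy for a stack of lattices, shape (n,)."""
        lattices = np.asarray(lattices)
        n = lattices.shape[0]
        amps = np.asarray(self.render.amplitude_map)[lattices]
        out = np.empty(n)
        for i0 in range(0, n, chunk):
            a = amps[i0 : i0 + chunk]
            deltas = np.zeros((a.shape[0], self.h_px, self.w_px), dtype=np.float32)
            deltas[:, self.rows[:, None], self.cols[None, :]] = a
            D = sfft.rfft2(deltas, s=(self.fh, self.fw))
            re = sfft.irfft2(D * self.K_even, s=(self.fh, self.fw))[
                :, self.y0 : self.y0 + self.h_px, self.x0 : self.x0 + self.w_px
            ]
            ro = sfft.irfft2(D * self.K_odd, s=(self.fh, self.fw))[
                :, self.y0 : self.y0 + self.h_px, self.x0 : self.x0 + self.w_px
            ]
            M = (re + self.bg_even) ** 2 + (ro + self.bg_odd) ** 2
            out[i0 : i0 + chunk] = M.sum(axis=(1, 2))
        return out


# ---------------------------------------------------------------------------
# Density models
# ---------------------------------------------------------------------------

BANDWIDTH_FLOOR = 1e-6

# Bandwidth, in whitened units, of the shared-covariance kernels used for
# high-dimensional count statistics (see fit_density_pair).  Rule-of-thumb
# bandwidths minimise pointwise density error but make likelihood-RATIO
# rankings nearest-neighbour dominated and noisy once the statistic has more
# than a handful of effective dimensions; a deliberately oversmoothed kernel
# stabilises the ranking (in the wide-kernel limit it approaches the
# pooled-metric linear discriminant).
KDE_RANKING_BANDWIDTH = 4.0


@dataclass(frozen=True)
class DensityModel:
    """Estimated density of a decision statistic.

    ``kde`` — product-Gaussian-kernel estimate with per-dimension
    rule-of-thumb (Scott) bandwidths; ``kde_whitened`` — Gaussian kernels
    with covariance proportional to a shared (pooled) training covariance,
    evaluated in its non-degenerate principal subspace; ``gaussian`` —
    diagonal moment fit.
    """

    kind: str
    training_n: int
    dim: int
    # kde fields
    data: np.ndarray | None = None  # (n, dim) raw or (n, rank) whitened
    bandwidths: np.ndarray | None = None
    # gaussian fields
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    # whitened-kde fields
    center: np.ndarray | None = None  # (dim,)
    basis: np.ndarray | None = None  # (dim, rank) whitening projection
    bandwidth: float | None = None  # scalar, whitened units
    log_norm: float = 0.0  # -0.5 * sum(log eigenvalues) of the kernel covariance

    def logpdf(self, x: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Log density at points ``x`` of shape (m, dim) or (dim,)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError(f"points have dimension {x.shape[1]}, model has {self.dim}")
        if self.kind == "gaussian":
            z = (x - self.mean) / self.sd
            return -0.5 * (z**2).sum(axis=1) - np.log(self.sd).sum() - 0.5 * self.dim * np.log(2 * np.pi)
        if self.kind == "kde_whitened":
            r = self.data.shape[1]
            zx = (x - self.center) @ self.basis
            h = self.bandwidth
            const = (
                self.log_norm
                - r * np.log(h)
                - 0.5 * r * np.log(2 * np.pi)
                - np.log(self.training_n)
            )
            out = np.empty(x.shape[0])
            for i0 in range(0, x.shape[0], chunk):
                z = (zx[i0 : i0 + chunk, None, :] - self.data[None, :, :]) / h
                out[i0 : i0 + chunk] = logsumexp(-0.5 * (z**2).sum(axis=2), axis=1) + const
            return out
        h = self.bandwidths
        const = -np.log(h).sum() - 0.5 * self.dim * np.log(2 * np.pi) - np.log(self.training_n)
        out = np.empty(x.shape[0])
        for i0 in range(0, x.shape[0], chunk):
            xc = x[i0 : i0 + chunk]
            z = (xc[:, None, :] - self.data[None, :, :]) / h
            logk = -0.5 * (z**2).sum(axis=2)
            out[i0 : i0 + chunk] = logsumexp(logk, axis=1) + const
        return out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def to_json(self) -> str:
        d = {"kind": self.kind, "training_n": self.training_n, "dim": self.dim,
             "log_norm": self.log_norm}
        for key in ("data", "bandwidths", "mean", "sd", "center", "basis"):
            val = getattr(self, key)
            d[key] = None if val is None else np.asarray(val).tolist()
        d["bandwidth"] = self.bandwidth
        return json.dumps(d)

    @staticmethod
    def from_json(text: str) -> "DensityModel":
        d = json.loads(text)
        arr = lambda k: None if d.get(k) is None else np.asarray(d[k], dtype=float)
        return DensityModel(
            kind=d["kind"],
            training_n=int(d["training_n"]),
            dim=int(d["dim"]),
            data=arr("data"),
            bandwidths=arr("bandwidths"),
            mean=arr("mean"),
            sd=arr("sd"),
            center=arr("center"),
            basis=arr("basis"),
            bandwidth=d.get("bandwidth"),
            log_norm=float(d.get("log_norm", 0.0)),
        )


def fit_density(samples: np.ndarray, kind: str = "kde") -> DensityModel:
    """Fit a density model to statistic vectors (one row per sample).

    Zero-variance dimensions get their bandwidth (or sd) floored at a small
    positive epsilon, with a warning — the density then concentrates near
    the constant value but stays finite.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples to fit a density, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite values")
    sd = X.std(axis=0, ddof=1)
    floor = BANDWIDTH_FLOOR * np.maximum(1.0, np.abs(X.mean(axis=0)))
    if np.any(sd <= 0):
        warnings.warn(
            f"{int((sd <= 0).sum())} zero-variance dimension(s); bandwidth floored",
            stacklevel=2,
        )
    sd_floored = np.maximum(sd, floor)
    if kind == "kde":
        h = sd_floored * n ** (-1.0 / (d + 4))  # Scott's rule, per dimension
        return DensityModel(kind="kde", training_n=n, dim=d, data=X, bandwidths=h)
    if kind == "gaussian":
        return DensityModel(kind="gaussian", training_n=n, dim=d, mean=X.mean(axis=0), sd=sd_floored)
    raise ValueError(f"unknown density kind {kind!r}")


def fit_density_pair(
    target_samples: np.ndarray,
    distractor_samples: np.ndarray,
    kind: str = "kde",
) -> tuple[DensityModel, DensityModel]:
    """Fit target and distractor densities for one condition.

    For ``kde`` and ``gaussian`` the two classes are fitted independently.
    ``kde_whitened`` fits both with Gaussian kernels sharing one covariance
    — the pooled within-class covariance of the two training sets — and a
    conservative bandwidth (KDE_RANKING_BANDWIDTH in whitened units).
    Count statistics live on an affine subspace (their sums are fixed), so
    the kernel is restricted to the pooled covariance's non-degenerate
    principal subspace; the discarded directions are common to both classes
    and cancel from every likelihood ratio.
    """
    if kind != "kde_whitened":
        return fit_density(target_samples, kind), fit_density(distractor_samples, kind)
    Xt = np.atleast_2d(np.asarray(target_samples, dtype=float))
    Xd = np.atleast_2d(np.asarray(distractor_samples, dtype=float))
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    if Xd.ndim == 1:
        Xd = Xd[:, None]
    if Xt.shape[1] != Xd.shape[1]:
        raise ValueError("target and distractor statistics differ in dimension")
    d = Xt.shape[1]
    pooled = np.vstack([Xt - Xt.mean(axis=0), Xd - Xd.mean(axis=0)])
    cov = np.cov(pooled.T) if d > 1 else np.atleast_2d(np.var(pooled, ddof=1))
    evals, evecs = np.linalg.eigh(cov)
    tol = max(float(evals.max()), 1.0) * 1e-9
    keep = evals > tol
    if not np.any(keep):
        warnings.warn("degenerate training sets: all dimensions constant", stacklevel=2)
        keep = evals >= evals.max()
        evals = np.maximum(evals, BANDWIDTH_FLOOR**2)
    W = evecs[:, keep] / np.sqrt(evals[keep])
    log_norm = -0.5 * float(np.log(evals[keep]).sum())
    center = np.vstack([Xt, Xd]).mean(axis=0)
    h = KDE_RANKING_BANDWIDTH

    def make(X: np.ndarray) -> DensityModel:
        return DensityModel(
            kind="kde_whitened",
            training_n=X.shape[0],
            dim=d,
            data=(X - center) @ W,
            center=center,
            basis=W,
            bandwidth=h,
            log_norm=log_norm,
        )

    return make(Xt), make(Xd)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

TIE_TOL = 1e-9


def _argmax_random_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    scores = np.asarray(scores, dtype=float)
    best = scores.max()
    ties = np.flatnonzero(scores >= best - TIE_TOL * max(1.0, abs(best)))
    return int(ties[0] if len(ties) == 1 else rng.choice(ties))


def decide_4afc(
    stats: list[QuadrantStatistic] | np.ndarray,
    target_density: DensityModel,
    distractor_density: DensityModel,
    rng: np.random.Generator,
) -> int:
    """Maximum-likelihood quadrant choice.

    Chooses argmax over q of f_t(s_q) * prod_{q' != q} f_d(s_{q'}); since
    the product of all distractor densities is common, this equals the
    argmax of the per-quadrant log likelihood ratio
    log f_t(s_q) - log f_d(s_q).  Ties are broken uniformly at random.
    """
    if isinstance(stats, (list, tuple)):
        kinds = {s.kind for s in stats if isinstance(s, QuadrantStatistic)}
        if len(kinds) > 1:
            raise ValueError(f"mixed statistic kinds: {kinds}")
        X = np.stack([np.asarray(s.values if isinstance(s, QuadrantStatistic) else s, dtype=float) for s in stats])
    else:
        X = np.asarray(stats, dtype=float)
    if X.shape[0] != 4:
        raise ValueError(f"expected 4 quadrant statistics, got {X.shape[0]}")
    scores = target_density.logpdf(X) - distractor_density.logpdf(X)
    return _argmax_random_ties(scores, rng)


def analytic_ideal_decide(
    configs: list[Lattice],
    spec: TextureSetSpec,
    beta: float,
    rng: np.random.Generator,
) -> int:
    """Exact maximum-likelihood choice for the pairwise Boltzmann model.

    log P_beta(I) - log P_uniform(I) = -beta U(I) + const, so for beta > 0
    the target is the minimum-energy quadrant.  Undefined at beta = 0
    (target and distractor distributions coincide); callers must fall back
    to chance there.
    """
    if beta <= 0:
        raise ValueError("analytic ideal rule is undefined at beta = 0")
    if len(configs) != 4:
        raise ValueError("expected 4 quadrant configurations")
    energies = np.array([energy(c, spec) for c in configs])
    return _argmax_random_ties(-energies, rng)


# ---------------------------------------------------------------------------
# Observer objects
# ---------------------------------------------------------------------------

OBSERVER_NAMES = ("luminance", "ideal", "ideal_analytic", "order", "channel_energy")


class Observer:
    """Base class: maps lattices to statistic vectors and declares the
    density family used to model them."""

    name: str = "observer"
    statistic_kind: str = "generic"
    density_kind: str = "kde"

    def __init__(self, spec: TextureSetSpec):
        self.spec = spec

    def statistics(self, lattices: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def statistic(self, config: Lattice) -> QuadrantStatistic:
        return QuadrantStatistic(self.statistic_kind, self.statistics(np.asarray(config)[None])[0])


class LuminanceObserver(Observer):
    name = "luminance"
    statistic_kind = "luminance"
    density_kind = "kde"

    def statistics(self, lattices):
        return luminance_statistic_batch(np.asarray(lattices), self.spec.n_states)


class IdealObserver(Observer):
    """KDE-based observer on the pair-count sufficient statistics."""

    name = "ideal"
    statistic_kind = "pair"
    density_kind = "kde_whitened"

    def statistics(self, lattices):
        return pair_statistic_batch(np.asarray(lattices), self.spec)


class OrderObserver(Observer):
    """Observer on the scalar order parameter, modelled by its mean and
    variability at each temperature (a two-moment Gaussian)."""

    name = "order"
    statistic_kind = "order"
    density_kind = "gaussian"

    def __init__(self, spec: TextureSetSpec):
        super().__init__(spec)
        self.orbit = order_mod.ground_state_orbit(spec)
        self._allowed = order_mod._allowed_joints(spec, self.orbit)

    def statistics(self, lattices):
        lattices = np.asarray(lattices)
        H, W = self.spec.lattice_shape
        rows, cols = np.indices((H, W))
        vals = np.zeros(lattices.shape[0])
        n_pairs = 2 * len(self.spec.offsets)
        for i, (dy, dx) in enumerate(self.spec.offsets):
            partner = np.roll(lattices, shift=(-dy, -dx), axis=(1, 2))
            match = self._allowed[i, rows, cols, lattices, partner]
            vals += 2 * match.mean(axis=(1, 2))  # fwd and bwd average equal
        return (vals / n_pairs)[:, None]


class ChannelEnergyObserver(Observer):
    name = "channel_energy"
    statistic_kind = "channel_energy"
    density_kind = "gaussian"

    def __init__(
        self,
        spec: TextureSetSpec,
        render: RenderSpec | None = None,
        gabor: GaborSpec | None = None,
    ):
        super().__init__(spec)
        self.render = render or RenderSpec()
        self.gabor = gabor or default_gabor(spec.name)
        self._plan = _ChannelEnergyPlan(spec, self.render, self.gabor)

    def statistics(self, lattices):
        return self._plan.statistics(np.asarray(lattices))[:, None]


class AnalyticIdealObserver(Observer):
    """Exact minimal-energy maximum-likelihood rule (no training)."""

    name = "ideal_analytic"
    statistic_kind = "energy"
    density_kind = "analytic"

    def statistics(self, lattices):
        from .texture_model import energy_batch

        return energy_batch(np.asarray(lattices), self.spec)[:, None]


def make_observer(name: str, spec: TextureSetSpec, **kwargs) -> Observer:
    """Observer factory by name (one of OBSERVER_NAMES)."""
    table = {
        "luminance": LuminanceObserver,
        "ideal": IdealObserver,
        "ideal_analytic": AnalyticIdealObserver,
        "order": OrderObserver,
        "channel_energy": ChannelEnergyObserver,
    }
    try:
        cls = table[name]
    except KeyError:
        raise KeyError(f"unknown observer {name!r}; available: {', '.join(OBSERVER_NAMES)}")
    return cls(spec, **kwargs)
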