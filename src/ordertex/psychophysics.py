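"""4AFC simulation, psychometric curves, thresholds and curve comparison.

Each simulated trial places one target texture (an equilibrium sample at
inverse temperature beta) in a random quadrant and three distractors in the
others — i.i.d. uniform-amplitude textures in ``uniform_distractor`` mode,
or random spatial permutations of that trial's target in
``permuted_distractor`` mode.  The observer reduces each quadrant to its
statistic and picks the maximum-likelihood quadrant; the fraction of
correct choices per beta forms the psychometric curve.  Thresholds are the
smallest beta reaching a criterion level (62.5% correct by default, halfway
between chance and perfect for 4 alternatives), interpolated linearly in
log beta.  Curves are compared level-by-level with pooled-proportion
chi-square statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .observers import (
    AnalyticIdealObserver,
    DensityModel,
    Observer,
    _argmax_random_ties,
    fit_density_pair,
    make_observer,
)
from .sampler import make_distractor, sample_texture_ensemble
from .texture_model import TextureSetSpec, validate_spec

__all__ = [
    "PsychometricCurve",
    "ThresholdSpec",
    "TrainedObserver",
    "train_observer",
    "simulate_trial",
    "performance_curve",
    "estimate_threshold",
    "chi2_compare",
    "curve_to_frame",
    "curve_from_frame",
    "derive_seed",
]

MODES = ("uniform_distractor", "permuted_distractor")
CHANCE = 0.25


def derive_seed(master: int, *parts) -> int:
    """Stable per-condition seed below 2**31, mixed from a master seed and
    identifying strings (spec, observer, beta, ...)."""
    h = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int((int(master) * 1000003 + h) % (2**31 - 1))


@dataclass(frozen=True)
class PsychometricCurve:
    """Proportion correct per beta, with recoverable trial counts."""

    beta_grid: tuple[float, ...]
    n_correct: tuple[int, ...]
    n_trials: tuple[int, ...]
    observer_id: str
    mode: str = "uniform_distractor"

    def __post_init__(self) -> None:
        if not (len(self.beta_grid) == len(self.n_correct) == len(self.n_trials)):
            raise ValueError("beta_grid, n_correct and n_trials lengths differ")
        if any(k < 0 or k > n for k, n in zip(self.n_correct, self.n_trials)):
            raise ValueError("n_correct out of range")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def p_correct(self) -> np.ndarray:
        return np.asarray(self.n_correct) / np.asarray(self.n_trials)

    @property
    def standard_errors(self) -> np.ndarray:
        p = self.p_correct
        return np.sqrt(p * (1 - p) / np.asarray(self.n_trials))


@dataclass(frozen=True)
class ThresholdSpec:
    """Criterion level and interpolation rule for threshold extraction."""

    level: float = 0.625
    interpolation: str = "linear_in_log_beta"

    def __post_init__(self) -> None:
        if not CHANCE < self.level < 1.0:
            raise ValueError(f"threshold level must be in ({CHANCE}, 1), got {self.level}")
        if self.interpolation != "linear_in_log_beta":
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedObserver:
    """An observer with densities fitted for one (spec, beta, mode)."""

    observer: Observer
    beta: float
    mode: str
    target_density: DensityModel | None
    distractor_density: DensityModel | None

    @property
    def is_analytic(self) -> bool:
        return isinstance(self.observer, AnalyticIdealObserver)

    def decide(self, quadrant_lattices: np.ndarray, rng: np.random.Generator) -> int:
        """Choose a quadrant given the 4 quadrant lattices."""
        stats4 = self.observer.statistics(np.asarray(quadrant_lattices))
        return self._decide_from_stats(stats4, rng)

    def _decide_from_stats(self, stats4: np.ndarray, rng: np.random.Generator) -> int:
        if self.is_analytic:
            if self.beta <= 0:
                return int(rng.integers(4))  # rule undefined: chance
            return _argmax_random_ties(-stats4[:, 0], rng)
        scores = self.target_density.logpdf(stats4) - self.distractor_density.logpdf(stats4)
        return _argmax_random_ties(scores, rng)


def train_observer(
    observer: Observer,
    beta: float,
    mode: str = "uniform_distractor",
    seed: int = 0,
    n_train: int = 1000,
    target_samples: np.ndarray | None = None,
    n_chains: int = 100,
    burn_in: int | None = None,
    thin: int | None = None,
) -> TrainedObserver:
    """Fit target and distractor densities for one condition.

    Target training samples are equilibrium draws at ``beta`` (1000 by
    default); distractor samples are i.i.d. uniform lattices, or random
    permutations of the target samples in permuted mode.  The analytic
    ideal observer needs no training and is returned as-is.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    spec = observer.spec
    if isinstance(observer, AnalyticIdealObserver):
        return TrainedObserver(observer, float(beta), mode, None, None)
    from .sampler import DEFAULT_BURN_IN, DEFAULT_THIN

    rng = np.random.default_rng(derive_seed(seed, "train", spec.name, observer.name, beta, mode))
    if target_samples is None:
        target_samples = sample_texture_ensemble(
            spec,
            beta,
            n_train,
            seed=derive_seed(seed, "train-targets", spec.name, beta),
            n_chains=n_chains,
            burn_in=DEFAULT_BURN_IN if burn_in is None else burn_in,
            thin=DEFAULT_THIN if thin is None else thin,
        )
    target_samples = np.asarray(target_samples)
    if mode == "uniform_distractor":
        distractors = rng.integers(
            0, spec.n_states, size=target_samples.shape, dtype=np.int64
        )
    else:
        flat = target_samples.reshape(target_samples.shape[0], -1)
        distractors = np.stack(
            [rng.permutation(row).reshape(spec.lattice_shape) for row in flat]
        )
    t_stats = observer.statistics(target_samples)
    d_stats = observer.statistics(distractors)
    td, dd = fit_density_pair(t_stats, d_stats, observer.density_kind)
    return TrainedObserver(observer, float(beta), mode, td, dd)


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def simulate_trial(
    spec: TextureSetSpec,
    beta: float,
    observer: TrainedObserver,
    mode: str,
    rng: np.random.Generator,
    target: np.ndarray | None = None,
    burn_in: int | None = None,
    thin: int | None = None,
) -> bool:
    """One 4AFC trial; returns whether the target quadrant was chosen.

    If no pre-drawn ``target`` lattice is supplied, one is sampled from a
    fresh seeded chain at ``beta``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if observer.target_density is None and not observer.is_analytic:
        raise ValueError("observer has not been trained for this condition")
    if target is None:
        from .sampler import DEFAULT_BURN_IN, DEFAULT_THIN, SamplingRequest, sample_texture

        req = SamplingRequest(
            spec=spec,
            beta=beta,
            n_sweeps=DEFAULT_THIN if thin is None else thin,
            burn_in=DEFAULT_BURN_IN if burn_in is None else burn_in,
            thin=DEFAULT_THIN if thin is None else thin,
            seed=int(rng.integers(2**31 - 1)),
        )
        target = sample_texture(req)[-1]
    dmode = "uniform" if mode == "uniform_distractor" else "permuted"
    distractors = [make_distractor(spec, dmode, rng, target=target) for _ in range(3)]
    tq = int(rng.integers(4))
    quadrants = []
    di = iter(distractors)
    for q in range(4):
        quadrants.append(target if q == tq else next(di))
    choice = observer.decide(np.stack(quadrants), rng)
    return choice == tq


def _run_trials(
    trained: TrainedObserver,
    targets: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> int:
    """Vectorised trial loop over pre-drawn target lattices."""
    spec = trained.observer.spec
    n = targets.shape[0]
    H, W = spec.lattice_shape
    if mode == "uniform_distractor":
        distractors = rng.integers(0, spec.n_states, size=(n, 3, H, W), dtype=np.int64)
    else:
        flat = targets.reshape(n, -1)
        distractors = np.stack(
            [
                np.stack([rng.permutation(row).reshape(H, W) for _ in range(3)])
                for row in flat
            ]
        )
    tq = rng.integers(4, size=n)
    # assemble (n, 4, H, W) displays
    displays = np.empty((n, 4, H, W), dtype=np.int64)
    for t in range(n):
        di = 0
        for q in range(4):
            if q == tq[t]:
                displays[t, q] = targets[t]
            else:
                displays[t, q] = distractors[t, di]
                di += 1
    stats_all = trained.observer.statistics(displays.reshape(n * 4, H, W))
    if trained.is_analytic:
        if trained.beta <= 0:
            choices = rng.integers(4, size=n)
        else:
            scores = -stats_all[:, 0].reshape(n, 4)
            choices = np.array([_argmax_random_ties(s, rng) for s in scores])
    else:
        scores = (
            trained.target_density.logpdf(stats_all)
            - trained.distractor_density.logpdf(stats_all)
        ).reshape(n, 4)
        choices = np.array([_argmax_random_ties(s, rng) for s in scores])
    return int((choices == tq).sum())


def performance_curve(
    spec: TextureSetSpec,
    observer: str | Observer,
    beta_grid=None,
    n_trials: int = 1000,
    mode: str = "uniform_distractor",
    seed: int = 0,
    n_train: int = 1000,
    n_chains: int = 100,
    burn_in: int | None = None,
    thin: int | None = None,
    observer_kwargs: dict | None = None,
) -> PsychometricCurve:
    """Simulate a full psychometric curve for one observer.

    For each beta, densities are trained on ``n_train`` equilibrium
    samples, ``n_trials`` 4AFC trials are simulated, and the fraction
    correct is recorded.  Per-beta seeds are derived from the master seed
    and the condition identifiers, so any single beta can be reproduced
    independently.
    """
    validate_spec(spec)
    if isinstance(observer, str):
        observer = make_observer(observer, spec, **(observer_kwargs or {}))
    if beta_grid is None:
        beta_grid = spec.beta_grid
    from .sampler import DEFAULT_BURN_IN, DEFAULT_THIN

    bi = DEFAULT_BURN_IN if burn_in is None else burn_in
    th = DEFAULT_THIN if thin is None else thin
    n_correct = []
    for beta in beta_grid:
        cond_seed = derive_seed(seed, spec.name, observer.name, beta, mode)
        rng = np.random.default_rng(cond_seed)
        need_train = not isinstance(observer, AnalyticIdealObserver)
        n_samp = n_trials + (n_train if need_train else 0)
        samples = sample_texture_ensemble(
            spec,
            beta,
            n_samp,
            seed=derive_seed(cond_seed, "samples"),
            n_chains=n_chains,
            burn_in=bi,
            thin=th,
        )
        if need_train:
            trained = train_observer(
                observer, beta, mode, seed=cond_seed, n_train=n_train,
                target_samples=samples[:n_train],
            )
            trial_targets = samples[n_train:]
        else:
            trained = TrainedObserver(observer, float(beta), mode, None, None)
            trial_targets = samples
        n_correct.append(_run_trials(trained, trial_targets, mode, rng))
    return PsychometricCurve(
        beta_grid=tuple(float(b) for b in beta_grid),
        n_correct=tuple(n_correct),
        n_trials=tuple([n_trials] * len(beta_grid)),
        observer_id=observer.name,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Thresholds and curve comparison
# ---------------------------------------------------------------------------

def estimate_threshold(
    curve: PsychometricCurve,
    t: ThresholdSpec = ThresholdSpec(),
) -> float | None:
    """Smallest beta at which the curve crosses the criterion level.

    Linear interpolation in log beta between adjacent grid points (the
    grid spans orders of magnitude); a grid point exactly at the level is
    returned as-is, and a segment starting at beta = 0 is interpolated
    linearly in beta.  Returns None when the curve never reaches the level.
    """
    betas = np.asarray(curve.beta_grid, dtype=float)
    p = curve.p_correct
    level = t.level
    for i in range(len(betas)):
        if np.isclose(p[i], level):
            return float(betas[i])
        if i + 1 < len(betas) and p[i] < level <= p[i + 1]:
            frac = (level - p[i]) / (p[i + 1] - p[i])
            if betas[i] <= 0:
                return float(betas[i] + frac * (betas[i + 1] - betas[i]))
            logb = np.log(betas[i]) + frac * (np.log(betas[i + 1]) - np.log(betas[i]))
            return float(np.exp(logb))
    return None


def chi2_compare(
    curve_a: PsychometricCurve,
    curve_b: PsychometricCurve,
    dof: int | None = None,
) -> tuple[float, int, float]:
    """Pooled-proportion chi-square comparison of two curves.

    At each beta the two binomial outcomes form a 2x2 table; the pooled
    one-degree chi-square contributions are summed over levels.  ``dof``
    defaults to the number of beta levels (configurable, e.g. to mirror a
    9-dof convention).  Symmetric in its arguments; identical curves give
    chi2 = 0, p = 1.
    """
    if tuple(curve_a.beta_grid) != tuple(curve_b.beta_grid):
        raise ValueError("curves are on different beta grids")
    chi2 = 0.0
    for ka, na, kb, nb in zip(
        curve_a.n_correct, curve_a.n_trials, curve_b.n_correct, curve_b.n_trials
    ):
        pooled = (ka + kb) / (na + nb)
        if pooled <= 0 or pooled >= 1:
            continue
        pa, pb = ka / na, kb / nb
        chi2 += (pa - pb) ** 2 / (pooled * (1 - pooled) * (1 / na + 1 / nb))
    if dof is None:
        dof = len(curve_a.beta_grid)
    p = float(stats.chi2.sf(chi2, dof))
    return float(chi2), int(dof), p


# ---------------------------------------------------------------------------
# Tabular round-trip
# ---------------------------------------------------------------------------

def curve_to_frame(curve: PsychometricCurve) -> pd.DataFrame:
    p = curve.p_correct
    return pd.DataFrame(
        {
            "observer": curve.observer_id,
            "mode": curve.mode,
            "beta": curve.beta_grid,
            "n": curve.n_trials,
            "k": curve.n_correct,
            "p": p,
            "se": curve.standard_errors,
        }
    )


def curve_from_frame(df: pd.DataFrame) -> PsychometricCurve:
    obs = df["observer"].unique()
    mode = df["mode"].unique()
    if len(obs) != 1 or len(mode) != 1:
        raise ValueError("frame mixes observers or modes")
    df = df.sort_values("beta")
    return PsychometricCurve(
        beta_grid=tuple(float(b) for b in df["beta"]),
        n_correct=tuple(int(k) for k in df["k"]),
        n_trials=tuple(int(n) for n in df["n"]),
        observer_id=str(obs[0]),
        mode=str(mode[0]),
    )
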