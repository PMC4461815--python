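"""Order fields and the symmetry-specific order parameter.

The amount of order in a configuration is quantified as the mean conformance
of its local pair configurations to the global symmetry of the texture set's
ordered (minimum-energy) phase.  Concretely:

* the *ground-state orbit* of a set is the collection of full-lattice
  minimum-energy configurations generated from its canonical periodic tile
  by cyclic translation and by the state relabelings that preserve the
  energy function;
* a site's interacting pair (the site together with one offset partner)
  *conforms* when its joint state equals the corresponding joint state in
  some member of the orbit — i.e. the pair locally looks like the ordered
  phase, in any of its symmetry-equivalent realisations;
* the *order field* assigns each site the fraction of its incident pairs
  (offsets and their negations) that conform, and the *order parameter* is
  the mean of the field.

With this construction the order parameter is exactly 1 on every orbit
member, and its expectation under i.i.d. uniform states (the disordered,
beta=0 limit) has the closed form  baseline = mean over pair slots of
(number of conforming joint states) / n_states**2  — e.g. 1/3 for the
3-state ferromagnetic Potts set, whose conforming horizontal and vertical
joints are the three matching pairs (s, s).

Measuring conformance against the whole orbit rather than one fixed phase
makes the statistic a function of the symmetry class: a configuration that
locally agrees with *some* ordered phase counts as ordered, which is the
standard reading of an order parameter (cf. the magnetisation magnitude of
a ferromagnet, which does not care which direction the spins chose).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .texture_model import (
    Lattice,
    TextureSetSpec,
    energy,
    state_permutations_preserving,
    validate_lattice,
    validate_spec,
)

__all__ = [
    "OrderStatistic",
    "ground_state_orbit",
    "order_field",
    "order_parameter",
    "uniform_baseline",
    "minimal_tiling_energy",
]


@dataclass(frozen=True)
class OrderStatistic:
    """Order parameter of one configuration.

    ``value`` is the mean of ``field``; ``baseline`` is the exact expected
    value under i.i.d. uniform states.
    """

    value: float
    baseline: float
    field: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"order parameter {self.value} outside [0, 1]")


def ground_state_orbit(spec: TextureSetSpec, max_search_period: int = 4) -> list[Lattice]:
    """All distinct minimum-energy configurations reachable from the
    canonical tile by cyclic translation and energy-preserving relabeling.

    If the spec carries no ``ground_state_tile`` an exhaustive search over
    periodic tiles of period up to ``max_search_period`` finds a
    minimum-energy tile first.
    """
    validate_spec(spec)
    H, W = spec.lattice_shape
    tile = spec.ground_state_tile
    if tile is None:
        if max_search_period < 1:
            raise ValueError("spec has no ground_state_tile and period search is disabled")
        tile = _search_ground_tile(spec, max_search_period)
    th, tw = tile.shape
    base = np.tile(tile, (H // th, W // tw))

    members: dict[bytes, Lattice] = {}
    perms = state_permutations_preserving(spec)
    for perm in perms:
        p = np.asarray(perm)
        relabeled = p[base]
        # distinct translations of a (th, tw)-periodic pattern
        for dy in range(th):
            for dx in range(tw):
                m = np.roll(relabeled, shift=(dy, dx), axis=(0, 1))
                members[m.tobytes()] = m
    orbit = list(members.values())
    energies = [energy(m, spec) for m in orbit]
    e_min = min(energies)
    # energy-preserving relabelings and translations cannot change energy,
    # but guard against a tile that is not actually a ground state
    if max(energies) - e_min > 1e-9 * max(1.0, abs(e_min)):
        raise ValueError("ground-state orbit members do not share one energy")
    return orbit


def _search_ground_tile(spec: TextureSetSpec, max_period: int) -> Lattice:
    """Exhaustive minimum-energy search over small periodic tiles."""
    H, W = spec.lattice_shape
    best: tuple[float, Lattice] | None = None
    for th in range(1, max_period + 1):
        if H % th:
            continue
        for tw in range(1, max_period + 1):
            if W % tw:
                continue
            for assignment in itertools.product(range(spec.n_states), repeat=th * tw):
                tile = np.asarray(assignment, dtype=np.int64).reshape(th, tw)
                e = energy(np.tile(tile, (H // th, W // tw)), spec)
                if best is None or e < best[0] - 1e-12:
                    best = (e, tile)
    assert best is not None
    return best[1]


def minimal_tiling_energy(spec: TextureSetSpec, max_period: int = 2) -> float:
    """Minimum full-lattice energy over all periodic tilings of period up
    to ``max_period`` in each axis (an independent check that a spec's
    declared ground state really is minimal among small-period patterns)."""
    tile = _search_ground_tile(spec, max_period)
    H, W = spec.lattice_shape
    th, tw = tile.shape
    return energy(np.tile(tile, (H // th, W // tw)), spec)


def _allowed_joints(spec: TextureSetSpec, orbit: list[Lattice]) -> np.ndarray:
    """Boolean table of conforming joint states per offset and site.

    Shape ``(n_offsets, H, W, S, S)``: entry ``[i, p, q, s, t]`` is True when
    some orbit member has state ``s`` at ``(p, q)`` and state ``t`` at the
    partner site ``(p, q) + offsets[i]``.
    """
    H, W = spec.lattice_shape
    S = spec.n_states
    allowed = np.zeros((len(spec.offsets), H, W, S, S), dtype=bool)
    rows, cols = np.indices((H, W))
    for T in orbit:
        for i, (dy, dx) in enumerate(spec.offsets):
            partner = np.roll(T, shift=(-dy, -dx), axis=(0, 1))
            allowed[i, rows, cols, T, partner] = True
    return allowed


def order_field(
    config: Lattice,
    spec: TextureSetSpec,
    orbit: list[Lattice] | None = None,
) -> np.ndarray:
    """Local conformance field in [0, 1].

    ``field[p, q]`` is the fraction of the site's incident interacting
    pairs — the site with its partner at each offset and each negated
    offset — whose joint state matches the corresponding joint state of
    some ground-state orbit member.  Shifting the configuration cyclically
    shifts the field (for translation-closed orbits).
    """
    config = validate_lattice(config, spec)
    if orbit is None:
        orbit = ground_state_orbit(spec)
    allowed = _allowed_joints(spec, orbit)
    H, W = spec.lattice_shape
    rows, cols = np.indices((H, W))
    n_pairs = 2 * len(spec.offsets)
    conf = np.zeros((H, W), dtype=float)
    for i, (dy, dx) in enumerate(spec.offsets):
        partner = np.roll(config, shift=(-dy, -dx), axis=(0, 1))
        match_fwd = allowed[i, rows, cols, config, partner]
        # the pair seen from the partner side: shift the indicator back
        match_bwd = np.roll(match_fwd, shift=(dy, dx), axis=(0, 1))
        conf += match_fwd
        conf += match_bwd
    return conf / n_pairs


def uniform_baseline(spec: TextureSetSpec, orbit: list[Lattice] | None = None) -> float:
    """Exact expected order parameter under i.i.d. uniform states.

    Each pair slot conforms independently with probability
    (number of allowed joints at that slot) / n_states**2, so the expected
    mean field is the average of that probability over all slots.
    """
    if orbit is None:
        orbit = ground_state_orbit(spec)
    allowed = _allowed_joints(spec, orbit)
    # fraction of allowed joints per slot, averaged over offsets and sites
    return float(allowed.mean(axis=(3, 4)).mean())


def order_parameter(
    config: Lattice,
    spec: TextureSetSpec,
    orbit: list[Lattice] | None = None,
) -> OrderStatistic:
    """Order parameter (mean conformance) of a configuration."""
    if orbit is None:
        orbit = ground_state_orbit(spec)
    field = order_field(config, spec, orbit)
    return OrderStatistic(
        value=float(field.mean()),
        baseline=uniform_baseline(spec, orbit),
        field=field,
    )
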