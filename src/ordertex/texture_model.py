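"""Markov random field texture sets and their Boltzmann energy.

A texture set is a shift-invariant pairwise Markov random field on a cyclic
(toroidal) lattice of discrete amplitude indices.  A lattice configuration
``I`` is an ``H x W`` integer matrix with entries in ``[0, n_states)``; each
entry indexes the amplitude of one Gaussian blob in the rendered stimulus.
The set is defined by a list of interaction offsets ``(dy, dx)`` and, per
offset, an ``n_states x n_states`` potential matrix ``U_o``.  The global
energy is

    U(I) = sum over sites (p, q) and offsets o of U_o(I[p, q], I[(p, q) + o])

with cyclic wrapping, and equilibrium configurations follow the Boltzmann
distribution P(I) = exp(-beta U(I)) / Z at inverse temperature beta.

Conventions (fixed so that offsets are unambiguous):

* coordinates are (row, col), 0-based, row increases downward;
* wrapping is modular in both axes;
* each unordered interacting pair is counted exactly once, so the offset
  list may not contain both an offset and its negation.

Lattice configurations are plain ``numpy`` integer arrays; helpers below
validate them against their owning spec.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Lattice",
    "SpecValidationError",
    "TextureSetSpec",
    "validate_spec",
    "validate_lattice",
    "energy",
    "random_lattice",
    "builtin_specs",
    "get_builtin",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
]

#: A lattice configuration: 2-D integer array of amplitude indices.
Lattice = np.ndarray

# Shared default beta grid for the builtin sets.  The ferromagnetic coupling
# strength of all builtin potentials is 1, which puts the order-disorder
# transition near beta ~ 1 (log(1 + sqrt(3)) for the 3-state Potts set), so
# the grid spans the disordered limit through the ordered phase.
DEFAULT_BETA_GRID = (0.0, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0)


class SpecValidationError(ValueError):
    """A texture-set specification violates one of its invariants."""


@dataclass(frozen=True)
class TextureSetSpec:
    """Definition of one texture set.

    Parameters
    ----------
    name:
        Identifier used in file names and manifests.
    n_states:
        Size of the amplitude alphabet (3 for blob stimuli).
    offsets:
        Interaction displacements ``(dy, dx)``; one unordered pair each
        (never both an offset and its negation).
    potentials:
        One ``n_states x n_states`` energy matrix per offset, same order.
        ``potentials[i][s, t]`` is the energy of a site in state ``s`` whose
        partner at ``offsets[i]`` is in state ``t``.
    lattice_shape:
        ``(H, W)`` of generated configurations.
    beta_grid:
        Strictly increasing non-negative inverse temperatures at which the
        set is studied.
    ground_state_tile:
        Optional small periodic matrix of state indices whose tiling is a
        canonical minimum-energy configuration.
    """

    name: str
    n_states: int
    offsets: tuple[tuple[int, int], ...]
    potentials: tuple[np.ndarray, ...]
    lattice_shape: tuple[int, int] = (32, 32)
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    ground_state_tile: np.ndarray | None = None

    def __post_init__(self) -> None:
        # normalise containers so frozen instances hash/compare predictably
        object.__setattr__(self, "offsets", tuple((int(dy), int(dx)) for dy, dx in self.offsets))
        object.__setattr__(
            self, "potentials", tuple(np.asarray(U, dtype=float) for U in self.potentials)
        )
        object.__setattr__(self, "lattice_shape", tuple(int(x) for x in self.lattice_shape))
        object.__setattr__(self, "beta_grid", tuple(float(b) for b in self.beta_grid))
        if self.ground_state_tile is not None:
            object.__setattr__(
                self, "ground_state_tile", np.asarray(self.ground_state_tile, dtype=np.int64)
            )

    def with_shape(self, shape: tuple[int, int]) -> "TextureSetSpec":
        """Return a copy of the spec on a different lattice shape."""
        return validate_spec(replace(self, lattice_shape=tuple(shape)))


def validate_spec(spec: TextureSetSpec) -> TextureSetSpec:
    """Check every TextureSetSpec invariant; return the spec unchanged.

    Raises
    ------
    SpecValidationError
        Describing the first violated invariant.
    """
    if spec.n_states < 2:
        raise SpecValidationError(f"n_states must be >= 2, got {spec.n_states}")
    H, W = spec.lattice_shape
    if H <= 0 or W <= 0:
        raise SpecValidationError(f"lattice dimensions must be positive, got {(H, W)}")
    if len(spec.offsets) == 0:
        raise SpecValidationError("at least one interaction offset is required")
    if len(spec.potentials) != len(spec.offsets):
        raise SpecValidationError(
            f"{len(spec.offsets)} offsets but {len(spec.potentials)} potential matrices"
        )
    seen: set[tuple[int, int]] = set()
    for off in spec.offsets:
        if off == (0, 0):
            raise SpecValidationError("offset (0, 0) is not a valid interaction")
        if off in seen:
            raise SpecValidationError(f"duplicate offset {off}")
        neg = (-off[0], -off[1])
        if neg in seen:
            raise SpecValidationError(
                f"offset and its negation both present: {neg} and {off} "
                "(each unordered pair is counted once)"
            )
        seen.add(off)
    for off, U in zip(spec.offsets, spec.potentials):
        if U.shape != (spec.n_states, spec.n_states):
            raise SpecValidationError(
                f"potential for offset {off} has shape {U.shape}, "
                f"expected {(spec.n_states, spec.n_states)}"
            )
        if not np.all(np.isfinite(U)):
            raise SpecValidationError(f"potential for offset {off} contains non-finite values")
    betas = np.asarray(spec.beta_grid, dtype=float)
    if betas.size == 0:
        raise SpecValidationError("beta_grid is empty")
    if np.any(betas < 0):
        raise SpecValidationError("beta_grid contains negative values")
    if betas.size > 1 and not np.all(np.diff(betas) > 0):
        raise SpecValidationError("beta_grid must be strictly increasing")
    tile = spec.ground_state_tile
    if tile is not None:
        if tile.ndim != 2:
            raise SpecValidationError("ground_state_tile must be a 2-D matrix")
        th, tw = tile.shape
        if H % th or W % tw:
            raise SpecValidationError(
                f"ground_state_tile shape {tile.shape} does not divide lattice {(H, W)}"
            )
        if tile.min() < 0 or tile.max() >= spec.n_states:
            raise SpecValidationError("ground_state_tile entries out of state range")
    return spec


def validate_lattice(states: Lattice, spec: TextureSetSpec) -> Lattice:
    """Check that a configuration matches its spec (shape and state range)."""
    states = np.asarray(states)
    if states.shape != tuple(spec.lattice_shape):
        raise ValueError(
            f"lattice shape {states.shape} does not match spec shape {spec.lattice_shape}"
        )
    if not np.issubdtype(states.dtype, np.integer):
        raise ValueError(f"lattice must be integer-valued, got dtype {states.dtype}")
    if states.size and (states.min() < 0 or states.max() >= spec.n_states):
        raise ValueError("lattice entries out of state range")
    return states


def energy(states: Lattice, spec: TextureSetSpec) -> float:
    """Total energy U(I) of a configuration under the spec's potentials.

    Sums, over every site and every offset, the pair potential between the
    site and its cyclically wrapped partner.  Independent of beta, and
    invariant under cyclic translation of the configuration.
    """
    states = validate_lattice(states, spec)
    total = 0.0
    for (dy, dx), U in zip(spec.offsets, spec.potentials):
        partner = np.roll(states, shift=(-dy, -dx), axis=(0, 1))
        total += float(U[states, partner].sum())
    return total


def energy_batch(states: np.ndarray, spec: TextureSetSpec) -> np.ndarray:
    """Energies of a stack of configurations, shape ``(n, H, W) -> (n,)``."""
    states = np.asarray(states)
    out = np.zeros(states.shape[0], dtype=float)
    for (dy, dx), U in zip(spec.offsets, spec.potentials):
        partner = np.roll(states, shift=(-dy, -dx), axis=(1, 2))
        out += U[states, partner].sum(axis=(1, 2))
    return out


def random_lattice(spec: TextureSetSpec, rng: np.random.Generator) -> Lattice:
    """An i.i.d. uniform configuration (the beta -> 0 limit)."""
    return rng.integers(0, spec.n_states, size=spec.lattice_shape, dtype=np.int64)


# ---------------------------------------------------------------------------
# Builtin example sets
# ---------------------------------------------------------------------------

def _match_potential(n: int) -> np.ndarray:
    """-1 for equal states, 0 otherwise (ferromagnetic Potts coupling)."""
    return -np.eye(n)


def _pair_potential(n: int, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """-1 for each listed ordered state pair, 0 otherwise."""
    U = np.zeros((n, n))
    for s, t in pairs:
        U[s, t] = -1.0
    return U


def builtin_specs() -> list[TextureSetSpec]:
    """Canonical example texture sets, each with a known ground-state tile.

    * ``potts`` — 3-state ferromagnetic Potts model: nearest-neighbour
      matching is favoured, so the ordered phase is a uniform field (the
      blob field of constant amplitude).
    * ``checkerboard`` — antiferromagnetic coupling between states 0 and 2:
      the ordered phase is a period-2 checkerboard of low and high
      amplitudes.
    * ``stripes`` — anisotropic set: horizontal neighbours prefer to
      alternate between states 0 and 1, vertical neighbours prefer to
      match, giving vertical stripes as the ordered phase.
    """
    n = 3
    nn = ((0, 1), (1, 0))
    potts = TextureSetSpec(
        name="potts",
        n_states=n,
        offsets=nn,
        potentials=(_match_potential(n), _match_potential(n)),
        ground_state_tile=np.array([[0]]),
    )
    checkerboard = TextureSetSpec(
        name="checkerboard",
        n_states=n,
        offsets=nn,
        potentials=(
            _pair_potential(n, [(0, 2), (2, 0)]),
            _pair_potential(n, [(0, 2), (2, 0)]),
        ),
        ground_state_tile=np.array([[0, 2], [2, 0]]),
    )
    stripes = TextureSetSpec(
        name="stripes",
        n_states=n,
        offsets=nn,
        potentials=(
            _pair_potential(n, [(0, 1), (1, 0)]),  # horizontal: alternate 0/1
            _match_potential(n),                   # vertical: match
        ),
        ground_state_tile=np.array([[0, 1]]),
    )
    return [validate_spec(s) for s in (potts, checkerboard, stripes)]


def get_builtin(name: str) -> TextureSetSpec:
    """Look up a builtin spec by name."""
    for spec in builtin_specs():
        if spec.name == name:
            return spec
    names = ", ".join(s.name for s in builtin_specs())
    raise KeyError(f"no builtin texture set named {name!r}; available: {names}")


# ---------------------------------------------------------------------------
# Config file round-trip (YAML or JSON by extension)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: TextureSetSpec) -> dict:
    d = {
        "name": spec.name,
        "n_states": spec.n_states,
        "lattice_shape": list(spec.lattice_shape),
        "offsets": [list(o) for o in spec.offsets],
        "potentials": [U.tolist() for U in spec.potentials],
        "beta_grid": list(spec.beta_grid),
    }
    if spec.ground_state_tile is not None:
        d["ground_state_tile"] = spec.ground_state_tile.tolist()
    return d


def spec_from_dict(d: dict) -> TextureSetSpec:
    tile = d.get("ground_state_tile")
    spec = TextureSetSpec(
        name=d["name"],
        n_states=int(d["n_states"]),
        offsets=tuple(tuple(o) for o in d["offsets"]),
        potentials=tuple(np.asarray(U, dtype=float) for U in d["potentials"]),
        lattice_shape=tuple(d.get("lattice_shape", (32, 32))),
        beta_grid=tuple(d.get("beta_grid", DEFAULT_BETA_GRID)),
        ground_state_tile=None if tile is None else np.asarray(tile),
    )
    return validate_spec(spec)


def save_spec(spec: TextureSetSpec, path: str | Path) -> None:
    """Write a spec to a YAML (.yaml/.yml) or JSON (.json) config file."""
    path = Path(path)
    d = spec_to_dict(spec)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")


def load_spec(path: str | Path) -> TextureSetSpec:
    """Read and validate a spec from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        d = yaml.safe_load(text)
    elif path.suffix == ".json":
        d = json.loads(text)
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")
    return spec_from_dict(d)


def state_permutations_preserving(spec: TextureSetSpec) -> list[tuple[int, ...]]:
    """State relabelings that leave every potential matrix invariant.

    A permutation pi preserves the energy function iff conjugating each
    potential by pi reproduces it: U[pi(s), pi(t)] == U[s, t] for all s, t.
    """
    out = []
    for perm in itertools.permutations(range(spec.n_states)):
        p = np.asarray(perm)
        if all(np.allclose(U[np.ix_(p, p)], U) for U in spec.potentials):
            out.append(perm)
    return out
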