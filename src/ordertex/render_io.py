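"""Rendering of amplitude lattices as Gaussian-blob luminance images, and
file I/O for stimuli, sample archives and trial manifests.

A lattice is rendered as an ``H x W`` grid of circularly symmetric Gaussian
blobs added to a uniform background.  Geometry defaults follow the
constant-stimuli display: blob envelope sigma 1.5 arcmin, quadrant textures
4.84 degrees on a side (so 32 blobs span 4.84 deg), amplitudes mapped to
three luminances (26, 56, 91 cd/m^2) on a 14 cd/m^2 background, and a
pixel scale of 120 px/deg so that sigma = 3 px renders faithfully.

Images are kept as floating-point luminance arrays; 8-bit PNG export uses
explicit max scaling.  Gamma and monitor calibration are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .texture_model import Lattice, TextureSetSpec, validate_lattice

__all__ = [
    "RenderSpec",
    "render_texture",
    "compose_display",
    "quadrant_slices",
    "save_image_png",
    "save_image_tiff",
    "save_samples",
    "load_samples",
    "render_spec_to_dict",
    "render_spec_from_dict",
]

ARCMIN = 1.0 / 60.0  # degrees


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and photometry of the rendered stimulus.

    Units: ``blob_sigma`` in arcmin, ``blob_spacing`` in degrees between
    blob centers, luminances in cd/m^2, ``pixel_scale`` in pixels/degree.
    """

    blob_sigma: float = 1.5
    blob_spacing: float = 4.84 / 32
    amplitude_map: tuple[float, ...] = (26.0, 56.0, 91.0)
    background: float = 14.0
    pixel_scale: float = 120.0
    layout: str = "attached"  # or "gapped"
    eccentricity: float = 4.0  # degrees, gapped layout only

    def __post_init__(self) -> None:
        if self.blob_sigma <= 0 or self.blob_spacing <= 0 or self.pixel_scale <= 0:
            raise ValueError("blob_sigma, blob_spacing and pixel_scale must be positive")
        amps = tuple(float(a) for a in self.amplitude_map)
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitude_map must be strictly increasing")
        object.__setattr__(self, "amplitude_map", amps)
        if self.layout not in {"attached", "gapped"}:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.sigma_px < 2.0:
            raise ValueError(
                f"pixel_scale {self.pixel_scale} too coarse: blob sigma renders as "
                f"{self.sigma_px:.2f} px (< 2 px)"
            )

    @property
    def sigma_px(self) -> float:
        return self.blob_sigma * ARCMIN * self.pixel_scale

    @property
    def spacing_px(self) -> float:
        return self.blob_spacing * self.pixel_scale


def _blob_kernel(sigma_px: float) -> np.ndarray:
    """Unit-peak Gaussian kernel truncated at +-3 sigma."""
    r = int(np.ceil(3 * sigma_px))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    return np.exp(-(x**2 + y**2) / (2 * sigma_px**2))


def render_texture(config: Lattice, spec: TextureSetSpec, r: RenderSpec) -> np.ndarray:
    """Render a lattice as a luminance image.

    Blobs sit at grid centers ``((i + 0.5) s, (j + 0.5) s)`` with
    ``s = blob_spacing * pixel_scale``; each adds a Gaussian of peak
    luminance ``amplitude_map[state]`` to the uniform background.  The
    image side is ``round(H * s)`` pixels.  Deterministic.
    """
    config = validate_lattice(config, spec)
    if len(r.amplitude_map) < spec.n_states:
        raise ValueError("amplitude_map shorter than the state alphabet")
    H, W = config.shape
    s = r.spacing_px
    h_px, w_px = int(round(H * s)), int(round(W * s))
    deltas = np.zeros((h_px, w_px))
    rows = np.clip(np.round((np.arange(H) + 0.5) * s - 0.5).astype(int), 0, h_px - 1)
    cols = np.clip(np.round((np.arange(W) + 0.5) * s - 0.5).astype(int), 0, w_px - 1)
    amps = np.asarray(r.amplitude_map)[config]
    np.add.at(deltas, (rows[:, None], cols[None, :]), amps)
    kernel = _blob_kernel(r.sigma_px)
    image = signal.fftconvolve(deltas, kernel, mode="same")
    return image + r.background


def quadrant_slices(h: int, w: int) -> list[tuple[slice, slice]]:
    """Pixel slices of the four quadrants: 0=UL, 1=UR, 2=LL, 3=LR."""
    return [
        (slice(0, h // 2), slice(0, w // 2)),
        (slice(0, h // 2), slice(w // 2, w)),
        (slice(h // 2, h), slice(0, w // 2)),
        (slice(h // 2, h), slice(w // 2, w)),
    ]


def compose_display(
    target_img: np.ndarray,
    distractor_imgs: list[np.ndarray],
    r: RenderSpec,
    target_quadrant: int,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Place the target and three distractors in the four quadrants.

    ``attached`` layout tiles the four images into a 2x2 block with no gap
    (a 64x64 blob grid for 32x32 inputs); ``gapped`` layout centers each
    quadrant image at the configured eccentricity from fixation on a
    uniform background.  Returns the display image and a manifest recording
    the target quadrant.
    """
    if len(distractor_imgs) != 3:
        raise ValueError("exactly 3 distractor images required")
    if not 0 <= target_quadrant < 4:
        raise ValueError(f"target quadrant {target_quadrant} out of range")
    shapes = {img.shape for img in [target_img, *distractor_imgs]}
    if len(shapes) != 1:
        raise ValueError(f"quadrant images differ in size: {shapes}")
    h, w = target_img.shape
    imgs: list[np.ndarray | None] = [None] * 4
    imgs[target_quadrant] = target_img
    di = iter(distractor_imgs)
    for q in range(4):
        if imgs[q] is None:
            imgs[q] = next(di)

    if r.layout == "attached":
        display = np.empty((2 * h, 2 * w))
        for q, (sy, sx) in enumerate(quadrant_slices(2 * h, 2 * w)):
            display[sy, sx] = imgs[q]
    else:
        ecc_px = int(round(r.eccentricity * r.pixel_scale))
        half = int(np.ceil(ecc_px / np.sqrt(2) + max(h, w) / 2)) + 1
        side = 2 * half
        display = np.full((side, side), r.background)
        off = int(round(ecc_px / np.sqrt(2)))
        centers = {
            0: (half - off, half - off),
            1: (half - off, half + off),
            2: (half + off, half - off),
            3: (half + off, half + off),
        }
        for q in range(4):
            cy, cx = centers[q]
            y0, x0 = cy - h // 2, cx - w // 2
            display[y0 : y0 + h, x0 : x0 + w] = imgs[q]

    manifest = {
        "layout": r.layout,
        "target_quadrant": int(target_quadrant),
        "quadrant_shape": [int(h), int(w)],
        "seed": seed,
    }
    return display, manifest


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def save_image_png(image: np.ndarray, path: str | Path, max_luminance: float | None = None) -> None:
    """8-bit PNG export with explicit max scaling."""
    from PIL import Image

    peak = float(image.max()) if max_luminance is None else float(max_luminance)
    scaled = np.clip(image / max(peak, 1e-12), 0.0, 1.0)
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(str(path))


def save_image_tiff(image: np.ndarray, path: str | Path) -> None:
    """Floating-point TIFF export (lossless luminance)."""
    import tifffile

    tifffile.imwrite(str(path), image.astype(np.float32))


def save_samples(
    samples: np.ndarray,
    path: str | Path,
    spec: TextureSetSpec,
    beta: float,
    seed: int,
    n_sweeps: int | None = None,
) -> None:
    """Write a sample archive: compressed integer lattices plus a JSON
    sidecar with the provenance needed to regenerate them."""
    path = Path(path)
    np.savez_compressed(path, samples=np.asarray(samples, dtype=np.int8))
    sidecar = {
        "spec_name": spec.name,
        "beta": float(beta),
        "seed": int(seed),
        "n_samples": int(np.asarray(samples).shape[0]),
        "lattice_shape": list(spec.lattice_shape),
        "n_sweeps": n_sweeps,
    }
    sidecar_path = path.with_suffix(".json") if path.suffix == ".npz" else Path(str(path) + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def load_samples(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a sample archive and its sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        samples = data["samples"].astype(np.int64)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return samples, meta


def render_spec_to_dict(r: RenderSpec) -> dict:
    return {
        "blob_sigma": r.blob_sigma,
        "blob_spacing": r.blob_spacing,
        "amplitude_map": list(r.amplitude_map),
        "background": r.background,
        "pixel_scale": r.pixel_scale,
        "layout": r.layout,
        "eccentricity": r.eccentricity,
    }


def render_spec_from_dict(d: dict) -> RenderSpec:
    return RenderSpec(
        blob_sigma=float(d.get("blob_sigma", 1.5)),
        blob_spacing=float(d.get("blob_spacing", 4.84 / 32)),
        amplitude_map=tuple(d.get("amplitude_map", (26.0, 56.0, 91.0))),
        background=float(d.get("background", 14.0)),
        pixel_scale=float(d.get("pixel_scale", 120.0)),
        layout=d.get("layout", "attached"),
        eccentricity=float(d.get("eccentricity", 4.0)),
    )
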