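"""Stochastic object models: lumpy backgrounds, a stylized brain phantom, and
Gaussian signals.

These generators play the role of a stochastic object model (SOM) for binary
signal-detection studies: they produce random background objects ``f_b`` and a
small Gaussian signal ``f_s`` whose presence the observer must detect.  The
stylized brain carries a tissue mask that restricts where the signal may be
placed, emulating lesions confined to white matter.

All generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter


__all__ = [
    "ObjectImage",
    "SignalModel",
    "LumpyParams",
    "HypothesisPair",
    "sample_lumpy_background",
    "make_stylized_brain",
    "render_gaussian_signal",
    "sample_signal_location",
    "compose_hypothesis_pair",
    "central_mask",
]


@dataclass
class ObjectImage:
    """A real-valued 2-D object on a pixel grid with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Object intensity (arbitrary units).
    pixel_size_mm : float
        Physical side length of one pixel in millimetres.
    tissue_mask : ndarray of bool, optional
        Signal-placement region, same shape as ``pixels``.
    """

    pixels: np.ndarray
    pixel_size_mm: float = 1.0
    tissue_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be positive")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.pixels.shape:
                raise ValueError("tissue_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SignalModel:
    """An isotropic Gaussian signal: amplitude, width in mm, pixel center."""

    amplitude: float
    sigma_mm: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.sigma_mm > 0):
            raise ValueError("sigma_mm must be positive")
        if not np.all(np.isfinite([self.amplitude, self.sigma_mm, *self.center])):
            raise ValueError("signal parameters must be finite")


@dataclass
class LumpyParams:
    """Parameters of the lumpy-background object model.

    The background is ``dc_offset`` plus a Poisson number of Gaussian lumps
    with continuous-uniform centers over the grid.  Lumps near the border are
    truncated at the grid edge (no wraparound).
    """

    mean_lump_count: float = 60.0
    lump_amplitude: float = 8.0
    lump_sigma_mm: float = 4.0
    shape: tuple[int, int] = (64, 64)
    dc_offset: float = 30.0
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.mean_lump_count, self.lump_amplitude, self.lump_sigma_mm,
                self.dc_offset, self.pixel_size_mm]
        if not np.all(np.isfinite(vals)):
            raise ValueError("lumpy parameters must be finite")
        if self.mean_lump_count < 0:
            raise ValueError("mean_lump_count must be >= 0")
        if not (self.lump_sigma_mm > 0):
            raise ValueError("lump_sigma_mm must be positive")


@dataclass
class HypothesisPair:
    """Signal-absent (H0) and signal-present (H1) objects sharing a background."""

    f_h0: ObjectImage
    f_h1: ObjectImage
    signal: SignalModel


def sample_lumpy_background(params: LumpyParams, seed: int) -> ObjectImage:
    """Draw one realization of the lumpy background model.

    The number of lumps is Poisson(``mean_lump_count``); each lump is an
    isotropic Gaussian of amplitude ``lump_amplitude`` and width
    ``lump_sigma_mm`` centered uniformly over the grid (continuous
    coordinates).  Identical seeds give bitwise-identical images.
    """
    rng = np.random.default_rng(seed)
    H, W = params.shape
    sigma_px = params.lump_sigma_mm / params.pixel_size_mm
    img = np.full((H, W), float(params.dc_offset))
    n_lumps = rng.poisson(params.mean_lump_count)
    rows = np.arange(H, dtype=float)
    cols = np.arange(W, dtype=float)
    for _ in range(n_lumps):
        cy = rng.uniform(0.0, H)
        cx = rng.uniform(0.0, W)
        gy = np.exp(-((rows - cy) ** 2) / (2.0 * sigma_px**2))
        gx = np.exp(-((cols - cx) ** 2) / (2.0 * sigma_px**2))
        img += params.lump_amplitude * np.outer(gy, gx)
    mask = central_mask((H, W), fraction=0.5)
    return ObjectImage(img, pixel_size_mm=params.pixel_size_mm, tissue_mask=mask)


def central_mask(shape: tuple[int, int], fraction: float = 0.5) -> np.ndarray:
    """Boolean mask covering the central ``fraction`` of each axis."""
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    h0 = int(round(H * (1 - fraction) / 2))
    w0 = int(round(W * (1 - fraction) / 2))
    mask[h0:H - h0, w0:W - w0] = True
    return mask


def _ellipse(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
             ry: float, rx: float, angle: float = 0.0) -> np.ndarray:
    """Boolean inside-ellipse indicator on coordinate grids."""
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def make_stylized_brain(shape: tuple[int, int] = (64, 64), seed: int = 0,
                        pixel_size_mm: float = 1.0,
                        intensity: float = 60.0) -> ObjectImage:
    """Generate a piecewise-smooth stylized head phantom with a tissue mask.

    The phantom consists of an outer head ellipse, a cortical rim, a
    white-matter interior, ventricle-like dark cavities near the midline and a
    few randomized internal structures.  The tissue mask marks the
    white-matter region (signal-placement region) and is always nonempty.
    Geometry is randomized per seed so distinct seeds give distinct phantoms.
    """
    H, W = shape
    if H < 32 or W < 32:
        raise ValueError("shape must be at least 32x32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = (H - 1) / 2 + rng.uniform(-1, 1), (W - 1) / 2 + rng.uniform(-1, 1)
    ry = 0.42 * H * rng.uniform(0.95, 1.05)
    rx = 0.36 * W * rng.uniform(0.95, 1.05)

    head = _ellipse(yy, xx, cy, cx, ry, rx)
    cortex = _ellipse(yy, xx, cy, cx, 0.92 * ry, 0.90 * rx)
    white = _ellipse(yy, xx, cy, cx, 0.78 * ry, 0.74 * rx)

    img = np.zeros((H, W))
    img[head] = 0.35          # scalp / CSF rim
    img[cortex] = 0.85        # gray matter
    img[white] = 0.65         # white matter

    # ventricles: two elongated dark cavities flanking the midline
    vent = np.zeros((H, W), dtype=bool)
    for side in (-1.0, 1.0):
        vc = cx + side * 0.10 * W * rng.uniform(0.8, 1.2)
        vent |= _ellipse(yy, xx, cy + rng.uniform(-1, 1), vc,
                         0.22 * ry * rng.uniform(0.8, 1.2),
                         0.10 * rx * rng.uniform(0.8, 1.2),
                         angle=side * rng.uniform(0.0, 0.3))
    img[vent & white] = 0.20

    # a few randomized internal structures (subcortical nuclei analogs)
    n_struct = rng.integers(2, 5)
    blob = np.zeros((H, W), dtype=bool)
    for _ in range(n_struct):
        bc_y = cy + rng.uniform(-0.4, 0.4) * ry
        bc_x = cx + rng.uniform(-0.4, 0.4) * rx
        b = _ellipse(yy, xx, bc_y, bc_x,
                     rng.uniform(0.05, 0.12) * ry,
                     rng.uniform(0.05, 0.12) * rx,
                     angle=rng.uniform(0, np.pi))
        blob |= b & white
        img[b & white] = rng.uniform(0.5, 0.8)

    img = gaussian_filter(img, sigma=0.8) * intensity

    tissue = white & ~vent & ~blob
    # keep the mask away from region borders so a 2 px signal stays in tissue
    interior = _ellipse(yy, xx, cy, cx, 0.70 * ry, 0.66 * rx)
    tissue &= interior
    if not tissue.any():  # pragma: no cover - geometry always leaves tissue
        tissue = central_mask((H, W), fraction=0.25)
    return ObjectImage(img, pixel_size_mm=pixel_size_mm, tissue_mask=tissue)


def render_gaussian_signal(signal: SignalModel, pixel_size_mm: float,
                           shape: tuple[int, int]) -> ObjectImage:
    """Render the Gaussian signal onto a pixel grid.

    ``pixels(r) = amplitude * exp(-||r - center||^2 / (2 sigma_px^2))`` with
    ``sigma_px = sigma_mm / pixel_size_mm``.  Signals narrower than half a
    pixel are rejected as unrepresentable on the grid.
    """
    H, W = shape
    sigma_px = signal.sigma_mm / pixel_size_mm
    if sigma_px < 0.5:
        raise ValueError(
            f"signal sigma {sigma_px:.3f} px is sub-pixel (< 0.5 px)")
    r0, c0 = signal.center
    if not (0 <= r0 <= H - 1 and 0 <= c0 <= W - 1):
        raise ValueError("signal center outside the grid")
    rows = np.arange(H, dtype=float)
    cols = np.arange(W, dtype=float)
    gy = np.exp(-((rows - r0) ** 2) / (2.0 * sigma_px**2))
    gx = np.exp(-((cols - c0) ** 2) / (2.0 * sigma_px**2))
    return ObjectImage(signal.amplitude * np.outer(gy, gx),
                       pixel_size_mm=pixel_size_mm)


def sample_signal_location(mask: np.ndarray, seed: int) -> tuple[int, int]:
    """Draw a signal center uniformly over the true pixels of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("mask has no true pixels")
    rng = np.random.default_rng(seed)
    flat = idx[rng.integers(idx.size)]
    return np.unravel_index(flat, mask.shape)


def compose_hypothesis_pair(background: ObjectImage,
                            signal: SignalModel) -> HypothesisPair:
    """Build the H0/H1 object pair: H0 is the background, H1 adds the signal."""
    rendered = render_gaussian_signal(signal, background.pixel_size_mm,
                                      background.shape)
    f_h1 = ObjectImage(background.pixels + rendered.pixels,
                       pixel_size_mm=background.pixel_size_mm,
                       tissue_mask=background.tissue_mask)
    return HypothesisPair(f_h0=background, f_h1=f_h1, signal=signal)
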