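"""Multi-coil SENSE acquisition model.

Each of C receive coils measures the 2-D discrete Fourier transform of the
object weighted by its complex sensitivity map, restricted to a Cartesian set
of phase-encode lines and corrupted by complex Gaussian noise:

    g_i = Phi F S_i f + n_i,   i = 1..C

Conventions
-----------
* The DFT is unitary and DC-centered: ``F = fftshift . fft2(norm='ortho') .
  ifftshift`` so Parseval holds exactly and k-space index (H//2, W//2) is DC.
* Undersampling removes whole rows (phase-encode lines, axis -2); the readout
  direction is always fully sampled, matching Cartesian SENSE practice.
* Noise of standard deviation ``sigma`` is added independently to the real
  and imaginary part of every *sampled* entry; unsampled lines are exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantoms import ObjectImage

__all__ = [
    "CoilEnsemble",
    "SamplingMask",
    "NoiseModel",
    "KspaceData",
    "simulate_coil_maps",
    "make_cartesian_mask",
    "forward",
    "adjoint",
    "add_noise",
    "fft2c",
    "ifft2c",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary DC-centered 2-D DFT over the trailing two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


@dataclass
class CoilEnsemble:
    """Complex coil-sensitivity maps, shape (C, H, W)."""

    maps: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 3:
            raise ValueError("maps must have shape (C, H, W)")
        if not np.all(np.isfinite(self.maps.view(float))):
            raise ValueError("coil maps must be finite")
        if self.normalized:
            sos = np.sum(np.abs(self.maps) ** 2, axis=0)
            if np.max(np.abs(sos - 1.0)) > 1e-6:
                raise ValueError("normalized ensemble must have sum |S_i|^2 = 1")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class SamplingMask:
    """Cartesian phase-encode line selector.

    ``line_selector[j]`` is True when row ``j`` of the DC-centered k-space
    grid is acquired.  ``acceleration`` records the nominal factor R.
    """

    line_selector: np.ndarray
    acceleration: float
    offset: int = 0
    center_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.line_selector = np.asarray(self.line_selector, dtype=bool)
        if self.line_selector.ndim != 1:
            raise ValueError("line_selector must be 1-D")
        if not self.line_selector.any():
            raise ValueError("at least one line must be selected")
        if not (0 <= self.center_fraction < 1):
            raise ValueError("center_fraction must be in [0, 1)")

    @property
    def n_lines(self) -> int:
        return self.line_selector.size

    @property
    def n_selected(self) -> int:
        return int(self.line_selector.sum())

    def as_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (H, W) mask broadcasting the line selector over columns."""
        H, W = shape
        if H != self.n_lines:
            raise ValueError("mask length does not match grid rows")
        return np.repeat(self.line_selector[:, None], W, axis=1)


@dataclass
class NoiseModel:
    """IID complex Gaussian noise; ``sigma`` is the std per real/imag
    component, per coil, per k-space sample (default 15)."""

    sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class KspaceData:
    """Measured multi-coil k-space with its sampling mask and provenance."""

    samples: np.ndarray
    mask: SamplingMask
    hypothesis_label: str = "unknown"
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 3:
            raise ValueError("samples must have shape (C, H, W)")
        if self.samples.shape[1] != self.mask.n_lines:
            raise ValueError("samples row count must match mask length")
        if np.any(self.samples[:, ~self.mask.line_selector, :] != 0):
            raise ValueError("unselected lines must be exactly zero")
        if self.hypothesis_label not in ("H0", "H1", "unknown"):
            raise ValueError("hypothesis_label must be H0, H1 or unknown")

    @property
    def coil_count(self) -> int:
        return self.samples.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape[1:]


def _coil_profile(yy: np.ndarray, xx: np.ndarray, center: tuple[float, float],
                  profile_sigma: float, phase_per_px: float) -> np.ndarray:
    """Complex sensitivity of one coil: Gaussian magnitude falloff from the
    coil center with phase linear in distance."""
    d = np.hypot(yy - center[0], xx - center[1])
    return np.exp(-(d**2) / (2.0 * profile_sigma**2)) * np.exp(
        1j * phase_per_px * d)


def simulate_coil_maps(n_coils: int = 8, shape: tuple[int, int] = (64, 64),
                       profile_sigma_mm: Optional[float] = None,
                       normalize: bool = True,
                       pixel_size_mm: float = 1.0,
                       phase_per_mm: float = 0.05) -> CoilEnsemble:
    """Simulate a circular array of surface coils.

    Coil ``i`` sits at angle ``2 pi i / C`` on the circle circumscribing the
    grid; its magnitude falls off as a Gaussian of the distance to the coil
    center (default width 0.7x the grid diagonal) and its phase grows
    linearly with that distance.  With ``normalize`` the maps are scaled so
    the pixelwise sum-of-squares is exactly one.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = (H - 1) / 2, (W - 1) / 2
    radius = np.hypot(H / 2, W / 2)  # circumscribing circle
    sigma_px = (profile_sigma_mm / pixel_size_mm if profile_sigma_mm
                else 0.7 * np.hypot(H, W))
    phase_per_px = phase_per_mm * pixel_size_mm
    maps = np.empty((n_coils, H, W), dtype=complex)
    for i in range(n_coils):
        theta = 2.0 * np.pi * i / n_coils
        center = (cy + radius * np.sin(theta), cx + radius * np.cos(theta))
        maps[i] = _coil_profile(yy, xx, center, sigma_px, phase_per_px)
    if normalize:
        sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps /= sos
    return CoilEnsemble(maps, normalized=normalize)


def make_cartesian_mask(n_lines: int, R: float, offset: int = 0,
                        center_fraction: float = 0.0) -> SamplingMask:
    """Equispaced Cartesian line mask: every R-th line starting at ``offset``,
    plus the central ``ceil(center_fraction * n_lines)`` lines.

    With ``offset = 0`` the selectors nest across divisible accelerations
    (R=8 subset of R=4 subset of R=2), which makes the ideal-observer bound
    exactly monotone in R.
    """
    step = int(round(R))
    if step < 1 or step > n_lines:
        raise ValueError("R must satisfy 1 <= R <= n_lines")
    sel = np.zeros(n_lines, dtype=bool)
    sel[(np.arange(n_lines) - offset) % step == 0] = True
    if center_fraction > 0:
        n_center = int(np.ceil(center_fraction * n_lines))
        lo = n_lines // 2 - n_center // 2
        sel[lo:lo + n_center] = True
    return SamplingMask(sel, acceleration=float(R), offset=offset,
                        center_fraction=center_fraction)


def forward(f: ObjectImage | np.ndarray, coils: CoilEnsemble,
            mask: SamplingMask, noise: NoiseModel = NoiseModel(0.0),
            seed: Optional[int] = None,
            hypothesis_label: str = "unknown") -> KspaceData:
    """Apply the SENSE forward model ``g_i = Phi F S_i f + n_i``."""
    pixels = f.pixels if isinstance(f, ObjectImage) else np.asarray(f)
    if pixels.shape != coils.shape:
        raise ValueError("object and coil-map shapes differ")
    if pixels.shape[0] != mask.n_lines:
        raise ValueError("mask length does not match grid rows")
    k = fft2c(coils.maps * pixels[None, :, :])
    k[:, ~mask.line_selector, :] = 0
    if noise.sigma > 0:
        if seed is None:
            raise ValueError("seed required when noise sigma > 0")
        k = add_noise(k, noise, mask, seed)
    return KspaceData(k, mask=mask, hypothesis_label=hypothesis_label,
                      noise_sigma=noise.sigma)


def adjoint(g: KspaceData | np.ndarray, coils: CoilEnsemble,
            mask: Optional[SamplingMask] = None) -> np.ndarray:
    """Exact adjoint of the noiseless forward map:
    ``sum_i conj(S_i) F^-1 (Phi g_i)``."""
    if isinstance(g, KspaceData):
        samples, mask = g.samples, g.mask
    else:
        samples = np.asarray(g, dtype=complex)
        if mask is None:
            raise ValueError("mask required for raw-array input")
    if samples.shape[0] != coils.n_coils or samples.shape[1:] != coils.shape:
        raise ValueError("k-space and coil-map shapes differ")
    masked = samples.copy()
    masked[:, ~mask.line_selector, :] = 0
    return np.sum(np.conj(coils.maps) * ifft2c(masked), axis=0)


def add_noise(k: np.ndarray, noise: NoiseModel, mask: SamplingMask,
              seed: int) -> np.ndarray:
    """Add seeded complex Gaussian noise on the sampled lines only."""
    if noise.sigma < 0:
        raise ValueError("sigma must be nonnegative")
    k = np.asarray(k, dtype=complex)
    if noise.sigma == 0:
        return k.copy()
    rng = np.random.default_rng(seed)
    out = k.copy()
    sel = mask.line_selector
    shape = (k.shape[0], int(sel.sum()), k.shape[2])
    out[:, sel, :] += (rng.normal(0.0, noise.sigma, shape)
                       + 1j * rng.normal(0.0, noise.sigma, shape))
    return out
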