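"""Shared fixtures: small simulation tasks reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from iobound import (LumpyParams, SignalModel, make_cartesian_mask,
                     render_gaussian_signal, sample_lumpy_background,
                     simulate_coil_maps)
from iobound.sense import fft2c


@pytest.fixture(scope="session")
def coils8():
    """Normalized 8-coil ensemble on a 64x64 grid."""
    return simulate_coil_maps(8, (64, 64), normalize=True)


@pytest.fixture(scope="session")
def uniform_coil():
    """Single normalized (unit-magnitude) coil on a 64x64 grid."""
    return simulate_coil_maps(1, (64, 64), normalize=True)


@pytest.fixture(scope="session")
def reference_signal_kspace(uniform_coil):
    """Noiseless single-coil k-space of the reference Gaussian signal
    (amplitude 0.7, sigma 2 mm, 1 mm pixels) at the grid center."""
    sig = SignalModel(0.7, 2.0, (32.0, 32.0))
    img = render_gaussian_signal(sig, 1.0, (64, 64)).pixels
    return fft2c(uniform_coil.maps * img[None])


@pytest.fixture(scope="session")
def lumpy_background64():
    """One fixed bright lumpy background realization (BKE tasks)."""
    return sample_lumpy_background(LumpyParams(), seed=5)


def draw_ske_kspace(b, s, sigma, n, signal_present, rng, dtype=complex):
    """Noisy k-space realizations g = b (+ s) + n for the SKE/BKE task."""
    base = b + (s if signal_present else 0)
    noise = (rng.normal(0, sigma, (n, *b.shape))
             + 1j * rng.normal(0, sigma, (n, *b.shape)))
    return (base[None] + noise).astype(dtype)
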