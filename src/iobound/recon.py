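"""Image-reconstruction baselines for under-sampled multi-coil k-space.

Three reconstructors of increasing sophistication:

* :func:`recon_rsos` — zero-filled inverse DFT per coil, root sum-of-squares
  combination (the classical parallel-imaging baseline);
* :func:`recon_cg_sense` — conjugate-gradient solution of the
  Tikhonov-regularized SENSE normal equations;
* :func:`train_recon_net` / :func:`apply_recon_net` — a deliberately small
  encoder-decoder mapping rSOS inputs directly to fully sampled
  references.  It plays the role of a learned (deep) reconstruction
  method at CPU scale and is an analog of such methods, not a
  reproduction of any published architecture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nnet
from .sense import CoilEnsemble, KspaceData, SamplingMask, ifft2c

__all__ = [
    "ReconImage",
    "ReconNetConfig",
    "ReconModel",
    "recon_rsos",
    "recon_cg_sense",
    "train_recon_net",
    "apply_recon_net",
]


@dataclass
class ReconImage:
    """A real, nonnegative magnitude reconstruction with provenance."""

    pixels: np.ndarray
    method_tag: str = ""
    provenance: dict = field(default_factory=dict)
    residuals: Optional[list] = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("reconstruction must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def recon_rsos(g: KspaceData) -> ReconImage:
    """Root sum-of-squares of the per-coil zero-filled inverse DFTs."""
    coil_images = ifft2c(g.samples)
    pixels = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    return ReconImage(pixels, method_tag="rsos",
                      provenance={"R": g.mask.acceleration,
                                  "sigma": g.noise_sigma})


def recon_cg_sense(g: KspaceData, coils: CoilEnsemble,
                   mask: Optional[SamplingMask] = None, lam: float = 0.0,
                   max_iter: int = 50, tol: float = 1e-8) -> ReconImage:
    """Krylov solution of ``(A^H A + lam I) x = A^H g`` for the noiseless
    SENSE operator A; returns the magnitude image and the residual-norm
    trace.

    The iteration is the conjugate-residual variant of CG (identical cost,
    same fixed point), which guarantees a monotonically non-increasing
    residual norm on this Hermitian positive-definite system.
    Non-convergence within ``max_iter`` is reported via ``converged=False``
    (not raised), with the final relative residual in ``provenance``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    mask = mask if mask is not None else g.mask
    sel = mask.line_selector
    S = coils.maps

    def normal_op(x: np.ndarray) -> np.ndarray:
        from .sense import fft2c
        k = fft2c(S * x[None])
        k[:, ~sel, :] = 0
        return np.sum(np.conj(S) * ifft2c(k), axis=0) + lam * x

    from .sense import adjoint
    b = adjoint(g, coils)
    x = np.zeros_like(b)
    r = b.copy()
    b_norm = float(np.linalg.norm(b))
    residuals = [b_norm]
    converged = False
    if b_norm == 0:
        return ReconImage(np.abs(x), method_tag="cg_sense",
                          provenance={"lam": lam, "iters": 0},
                          residuals=residuals, converged=True)
    p = r.copy()
    Ar = normal_op(r)
    Ap = Ar.copy()
    rAr = float(np.vdot(r, Ar).real)
    for it in range(max_iter):
        denom = float(np.vdot(Ap, Ap).real)
        if denom == 0 or rAr == 0:
            converged = True
            break
        alpha = rAr / denom
        x = x + alpha * p
        r = r - alpha * Ap
        res = float(np.linalg.norm(r))
        residuals.append(res)
        if res <= tol * b_norm:
            converged = True
            break
        Ar = normal_op(r)
        rAr_new = float(np.vdot(r, Ar).real)
        beta = rAr_new / rAr
        p = r + beta * p
        Ap = Ar + beta * Ap
        rAr = rAr_new
    return ReconImage(np.abs(x), method_tag="cg_sense",
                      provenance={"lam": lam, "iters": len(residuals) - 1,
                                  "final_relres": residuals[-1] / b_norm},
                      residuals=residuals, converged=converged)


@dataclass
class ReconNetConfig:
    """Configuration of the small encoder-decoder reconstructor."""

    channels: tuple[int, int] = (8, 16)
    epochs: int = 45
    batch_size: int = 16
    lr: float = 5e-3
    weight_decay: float = 0.0

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReconModel:
    """A trained reconstructor: network, normalization constants, provenance."""

    net: nnet.Network
    mu: float
    sd: float
    config_digest: str
    loss_trace: list = field(default_factory=list)


def _build_recon_net(config: ReconNetConfig,
                     rng: np.random.Generator) -> nnet.Network:
    """Two-level encoder-decoder (conv/pool/conv/conv/upsample/conv)."""
    c1, c2 = config.channels
    return nnet.Network([
        nnet.Conv2D(1, c1, rng=rng), nnet.ReLU(),
        nnet.AvgPool2(),
        nnet.Conv2D(c1, c2, rng=rng), nnet.ReLU(),
        nnet.Conv2D(c2, c2, rng=rng), nnet.ReLU(),
        nnet.Upsample2(),
        nnet.Conv2D(c2, c1, rng=rng), nnet.ReLU(),
        nnet.Conv2D(c1, 1, rng=rng),
    ])


def train_recon_net(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                    config: ReconNetConfig = ReconNetConfig(),
                    seed: int = 0) -> ReconModel:
    """Train the encoder-decoder on (under-sampled rSOS, reference) pairs.

    Inputs and targets share one scalar normalization (training-input mean
    and std) so the output scale is consistent; the network predicts the
    reference directly, which suits these piecewise-smooth objects (direct
    prediction trains far more reliably here than predicting the
    input-to-reference residual, whose high-frequency content a small net
    struggles to regress).  Training minimizes mean-squared error and is
    fully seeded.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    x = np.stack([np.asarray(p[0], dtype=np.float32)
                  for p in pairs])[..., None]
    y = np.stack([np.asarray(p[1], dtype=np.float32)
                  for p in pairs])[..., None]
    mu = float(x.mean())
    sd = float(x.std()) or 1.0
    xn = (x - mu) / sd
    yn = (y - mu) / sd
    rng = np.random.default_rng(seed)
    net = _build_recon_net(config, rng)
    history = nnet.train_network(net, xn, yn, loss="mse",
                                 epochs=config.epochs,
                                 batch_size=config.batch_size, lr=config.lr,
                                 weight_decay=config.weight_decay,
                                 seed=seed + 1)
    return ReconModel(net=net, mu=mu, sd=sd, config_digest=config.digest(),
                      loss_trace=history["loss"])


def apply_recon_net(model: ReconModel, g) -> ReconImage:
    """Apply a trained reconstructor to k-space data (via rSOS) or directly
    to an rSOS image; deterministic for a fixed model."""
    if isinstance(g, KspaceData):
        base = recon_rsos(g).pixels
        prov = {"R": g.mask.acceleration, "sigma": g.noise_sigma}
    else:
        base = np.asarray(g.pixels if hasattr(g, "pixels") else g, dtype=float)
        prov = {}
    xn = ((base - model.mu) / model.sd).astype(np.float32)[None, ..., None]
    out = model.net.predict(xn)[0, ..., 0].astype(float)
    pixels = np.maximum(out * model.sd + model.mu, 0.0)
    prov["config_digest"] = model.config_digest
    return ReconImage(pixels, method_tag="net", provenance=prov)
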