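"""Signal-detection observers: analytic ideal observers for tractable
Gaussian tasks, the Hotelling (optimal linear) observer, and a CNN
approximation of the ideal observer trained directly on raw k-space or on
reconstructed images.

Statistical background
----------------------
A binary detection task asks whether measured data ``g`` contains a known or
statistically known signal on top of a background.  The ideal observer (IO)
computes the likelihood ratio ``Lambda(g) = p(g|H1) / p(g|H0)`` (or any
monotone transform of it) and maximizes the ROC curve — hence the AUC —
among all observers.  Acting on the *raw measurement data*, the IO's AUC is
an upper bound that no reconstruction-then-detection pipeline can exceed
(data-processing inequality).

For background-known-exactly (BKE) tasks with complex Gaussian noise the IO
is available in closed form (:func:`ske_bke_statistic`,
:func:`sks_bke_statistic`) together with its exact detectability
(:func:`ske_bke_analytic_auc`).  For intractable cases the IO is
approximated by a CNN classifier whose depth is grown until validation
detection performance stops improving (:class:`CnnIdealObserver`).

The trainable observers follow a Model/Results pattern: construct the model
with its training data, call :meth:`fit`, and use the returned results
object to compute test statistics and AUCs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import LinAlgError, solve
from scipy.special import logsumexp, ndtr

from . import nnet
from .roc import AUCResult, estimate_auc
from .sense import SamplingMask

__all__ = [
    "TestStatistic",
    "AnalyticDetectability",
    "CnnIoConfig",
    "SkeObserver",
    "SksObserver",
    "ske_bke_statistic",
    "ske_bke_analytic_auc",
    "sks_bke_statistic",
    "HotellingObserver",
    "HotellingResults",
    "CnnIdealObserver",
    "CnnIoResults",
    "apply_observer",
    "as_real_vector",
    "save_observer",
    "load_observer",
]


@dataclass
class TestStatistic:
    """Scalar test statistic(s) with the tag of the observer that made them."""

    value: np.ndarray
    observer_tag: str = ""

    def __post_init__(self) -> None:
        self.value = np.atleast_1d(np.asarray(self.value, dtype=float))
        if not np.all(np.isfinite(self.value)):
            raise ValueError("test statistic must be finite")


@dataclass
class AnalyticDetectability:
    """Detectability index d' and the corresponding ideal-observer AUC
    ``Phi(d'/2)`` for a Gaussian-statistics task."""

    d_prime: float
    auc: float

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValueError("d_prime must be nonnegative")
        if abs(self.auc - float(ndtr(self.d_prime / 2.0))) > 1e-12:
            raise ValueError("auc must equal Phi(d_prime / 2)")


def _apply_line_mask(x: np.ndarray, mask: Optional[SamplingMask]) -> np.ndarray:
    if mask is None:
        return x
    out = x.copy()
    out[..., ~mask.line_selector, :] = 0
    return out


def ske_bke_statistic(g: np.ndarray, b: np.ndarray, s: np.ndarray,
                      sigma: float,
                      mask: Optional[SamplingMask] = None) -> np.ndarray:
    """Exact log-likelihood ratio for the SKE/BKE complex-Gaussian task.

    ``t = Re<s, g - b> / sigma^2 - ||s||^2 / (2 sigma^2)``, with the inner
    product restricted to sampled entries.  ``g`` may carry an extra leading
    batch axis; the return value is then a 1-D array of statistics.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    b = np.asarray(b, dtype=complex)
    s = _apply_line_mask(np.asarray(s, dtype=complex), mask)
    g = np.asarray(g, dtype=complex)
    batched = g.ndim == b.ndim + 1
    diff = g - b
    axes = tuple(range(-b.ndim, 0))
    inner = np.sum(np.conj(s) * diff, axis=axes).real
    energy = float(np.sum(np.abs(s) ** 2))
    t = inner / sigma**2 - energy / (2.0 * sigma**2)
    return t if batched else float(t)


def ske_bke_analytic_auc(s: np.ndarray, mask: Optional[SamplingMask],
                         sigma: float) -> AnalyticDetectability:
    """Exact IO detectability for SKE/BKE under complex Gaussian noise.

    With noise std ``sigma`` per real/imaginary component of every sampled
    k-space entry, the ideal-observer detectability is
    ``d'^2 = 2 sum_sampled |s_k|^2 / sigma^2`` and ``AUC = Phi(d'/2)``
    (equivalently ``1/2 + 1/2 erf(SNR_t/2)`` for the log-likelihood-ratio
    SNR ``SNR_t = d'/sqrt(2)``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = _apply_line_mask(np.asarray(s, dtype=complex), mask)
    d_prime = float(np.sqrt(2.0 * np.sum(np.abs(s) ** 2)) / sigma)
    return AnalyticDetectability(d_prime=d_prime,
                                 auc=float(ndtr(d_prime / 2.0)))


def sks_bke_statistic(g: np.ndarray, b: np.ndarray,
                      signal_set: Sequence[np.ndarray],
                      prior: Optional[Sequence[float]], sigma: float,
                      mask: Optional[SamplingMask] = None) -> np.ndarray:
    """Exact IO log-likelihood ratio for a discrete signal-location mixture.

    ``log Lambda = logsumexp_j [log prior_j + Re<s_j, g-b>/sigma^2
    - ||s_j||^2/(2 sigma^2)]`` — the signal-known-statistically (SKS)
    observer for a finite set of candidate signals under a BKE Gaussian
    model.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    signals = np.stack([_apply_line_mask(np.asarray(s, dtype=complex), mask)
                        for s in signal_set])
    J = signals.shape[0]
    if J == 0:
        raise ValueError("empty signal set")
    if prior is None:
        prior = np.full(J, 1.0 / J)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (J,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValueError("prior must be a length-J probability vector")
    b = np.asarray(b, dtype=complex)
    g = np.asarray(g, dtype=complex)
    batched = g.ndim == b.ndim + 1
    diff = (g - b).reshape((-1, b.size) if batched else (1, b.size))
    smat = signals.reshape(J, -1)
    inner = (diff @ np.conj(smat).T).real / sigma**2  # (N, J)
    energies = np.sum(np.abs(smat) ** 2, axis=1) / (2.0 * sigma**2)
    with np.errstate(divide="ignore"):
        logw = np.log(prior)
    t = logsumexp(inner - energies[None, :] + logw[None, :], axis=1)
    return t if batched else float(t[0])


def as_real_vector(x: np.ndarray) -> np.ndarray:
    """Flatten measurements to real feature vectors.

    Complex arrays are stacked as [Re, Im] (doubling the dimension); a
    leading batch axis is preserved when present (ndim > 2 or 2-D real
    stacks are treated as (N, d) when already flat).
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        flat = x.reshape(x.shape[0], -1) if x.ndim > 2 else x.reshape(1, -1)
        return np.concatenate([flat.real, flat.imag], axis=1)
    if x.ndim <= 1:
        return x.reshape(1, -1).astype(float)
    if x.ndim == 2:
        return x.astype(float)  # already (N, d)
    return x.reshape(x.shape[0], -1).astype(float)


class SkeObserver:
    """Analytic SKE/BKE ideal observer (known background, signal, noise)."""

    kind = "analytic_ske"
    input_space = "data"

    def __init__(self, b: np.ndarray, s: np.ndarray, sigma: float,
                 mask: Optional[SamplingMask] = None) -> None:
        self.b = np.asarray(b, dtype=complex)
        self.s = np.asarray(s, dtype=complex)
        self.sigma = float(sigma)
        self.mask = mask

    def statistic(self, g: np.ndarray) -> np.ndarray:
        return ske_bke_statistic(g, self.b, self.s, self.sigma, self.mask)

    def analytic(self) -> AnalyticDetectability:
        return ske_bke_analytic_auc(self.s, self.mask, self.sigma)


class SksObserver:
    """Analytic SKS/BKE ideal observer over a finite signal-location set."""

    kind = "analytic_sks"
    input_space = "data"

    def __init__(self, b: np.ndarray, signal_set: Sequence[np.ndarray],
                 prior: Optional[Sequence[float]], sigma: float,
                 mask: Optional[SamplingMask] = None) -> None:
        self.b = np.asarray(b, dtype=complex)
        self.signal_set = [np.asarray(s, dtype=complex) for s in signal_set]
        self.prior = prior
        self.sigma = float(sigma)
        self.mask = mask

    def statistic(self, g: np.ndarray) -> np.ndarray:
        return sks_bke_statistic(g, self.b, self.signal_set, self.prior,
                                 self.sigma, self.mask)


class HotellingObserver:
    """The optimal linear observer, estimated from training samples.

    The template is ``w = Sigma_shrunk^{-1} (mean_H1 - mean_H0)`` on the
    real-stacked representation, where the pooled sample covariance is
    shrunk toward its diagonal: ``Sigma_shrunk = (1-gamma) Sigma + gamma
    diag(Sigma)``.  For Gaussian data the Hotelling observer coincides with
    the ideal observer, which makes it a practical stand-in for the IO on
    reconstructed images.
    """

    def __init__(self, train_h0: np.ndarray, train_h1: np.ndarray,
                 shrinkage: float = 0.01) -> None:
        if not (0.0 <= shrinkage <= 1.0):
            raise ValueError("shrinkage must lie in [0, 1]")
        self.x0 = as_real_vector(train_h0)
        self.x1 = as_real_vector(train_h1)
        if self.x0.shape[0] < 2 or self.x1.shape[0] < 2:
            raise ValueError("need at least 2 training samples per class")
        self.shrinkage = float(shrinkage)

    def fit(self) -> "HotellingResults":
        n0, n1 = self.x0.shape[0], self.x1.shape[0]
        mu0 = self.x0.mean(axis=0)
        mu1 = self.x1.mean(axis=0)
        c0 = self.x0 - mu0
        c1 = self.x1 - mu1
        cov = (c0.T @ c0 + c1.T @ c1) / (n0 + n1 - 2)
        gamma = self.shrinkage
        if gamma > 0:
            cov = (1 - gamma) * cov + gamma * np.diag(np.diag(cov))
        delta = mu1 - mu0
        singular = False
        try:
            w = solve(cov, delta, assume_a="pos")
        except (LinAlgError, np.linalg.LinAlgError):
            w = np.linalg.lstsq(cov, delta, rcond=None)[0]
            singular = True
        return HotellingResults(template=w, mean_h0=mu0, mean_h1=mu1,
                                shrinkage=gamma, singular=singular,
                                n_train=(n0, n1))


@dataclass
class HotellingResults:
    """Fitted Hotelling observer: template, training means, diagnostics."""

    template: np.ndarray
    mean_h0: np.ndarray
    mean_h1: np.ndarray
    shrinkage: float
    singular: bool
    n_train: tuple[int, int]
    kind: str = "hotelling"
    input_space: str = "image"

    def statistic(self, x: np.ndarray) -> np.ndarray:
        return as_real_vector(x) @ self.template

    def auc(self, test_h0: np.ndarray, test_h1: np.ndarray) -> AUCResult:
        return estimate_auc(self.statistic(test_h0), self.statistic(test_h1))

    def summary(self) -> str:
        lines = [
            "Hotelling observer",
            "==================",
            f"dimension        : {self.template.size}",
            f"training samples : {self.n_train[0]} (H0), {self.n_train[1]} (H1)",
            f"shrinkage        : {self.shrinkage}",
            f"singular cov     : {self.singular}",
            f"template norm    : {np.linalg.norm(self.template):.6g}",
        ]
        return "\n".join(lines)


@dataclass
class CnnIoConfig:
    """Depth-growth schedule and optimizer settings for the CNN-IO.

    Training starts from a classifier with ``base_depth`` convolutional
    layers; after each stage converges, ``growth_step`` further layers are
    added and the model retrained, until the validation-AUC improvement
    falls below ``convergence_tol`` for ``patience`` consecutive stages or
    ``max_stages`` is reached.
    """

    base_depth: int = 2
    growth_step: int = 1
    max_stages: int = 5
    convergence_tol: float = 0.005
    patience: int = 1
    channels: int = 16
    epochs_per_stage: int = 14
    batch_size: int = 64
    lr: float = 2e-3
    weight_decay: float = 5e-3
    ensemble_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.max_stages < 1:
            raise ValueError("max_stages must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_channels(x: np.ndarray) -> np.ndarray:
    """Map measurements to network input channels (channels-last).

    Complex (N, C, H, W) k-space becomes (N, H, W, 2C) with channels
    ordered coil-major, (real, imag); real (N, H, W) images become one
    channel.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        if x.ndim == 3:  # (N, H, W) single coil
            x = x[:, None]
        n, c, h, w = x.shape
        xt = x.transpose(0, 2, 3, 1)  # N, H, W, C
        out = np.empty((n, h, w, 2 * c), dtype=np.float32)
        out[..., 0::2] = xt.real
        out[..., 1::2] = xt.imag
        return out
    if x.ndim == 3:
        return x[..., None].astype(np.float32)
    return x.astype(np.float32)


def _build_cnn(depth: int, channels: int, c_in: int, h: int, w: int,
               rng: np.random.Generator) -> nnet.Network:
    """Classifier stack: space-to-depth front (lossless, keeps convs on a
    <=16x16 grid for CPU speed), ``depth`` conv/ReLU layers, two average
    poolings, dense logit."""
    block = max(1, min(h, w) // 16)
    layers: list[nnet.Layer] = []
    if block > 1:
        layers.append(nnet.SpaceToDepth(block))
        c_in *= block * block
        h, w = h // block, w // block
    layers += [nnet.Conv2D(c_in, channels, rng=rng), nnet.ReLU()]
    for _ in range(depth - 1):
        layers += [nnet.Conv2D(channels, channels, rng=rng), nnet.ReLU()]
    layers += [nnet.AvgPool2(), nnet.AvgPool2(), nnet.Flatten(),
               nnet.Dense(channels * (h // 4) * (w // 4), 1, rng=rng)]
    return nnet.Network(layers)


class CnnIdealObserver:
    """CNN approximation of the ideal observer (Model half of Model/Results).

    A sigmoid-output convolutional classifier is trained with binary
    cross-entropy on labeled H0/H1 measurements; at the optimum its output
    is a monotone transform of the likelihood ratio, so its ranking
    performance approaches the IO's.  Depth is grown stage by stage per the
    schedule in :class:`CnnIoConfig`; the best stage (by validation AUC) is
    returned.
    """

    def __init__(self, train_h0: np.ndarray, train_h1: np.ndarray,
                 val_h0: np.ndarray, val_h1: np.ndarray,
                 config: CnnIoConfig = CnnIoConfig()) -> None:
        if len(train_h0) == 0 or len(train_h1) == 0:
            raise ValueError("empty training set")
        self.input_space = ("data" if np.iscomplexobj(np.asarray(train_h0))
                            else "image")
        self.x_train = np.concatenate([_to_channels(train_h0),
                                       _to_channels(train_h1)])
        self.y_train = np.concatenate([
            np.zeros(len(train_h0), dtype=np.float32),
            np.ones(len(train_h1), dtype=np.float32)])
        if self.y_train.min() == self.y_train.max():
            raise ValueError("training labels are degenerate")
        self.x_val0 = _to_channels(val_h0)
        self.x_val1 = _to_channels(val_h1)
        self.config = config
        # standardization from training-set statistics: the mean is removed
        # per location (so a bright deterministic background component does
        # not swamp the net's input) and the scale is per channel
        self.mu = self.x_train.mean(axis=0, keepdims=True)
        sd = (self.x_train - self.mu).std(axis=(0, 1, 2), keepdims=True)
        sd[sd == 0] = 1.0
        self.sd = sd

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.mu) / self.sd).astype(np.float32)

    def _build(self, depth: int, rng: np.random.Generator) -> nnet.Network:
        h, w, c_in = self.x_train.shape[1:4]
        return _build_cnn(depth, self.config.channels, c_in, h, w, rng)

    def fit(self) -> "CnnIoResults":
        cfg = self.config
        xt = self._standardize(self.x_train)
        xv0 = self._standardize(self.x_val0)
        xv1 = self._standardize(self.x_val1)
        trace: list[dict] = []
        best_auc, best_members, best_depth = -np.inf, None, 0
        stale = 0
        stopped_stage = cfg.max_stages - 1
        for stage in range(cfg.max_stages):
            depth = cfg.base_depth + stage * cfg.growth_step
            net = self._build(depth, np.random.default_rng(
                cfg.seed + 1000 * stage))
            opt = nnet.Adam(net, lr=cfg.lr, weight_decay=cfg.weight_decay)
            shuffle_rng = np.random.default_rng(cfg.seed + 1000 * stage + 1)
            epoch_records: list[tuple] = []  # (val_auc, state, z0, z1)
            for epoch in range(cfg.epochs_per_stage):
                opt.lr = cfg.lr * 0.5 ** (epoch // 5)  # step decay
                order = shuffle_rng.permutation(xt.shape[0])
                for lo in range(0, xt.shape[0], cfg.batch_size):
                    idx = order[lo:lo + cfg.batch_size]
                    z = net.forward(xt[idx], train=True)
                    _, dz = nnet.bce_with_logits(z, self.y_train[idx])
                    net.backward(dz.reshape(z.shape))
                    opt.step()
                z0 = net.predict(xv0).ravel()
                z1 = net.predict(xv1).ravel()
                epoch_records.append((estimate_auc(z0, z1).auc,
                                      net.get_state(), z0, z1))
            # checkpoint ensemble: average z-scored logits of the best
            # ensemble_k epochs (variance reduction for the statistic)
            top = sorted(epoch_records, key=lambda r: -r[0])[:cfg.ensemble_k]
            members = []
            ens0 = np.zeros(xv0.shape[0])
            ens1 = np.zeros(xv1.shape[0])
            for auc_e, state, z0, z1 in top:
                allz = np.concatenate([z0, z1])
                mu_z, sd_z = float(allz.mean()), float(allz.std()) or 1.0
                member = self._build(depth, np.random.default_rng(0))
                member.set_state(state)
                members.append((member, mu_z, sd_z))
                ens0 += (z0 - mu_z) / sd_z
                ens1 += (z1 - mu_z) / sd_z
            stage_auc = estimate_auc(ens0, ens1).auc
            trace.append({"stage": stage, "depth": depth,
                          "val_auc": stage_auc,
                          "best_epoch_auc": top[0][0],
                          "n_params": net.n_params()})
            improvement = stage_auc - best_auc
            if stage_auc > best_auc:
                best_auc, best_members, best_depth = stage_auc, members, depth
            if improvement < cfg.convergence_tol:
                stale += 1
                if stale >= cfg.patience:
                    stopped_stage = stage
                    break
            else:
                stale = 0
        return CnnIoResults(members=best_members, depth=best_depth,
                            val_auc=best_auc, auc_trace=trace,
                            stopped_stage=stopped_stage,
                            input_space=self.input_space,
                            mu=self.mu, sd=self.sd,
                            config_digest=cfg.digest())


@dataclass
class CnnIoResults:
    """A trained CNN-IO: checkpoint-ensemble members, growth trace,
    provenance."""

    members: list  # (network, logit mean, logit sd) triples
    depth: int
    val_auc: float
    auc_trace: list
    stopped_stage: int
    input_space: str
    mu: np.ndarray
    sd: np.ndarray
    config_digest: str
    kind: str = "cnn"

    def statistic(self, x: np.ndarray) -> np.ndarray:
        """Ensemble-averaged z-scored classifier logit — a monotone
        transform of the estimated likelihood ratio."""
        xs = ((_to_channels(x) - self.mu) / self.sd).astype(np.float32)
        out = np.zeros(xs.shape[0])
        for net, mu_z, sd_z in self.members:
            out += (net.predict(xs).ravel().astype(float) - mu_z) / sd_z
        return out / len(self.members)

    def auc(self, test_h0: np.ndarray, test_h1: np.ndarray) -> AUCResult:
        return estimate_auc(self.statistic(test_h0), self.statistic(test_h1))

    def summary(self) -> str:
        lines = ["CNN ideal-observer approximation",
                 "================================",
                 f"input space      : {self.input_space}",
                 f"selected depth   : {self.depth} conv layers",
                 f"ensemble size    : {len(self.members)}",
                 f"validation AUC   : {self.val_auc:.4f}",
                 f"stages trained   : {len(self.auc_trace)}",
                 f"config digest    : {self.config_digest}",
                 "stage trace      :"]
        for row in self.auc_trace:
            lines.append(f"  stage {row['stage']} depth {row['depth']:2d} "
                         f"val AUC {row['val_auc']:.4f} "
                         f"({row['n_params']} params)")
        return "\n".join(lines)


def save_observer(results, path: str) -> None:
    """Serialize a fitted observer to ``path`` (npz) plus a JSON sidecar
    (``path + '.json'``) carrying kind, provenance and the training trace."""
    meta: dict = {}
    arrays: dict[str, np.ndarray] = {}
    if isinstance(results, HotellingResults):
        meta.update(kind="hotelling", input_space=results.input_space,
                    shrinkage=results.shrinkage, singular=results.singular,
                    n_train=list(results.n_train))
        arrays.update(template=results.template, mean_h0=results.mean_h0,
                      mean_h1=results.mean_h1)
    elif isinstance(results, CnnIoResults):
        first_conv = next(l for l in results.members[0][0].flat_layers()
                          if isinstance(l, nnet.Conv2D))
        meta.update(kind="cnn", input_space=results.input_space,
                    depth=results.depth, val_auc=results.val_auc,
                    auc_trace=results.auc_trace,
                    stopped_stage=results.stopped_stage,
                    config_digest=results.config_digest,
                    channels=first_conv.c_out,
                    zscores=[[m[1], m[2]] for m in results.members])
        arrays.update(mu=results.mu, sd=results.sd)
        for i, (net, _, _) in enumerate(results.members):
            for j, layer_params in enumerate(net.get_state()):
                for key, value in layer_params.items():
                    arrays[f"m{i}_l{j}_{key}"] = value
    else:
        raise TypeError(f"cannot serialize observer type {type(results)!r}")
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, **arrays)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_observer(path: str):
    """Inverse of :func:`save_observer`."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path, allow_pickle=False)
    if meta["kind"] == "hotelling":
        return HotellingResults(template=data["template"],
                                mean_h0=data["mean_h0"],
                                mean_h1=data["mean_h1"],
                                shrinkage=meta["shrinkage"],
                                singular=meta["singular"],
                                n_train=tuple(meta["n_train"]),
                                input_space=meta["input_space"])
    if meta["kind"] == "cnn":
        mu, sd = data["mu"], data["sd"]
        h, w, c_in = mu.shape[1:4]
        members = []
        for i, (mu_z, sd_z) in enumerate(meta["zscores"]):
            net = _build_cnn(meta["depth"], meta["channels"], c_in, h, w,
                             np.random.default_rng(0))
            state = []
            for j in range(len(net.flat_layers())):
                state.append({key: data[f"m{i}_l{j}_{key}"]
                              for key in ("W", "b")
                              if f"m{i}_l{j}_{key}" in data})
            net.set_state(state)
            members.append((net, mu_z, sd_z))
        return CnnIoResults(members=members, depth=meta["depth"],
                            val_auc=meta["val_auc"],
                            auc_trace=meta["auc_trace"],
                            stopped_stage=meta["stopped_stage"],
                            input_space=meta["input_space"], mu=mu, sd=sd,
                            config_digest=meta["config_digest"])
    raise ValueError(f"unknown observer kind {meta['kind']!r}")


def apply_observer(model, g: np.ndarray) -> TestStatistic:
    """Evaluate any observer on measurements, returning a TestStatistic.

    Dispatches on the observer type (analytic SKE/SKS, fitted Hotelling,
    trained CNN-IO); evaluation is deterministic for fixed parameters.
    """
    if isinstance(model, (SkeObserver, SksObserver)):
        tag = model.kind
        value = model.statistic(g)
    elif isinstance(model, HotellingResults):
        if np.iscomplexobj(np.asarray(g)) and model.input_space == "image":
            raise ValueError("Hotelling observer fitted on images received "
                             "complex data")
        tag = model.kind
        value = model.statistic(g)
    elif isinstance(model, CnnIoResults):
        arr = np.asarray(g)
        space = "data" if np.iscomplexobj(arr) else "image"
        if space != model.input_space:
            raise ValueError(
                f"observer expects {model.input_space}-space input, got {space}")
        tag = model.kind
        value = model.statistic(g)
    else:
        raise TypeError(f"unsupported observer type {type(model)!r}")
    return TestStatistic(value=value, observer_tag=tag)
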