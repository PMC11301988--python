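"""Inductive logistic matrix completion with two MLP towers.

A compound tower maps a fingerprint ``x_c`` (d_c -> 128 -> 64 by default)
and a kinase tower maps a sequence descriptor ``x_p`` (d_p -> 128 -> 64)
into a shared embedding space; the active probability of the pair is the
logistic link on their inner product,

    P(active | x_c, x_p) = sigma( <NN(x_c | U), NN(x_p | V)> ),

and training minimizes the mean binary cross-entropy over the observed
active/inactive pairs plus an L2 penalty lambda * (||U||_F^2 + ||V||_F^2)
on the tower weights (biases unpenalized).  Because both towers consume
side-information features, the model is inductive: it scores compounds and
kinases never seen during training.

All parameters live in one flat vector so the meta-learning module can
treat training as a differentiable map.  Gradients are analytic backprop;
Hessian-vector products — needed for second-order meta-gradients — are
obtained by complex-step differentiation of the gradient (exact to machine
precision, no subtractive cancellation), which is why every kernel below
is written to be complex-safe: branch conditions use only real parts.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_features import FeatureMatrix
from .seeding import substream

PROB_EPS = 1e-12  # reported probabilities clipped to the open interval
_CSTEP = 1e-100  # complex-step size; any tiny value works (no cancellation)


# ---------------------------------------------------------------------------
# architecture and parameter container


@dataclass(frozen=True)
class TowerArch:
    """Layer sizes of the two towers (shared final embedding dimension)."""

    d_c: int
    d_p: int
    hidden: tuple[int, ...] = (128,)
    embedding_dim: int = 64

    @property
    def compound_dims(self) -> tuple[int, ...]:
        return (self.d_c, *self.hidden, self.embedding_dim)

    @property
    def kinase_dims(self) -> tuple[int, ...]:
        return (self.d_p, *self.hidden, self.embedding_dim)

    @property
    def n_params(self) -> int:
        return sum(
            din * dout + dout
            for dims in (self.compound_dims, self.kinase_dims)
            for din, dout in zip(dims[:-1], dims[1:])
        )

    def to_dict(self) -> dict:
        return {
            "d_c": self.d_c,
            "d_p": self.d_p,
            "hidden": list(self.hidden),
            "embedding_dim": self.embedding_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TowerArch":
        return cls(d["d_c"], d["d_p"], tuple(d["hidden"]), d["embedding_dim"])


def _layer_slices(dims: Sequence[int], offset: int):
    """Yield (W_slice, b_slice, shape) for each layer of one tower."""
    for din, dout in zip(dims[:-1], dims[1:]):
        wlen = din * dout
        yield slice(offset, offset + wlen), slice(offset + wlen, offset + wlen + dout), (din, dout)
        offset += wlen + dout


def _unpack(theta: np.ndarray, arch: TowerArch):
    """Views of the flat parameter vector as per-layer (W, b) lists."""
    towers = []
    offset = 0
    for dims in (arch.compound_dims, arch.kinase_dims):
        layers = []
        for wsl, bsl, shape in _layer_slices(dims, offset):
            layers.append((theta[wsl].reshape(shape), theta[bsl]))
            offset = bsl.stop
        towers.append(layers)
    return towers  # [compound_layers, kinase_layers]


@dataclass
class TowerParams:
    """Learnable parameters theta = (U, V) of both towers, stored flat."""

    arch: TowerArch
    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.theta.size != self.arch.n_params:
            raise ValueError(
                f"theta has {self.theta.size} entries, arch needs {self.arch.n_params}"
            )
        if not np.isfinite(self.theta).all():
            raise ValueError("non-finite tower parameters")

    def copy(self) -> "TowerParams":
        return TowerParams(self.arch, self.theta.copy())

    @property
    def embedding_dim(self) -> int:
        return self.arch.embedding_dim

    def layers(self):
        return _unpack(self.theta, self.arch)


def init_params(arch: TowerArch, seed: int = 0) -> TowerParams:
    """He-normal weights (ReLU hidden layers), zero biases."""
    rng = substream(seed, "init")
    theta = np.zeros(arch.n_params)
    layers_c, layers_p = _unpack(theta, arch)
    for layers in (layers_c, layers_p):
        for W, b in layers:
            W[...] = rng.normal(size=W.shape) * np.sqrt(2.0 / W.shape[0])
    return TowerParams(arch, theta)


# ---------------------------------------------------------------------------
# complex-safe numerics


def _sigmoid(z):
    z = np.asarray(z)
    out = np.empty_like(z)
    pos = z.real >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z):
    z = np.asarray(z)
    out = np.empty_like(z)
    pos = z.real > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def _tower_forward(layers, X):
    """Forward pass with caches; ReLU on hidden layers, linear output."""
    h = X
    caches = []
    for i, (W, b) in enumerate(layers):
        a = h @ W + b
        if i < len(layers) - 1:
            mask = a.real > 0
            caches.append((h, mask))
            h = a * mask
        else:
            caches.append((h, None))
            h = a
    return h, caches


def _tower_backward(layers, caches, d_out):
    """Gradients of each (W, b) given the gradient w.r.t. the tower output."""
    grads = [None] * len(layers)
    d = d_out
    for i in range(len(layers) - 1, -1, -1):
        h_in, mask = caches[i]
        d_pre = d if mask is None else d * mask
        W, _ = layers[i]
        grads[i] = (h_in.T @ d_pre, d_pre.sum(axis=0))
        if i > 0:
            d = d_pre @ W.T
    return grads


def forward_logits(theta: np.ndarray, arch: TowerArch, Xc, Xp):
    """Pairwise logits <NN(x_c), NN(x_p)> for row-aligned feature batches."""
    layers_c, layers_p = _unpack(theta, arch)
    ec, _ = _tower_forward(layers_c, Xc)
    ep, _ = _tower_forward(layers_p, Xp)
    return (ec * ep).sum(axis=1)


def loss_value(theta, arch, Xc, Xp, y, lambda_reg=0.0):
    """Mean BCE over the batch + lambda * sum of squared tower weights."""
    if len(y) == 0:
        raise ValueError("empty batch")
    z = forward_logits(theta, arch, Xc, Xp)
    nll = (_softplus(z) - y * z).mean()
    if lambda_reg:
        layers_c, layers_p = _unpack(theta, arch)
        reg = sum((W * W).sum() for W, _ in layers_c + layers_p)
        nll = nll + lambda_reg * reg
    return nll


def loss_and_grad(theta, arch, Xc, Xp, y, lambda_reg=0.0):
    """Loss and its analytic gradient as a flat vector (complex-safe)."""
    if len(y) == 0:
        raise ValueError("empty batch")
    layers_c, layers_p = _unpack(theta, arch)
    ec, cache_c = _tower_forward(layers_c, Xc)
    ep, cache_p = _tower_forward(layers_p, Xp)
    z = (ec * ep).sum(axis=1)
    n = len(y)
    loss = (_softplus(z) - y * z).mean()

    dz = (_sigmoid(z) - y) / n
    grads_c = _tower_backward(layers_c, cache_c, dz[:, None] * ep)
    grads_p = _tower_backward(layers_p, cache_p, dz[:, None] * ec)

    grad = np.empty_like(theta)
    gl_c, gl_p = _unpack(grad, arch)
    for (gW, gb), (dW, db) in zip(gl_c + gl_p, grads_c + grads_p):
        gW[...] = dW
        gb[...] = db
    if lambda_reg:
        reg = 0.0
        for (W, _), (gW, _) in zip(layers_c + layers_p, gl_c + gl_p):
            reg = reg + (W * W).sum()
            gW += 2.0 * lambda_reg * W
        loss = loss + lambda_reg * reg
    return loss, grad


def hessian_vector_product(theta, v, arch, Xc, Xp, y, lambda_reg=0.0):
    """H(theta) v for the batch loss, via a complex step on the gradient.

    Exact to machine precision away from ReLU kinks: the perturbation lives
    entirely in the imaginary part, so activation masks (taken on the real
    part) are unchanged and the result is the true piecewise Hessian.
    """
    zt = theta.astype(complex)
    zt += 1j * _CSTEP * v
    _, g = loss_and_grad(zt, arch, Xc, Xp, y, lambda_reg)
    return g.imag / _CSTEP


# ---------------------------------------------------------------------------
# public model surface


def nll_loss(
    params: TowerParams, Xc, Xp, y, lambda_reg: float = 0.0
) -> float:
    """Regularized negative log-likelihood of a labelled feature batch."""
    return float(loss_value(params.theta, params.arch, np.asarray(Xc, float),
                            np.asarray(Xp, float), np.asarray(y, float), lambda_reg))


def predict_proba(x_c, x_p, params: TowerParams):
    """Active probability sigma(<NN(x_c|U), NN(x_p|V)>) for one pair or a batch."""
    Xc = np.atleast_2d(np.asarray(x_c, dtype=float))
    Xp = np.atleast_2d(np.asarray(x_p, dtype=float))
    if Xc.shape[1] != params.arch.d_c:
        raise ValueError(f"compound features have dim {Xc.shape[1]}, tower expects {params.arch.d_c}")
    if Xp.shape[1] != params.arch.d_p:
        raise ValueError(f"kinase features have dim {Xp.shape[1]}, tower expects {params.arch.d_p}")
    if Xc.shape[0] != Xp.shape[0]:
        if Xc.shape[0] == 1:
            Xc = np.broadcast_to(Xc, (Xp.shape[0], Xc.shape[1]))
        elif Xp.shape[0] == 1:
            Xp = np.broadcast_to(Xp, (Xc.shape[0], Xp.shape[1]))
        else:
            raise ValueError("mismatched batch sizes")
    z = forward_logits(params.theta, params.arch, Xc, Xp)
    p = np.clip(_sigmoid(z).real, PROB_EPS, 1.0 - PROB_EPS)
    return float(p[0]) if p.size == 1 and np.ndim(x_c) == 1 and np.ndim(x_p) == 1 else p


# ---------------------------------------------------------------------------
# supervised training


@dataclass
class TrainConfig:
    """Plain supervised training controls for the non-meta model."""

    lambda_reg: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    optimizer: str = "adam"
    hidden: tuple[int, ...] = (128,)
    embedding_dim: int = 64

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


class _Adam:
    def __init__(self, n, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, theta, grad):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pair_features(
    pairs: pd.DataFrame,
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
):
    """Row-aligned (Xc, Xp, y) arrays for a labelled pair frame."""
    for cid in pairs["compound_id"].unique():
        if cid not in compound_feats:
            raise KeyError(f"no compound features for id {cid!r}")
    for kid in pairs["kinase_id"].unique():
        if kid not in kinase_feats:
            raise KeyError(f"no kinase features for id {kid!r}")
    Xc = compound_feats.rows(list(pairs["compound_id"]))
    Xp = kinase_feats.rows(list(pairs["kinase_id"]))
    y = pairs["label"].to_numpy(dtype=float)
    return Xc, Xp, y


def fit_arrays(
    Xc, Xp, y,
    config: TrainConfig,
    arch: TowerArch | None = None,
    init: TowerParams | None = None,
) -> tuple[TowerParams, list[float]]:
    """Mini-batch training on pre-assembled arrays; returns params + loss history."""
    Xc = np.asarray(Xc, dtype=float)
    Xp = np.asarray(Xp, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty training set")
    if init is not None:
        params = init.copy()
        arch = params.arch
    else:
        if arch is None:
            arch = TowerArch(Xc.shape[1], Xp.shape[1],
                             hidden=tuple(config.hidden),
                             embedding_dim=config.embedding_dim)
        params = init_params(arch, seed=config.seed)
    theta = params.theta.copy()
    opt = _Adam(theta.size, config.learning_rate) if config.optimizer == "adam" else None
    rng = substream(config.seed, "train", "batches")
    n = len(y)
    bs = min(config.batch_size, n)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            loss, grad = loss_and_grad(theta, arch, Xc[idx], Xp[idx], y[idx],
                                       config.lambda_reg)
            epoch_losses.append(float(loss))
            if opt is not None:
                theta = opt.step(theta, grad)
            else:
                theta = theta - config.learning_rate * grad
        history.append(float(np.mean(epoch_losses)))
    return TowerParams(arch, theta), history


def train_supervised(
    pairs: pd.DataFrame,
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
    config: TrainConfig,
    init: TowerParams | None = None,
) -> tuple[TowerParams, list[float]]:
    """Train the two-tower model on an interaction table's labelled pairs."""
    Xc, Xp, y = pair_features(pairs, compound_feats, kinase_feats)
    return fit_arrays(Xc, Xp, y, config, init=init)


def predict_table(
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
    params: TowerParams,
    pairs: pd.DataFrame | None = None,
    compounds: Sequence[str] | None = None,
    kinases: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score requested pairs (or the compounds x kinases product).

    Returns one row per pair with columns compound_id, kinase_id, score,
    label_hat (1 iff score >= threshold).
    """
    if pairs is None:
        if compounds is None:
            compounds = compound_feats.ids
        if kinases is None:
            kinases = kinase_feats.ids
        pairs = pd.DataFrame(
            [(c, k) for c in compounds for k in kinases],
            columns=["compound_id", "kinase_id"],
        )
    else:
        pairs = pairs[["compound_id", "kinase_id"]].copy()
    if pairs.empty:
        return pairs.assign(score=[], label_hat=[])
    Xc = compound_feats.rows(list(pairs["compound_id"]))
    Xp = kinase_feats.rows(list(pairs["kinase_id"]))
    scores = np.atleast_1d(predict_proba(Xc, Xp, params))
    out = pairs.reset_index(drop=True)
    out["score"] = scores
    out["label_hat"] = (scores >= threshold).astype(int)
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: TowerParams, directory: str, manifest_extra: dict | None = None):
    """Write one array file per tower layer plus a JSON manifest."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    layers_c, layers_p = params.layers()
    arrays = {}
    for tower, layers in (("compound", layers_c), ("kinase", layers_p)):
        for i, (W, b) in enumerate(layers):
            arrays[f"{tower}_W{i}"] = W
            arrays[f"{tower}_b{i}"] = b
    np.savez(d / "towers.npz", **arrays)
    manifest = {"arch": params.arch.to_dict(), **(manifest_extra or {})}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_checkpoint(directory: str) -> tuple[TowerParams, dict]:
    d = pathlib.Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    arch = TowerArch.from_dict(manifest["arch"])
    theta = np.zeros(arch.n_params)
    layers_c, layers_p = _unpack(theta, arch)
    with np.load(d / "towers.npz") as z:
        for tower, layers in (("compound", layers_c), ("kinase", layers_p)):
            for i, (W, b) in enumerate(layers):
                W[...] = z[f"{tower}_W{i}"]
                b[...] = z[f"{tower}_b{i}"]
    return TowerParams(arch, theta), manifest
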