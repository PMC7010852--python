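"""Denoising autoencoder for dense, noisy feature tables.

Microarray-style expression tables and homolog-phenotype blocks are wide,
highly correlated and noisy.  A denoising autoencoder corrupts each input,
then trains an encoder/decoder stack to reconstruct the *clean* input,
forcing the bottleneck code to capture the stable structure of the data
rather than copy it.  The bottleneck activations are the compact features
fed to the matrix-completion stage.

The trainer is a self-contained numpy implementation of minibatch Adam with
backpropagation; widths used here are desk-scale, so no GPU framework is
needed.  Training is fully deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DAEConfig", "DAEModel", "corrupt", "train_dae", "encode", "reconstruction_error"]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class DAEConfig:
    """Architecture and training hyperparameters.

    ``layer_sizes`` are the encoder widths only (e.g. ``[3000, 800, 300, 100]``
    for a four-layer gene-expression encoder); the decoder mirrors them
    symmetrically with untied weights.  ``noise_factor`` is the standard
    deviation of the additive Gaussian corruption (default 0.2), or the
    masking probability when ``corruption="mask"``.
    """

    layer_sizes: list[int]
    noise_factor: float = 0.2
    activation: str = "sigmoid"
    batch_size: int = 150
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    corruption: str = "gaussian"
    scale_input: bool = True

    def __post_init__(self) -> None:
        if not self.layer_sizes or any(w < 1 for w in self.layer_sizes):
            raise ValueError("layer_sizes must be a non-empty list of positive ints")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be nonnegative")
        if self.activation not in ("sigmoid", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.corruption not in ("gaussian", "mask"):
            raise ValueError(f"unknown corruption {self.corruption!r}")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


@dataclass
class DAEModel:
    """Trained autoencoder: full weight stack plus the input scaler."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_encoder_layers: int
    activation: str
    feature_min: np.ndarray | None
    feature_range: np.ndarray | None
    loss_history: list[float] = field(default_factory=list)

    @property
    def code_dim(self) -> int:
        return self.weights[self.n_encoder_layers - 1].shape[1]


def corrupt(
    data: np.ndarray, noise_factor: float, seed: int, mode: str = "gaussian"
) -> np.ndarray:
    """Corrupt a data matrix, deterministically for a given seed.

    ``"gaussian"`` adds i.i.d. noise with standard deviation ``noise_factor``;
    ``"mask"`` zeroes each entry independently with probability
    ``noise_factor`` (dropout-style feature discarding).
    """
    data = np.asarray(data, dtype=float)
    if noise_factor < 0:
        raise ValueError("noise_factor must be nonnegative")
    rng = np.random.default_rng(seed)
    if mode == "gaussian":
        if noise_factor == 0:
            return data.copy()
        return data + rng.normal(0.0, noise_factor, size=data.shape)
    if mode == "mask":
        return data * (rng.random(data.shape) >= noise_factor)
    raise ValueError(f"unknown corruption mode {mode!r}")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return z


def _act_grad_from_output(a: np.ndarray, kind: str) -> np.ndarray:
    return a * (1.0 - a) if kind == "sigmoid" else np.ones_like(a)


def _forward(x: np.ndarray, W: list[np.ndarray], b: list[np.ndarray], kind: str):
    acts = [x]
    for Wi, bi in zip(W, b):
        acts.append(_act(acts[-1] @ Wi + bi, kind))
    return acts


def _minmax_fit(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = data.min(axis=0)
    span = data.max(axis=0) - lo
    # constant (zero-span) features scale to 0.5, the sigmoid midpoint
    lo = np.where(span == 0, lo - 0.5, lo)
    span = np.where(span == 0, 1.0, span)
    return lo, span


def train_dae(data: np.ndarray, cfg: DAEConfig) -> DAEModel:
    """Train the corruption-then-reconstruct stack with minibatch Adam.

    Minimizes mean squared error between the clean (scaled) input and the
    decoder output for corrupted input.  One loss-history entry per epoch
    (mean over minibatches).  Fully reproducible given ``cfg.seed``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.size == 0:
        raise ValueError("data must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite entries")

    if cfg.scale_input:
        lo, span = _minmax_fit(data)
        X = (data - lo) / span
    else:
        lo = span = None
        X = data

    n, f = X.shape
    widths = [f] + list(cfg.layer_sizes) + list(reversed(cfg.layer_sizes[:-1])) + [f]
    rng = np.random.default_rng(cfg.seed)
    W = [
        rng.normal(0.0, np.sqrt(1.0 / widths[i]), size=(widths[i], widths[i + 1]))
        for i in range(len(widths) - 1)
    ]
    b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mb = [np.zeros_like(x) for x in b]
    vb = [np.zeros_like(x) for x in b]

    step = 0
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            clean = X[idx]
            if cfg.corruption == "gaussian":
                noisy = clean + rng.normal(0.0, cfg.noise_factor, clean.shape) \
                    if cfg.noise_factor > 0 else clean
            else:
                noisy = clean * (rng.random(clean.shape) >= cfg.noise_factor)
            acts = _forward(noisy, W, b, cfg.activation)
            out = acts[-1]
            diff = out - clean
            loss = float(np.mean(diff**2))
            epoch_losses.append(loss)

            delta = (2.0 / diff.size) * diff * _act_grad_from_output(out, cfg.activation)
            step += 1
            for li in range(len(W) - 1, -1, -1):
                gW = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ W[li].T) * _act_grad_from_output(
                        acts[li], cfg.activation
                    )
                for g, p, m, v in ((gW, W, mW, vW), (gb, b, mb, vb)):
                    m[li] = _ADAM_B1 * m[li] + (1 - _ADAM_B1) * g
                    v[li] = _ADAM_B2 * v[li] + (1 - _ADAM_B2) * g**2
                    mhat = m[li] / (1 - _ADAM_B1**step)
                    vhat = v[li] / (1 - _ADAM_B2**step)
                    p[li] = p[li] - cfg.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        history.append(float(np.mean(epoch_losses)))

    return DAEModel(
        weights=W,
        biases=b,
        n_encoder_layers=len(cfg.layer_sizes),
        activation=cfg.activation,
        feature_min=lo,
        feature_range=span,
        loss_history=history,
    )


def encode(data: np.ndarray, model: DAEModel) -> np.ndarray:
    """Bottleneck codes for (clean) data: forward pass through the encoder."""
    data = np.asarray(data, dtype=float)
    f_expected = model.weights[0].shape[0]
    if data.ndim != 2 or data.shape[1] != f_expected:
        raise ValueError(
            f"expected {f_expected} features, got {data.shape[1] if data.ndim == 2 else '?'}"
        )
    if model.feature_min is not None:
        data = (data - model.feature_min) / model.feature_range
    a = data
    for Wi, bi in zip(
        model.weights[: model.n_encoder_layers], model.biases[: model.n_encoder_layers]
    ):
        a = _act(a @ Wi + bi, model.activation)
    return a


def reconstruction_error(data: np.ndarray, model: DAEModel) -> float:
    """Mean squared reconstruction error of clean data, in scaled space."""
    data = np.asarray(data, dtype=float)
    if model.feature_min is not None:
        data = (data - model.feature_min) / model.feature_range
    acts = _forward(data, model.weights, model.biases, model.activation)
    return float(np.mean((acts[-1] - data) ** 2))
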