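"""Single-hidden-layer backpropagation network, written from scratch.

Architecture: N binary inputs, Y = 10 + N + Gamma sigmoid hidden
units, Gamma softmax outputs, trained on cross-entropy by per-sample
stochastic gradient descent.  Thresholds are carried as weights: an
extra input unit and an extra hidden unit are clamped to -1, so the
last row of each weight matrix holds the layer's thresholds (b_p for
the hidden layer, theta_q for the output layer) and the forward pass
is a plain matrix product.

For one sample (x, d) with one-hot target d:

    hn_p = sum_n w_np x_n - b_p          ho_p = sigmoid(hn_p)
    yn_q = sum_p v_pq ho_p - theta_q     yo   = softmax(yn)
    e    = -sum_q d_q ln(yo_q)

The output-layer error signal is delta_q = yo_q - d_q and the hidden
signal is sigma_p = (sum_q delta_q v_pq) * ho_p (1 - ho_p); both
layers are updated by descent, W <- W - eta * grad, scaled by the
sample's loss weight when weighted training is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from symdx.errors import TrainingError

HIDDEN_OFFSET = 10  # hidden width is this constant plus n_in plus n_out

_LOG_CLIP = 1e-12  # floor on softmax outputs inside the logarithm


def hidden_size(n_in: int, n_out: int) -> int:
    """Hidden-layer width Y = 10 + N + Gamma."""
    return HIDDEN_OFFSET + n_in + n_out


@dataclass
class NetworkParams:
    """Weights of the network; the bias rows are part of the matrices.

    ``w_in`` has shape (N+1, Y): row N+1 holds the hidden thresholds
    b_p (fed by the constant -1 input unit).  ``w_out`` has shape
    (Y+1, Gamma): row Y+1 holds the output thresholds theta_q.
    """

    n_in: int
    n_out: int
    n_hidden: int
    eta: float
    w_in: np.ndarray
    w_out: np.ndarray

    def __post_init__(self):
        if self.w_in.shape != (self.n_in + 1, self.n_hidden):
            raise ValueError(
                f"w_in shape {self.w_in.shape} != {(self.n_in + 1, self.n_hidden)}"
            )
        if self.w_out.shape != (self.n_hidden + 1, self.n_out):
            raise ValueError(
                f"w_out shape {self.w_out.shape} != {(self.n_hidden + 1, self.n_out)}"
            )
        if not (np.isfinite(self.w_in).all() and np.isfinite(self.w_out).all()):
            raise ValueError("network weights must be finite")
        if self.eta < 0:
            raise ValueError("learning rate eta must be nonnegative")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.n_in, self.n_out, self.n_hidden, self.eta,
                             self.w_in.copy(), self.w_out.copy())

    # -- persistence --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_hidden": self.n_hidden,
            "eta": self.eta,
            "w_in": self.w_in.tolist(),
            "w_out": self.w_out.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NetworkParams":
        return cls(
            n_in=payload["n_in"],
            n_out=payload["n_out"],
            n_hidden=payload["n_hidden"],
            eta=payload["eta"],
            w_in=np.asarray(payload["w_in"], dtype=float),
            w_out=np.asarray(payload["w_out"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ForwardTrace:
    """Intermediate activations of one forward pass."""

    hn: np.ndarray  # hidden-layer inputs, length Y
    ho: np.ndarray  # hidden-layer outputs (sigmoid), length Y
    yn: np.ndarray  # output-layer inputs, length Gamma
    yo: np.ndarray  # softmax outputs, length Gamma


def init_network(n_in: int, n_out: int, eta: float = 0.1,
                 seed: int | np.random.SeedSequence = 0) -> NetworkParams:
    """Create a network with uniform(-0.5, 0.5) weights from a seeded RNG."""
    if n_in < 1:
        raise ValueError(f"need at least one input unit, got n_in={n_in}")
    if n_out < 2:
        raise ValueError(f"need at least two output classes, got n_out={n_out}")
    if eta <= 0:
        raise ValueError(f"learning rate must be positive, got eta={eta}")
    y = hidden_size(n_in, n_out)
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5, 0.5, size=(n_in + 1, y))
    w_out = rng.uniform(-0.5, 0.5, size=(y + 1, n_out))
    return NetworkParams(n_in, n_out, y, eta, w_in, w_out)


def _augment(x: Sequence[float]) -> np.ndarray:
    """Append the constant -1 bias unit to an activation vector."""
    x = np.asarray(x, dtype=float)
    return np.concatenate([x, [-1.0]])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # split by sign to avoid overflow in exp for large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def forward(params: NetworkParams, x: Sequence[float]) -> ForwardTrace:
    """Run one sample through the network and keep all activations."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_in,):
        raise ValueError(f"input has shape {x.shape}, expected ({params.n_in},)")
    hn = _augment(x) @ params.w_in
    ho = _sigmoid(hn)
    yn = _augment(ho) @ params.w_out
    yo = _softmax(yn)
    return ForwardTrace(hn=hn, ho=ho, yn=yn, yo=yo)


def loss(yo: Sequence[float], d: Sequence[float], weight: float = 1.0) -> float:
    """Weighted cross-entropy  -w * sum_q d_q ln(yo_q)."""
    yo = np.asarray(yo, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(yo < 0):
        raise ValueError("output probabilities must be nonnegative")
    return float(-weight * np.sum(d * np.log(np.clip(yo, _LOG_CLIP, None))))


def gradients(params: NetworkParams, x: Sequence[float], d: Sequence[float],
              weight: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Analytic loss gradients for one sample.

    Returns ``(g_out, g_in)`` matching the shapes of ``w_out`` and
    ``w_in``; the bias rows fall out of the same outer products because
    the clamped -1 units are just ordinary activations.
    """
    trace = forward(params, x)
    d = np.asarray(d, dtype=float)
    delta = trace.yo - d                       # output error signal, per class
    ho_aug = _augment(trace.ho)
    g_out = weight * np.outer(ho_aug, delta)
    # back through the output weights (bias row excluded) and the sigmoid
    sigma = (params.w_out[: params.n_hidden] @ delta) * trace.ho * (1.0 - trace.ho)
    g_in = weight * np.outer(_augment(np.asarray(x, dtype=float))[: params.n_in + 1],
                             sigma)
    return g_out, g_in


def predict(params: NetworkParams, x: Sequence[float]) -> int:
    """Class index with maximal softmax output; ties go to the lowest index."""
    return int(np.argmax(forward(params, x).yo))


def train(params: NetworkParams,
          X: Sequence[Sequence[float]],
          D: Sequence[Sequence[float]],
          weights: Sequence[float] | None = None,
          epochs: int = 200,
          shuffle_seed: int | np.random.SeedSequence = 0,
          tol: float = 1e-6,
          patience: int = 10) -> tuple[NetworkParams, list[float]]:
    """Stochastic gradient descent over the sample set.

    Each epoch visits the samples once in a freshly shuffled order and
    applies ``W <- W - eta * grad`` after every sample.  Training stops
    early when the mean epoch loss has improved by less than ``tol``
    for ``patience`` consecutive epochs.

    Returns a trained copy of ``params`` (the input is not modified)
    and the per-epoch mean weighted loss.
    """
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a nonempty 2-D sample matrix")
    n_samples = X.shape[0]
    if X.shape[1] != params.n_in or D.shape != (n_samples, params.n_out):
        raise ValueError(
            f"samples {X.shape} / targets {D.shape} do not match network "
            f"dimensions N={params.n_in}, Gamma={params.n_out}"
        )
    if weights is None:
        w_vec = np.ones(n_samples)
    else:
        w_vec = np.asarray(weights, dtype=float)
        if w_vec.shape != (n_samples,):
            raise ValueError("weights must align one-to-one with samples")
        if np.any(w_vec <= 0):
            raise ValueError("sample weights must be positive")

    out = params.copy()
    w_in, w_out = out.w_in, out.w_out
    y = out.n_hidden
    eta = out.eta
    rng = np.random.default_rng(shuffle_seed)
    # pre-augmented inputs: constant -1 bias column
    X_aug = np.hstack([X, -np.ones((n_samples, 1))])

    history: list[float] = []
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        for k in order:
            a = X_aug[k]
            hn = a @ w_in
            ho = _sigmoid(hn)
            ho_aug = np.concatenate([ho, [-1.0]])
            yo = _softmax(ho_aug @ w_out)
            wk = w_vec[k]
            epoch_loss += -wk * np.log(max(yo[np.argmax(D[k])], _LOG_CLIP))
            delta = (yo - D[k]) * wk
            sigma = (w_out[:y] @ delta) * ho * (1.0 - ho)
            w_out -= eta * np.outer(ho_aug, delta)
            w_in -= eta * np.outer(a, sigma)
        mean_loss = epoch_loss / n_samples
        if not np.isfinite(mean_loss):
            raise TrainingError(
                f"non-finite training loss at epoch {epoch}", epoch=epoch
            )
        if history and history[-1] - mean_loss < tol:
            stall += 1
        else:
            stall = 0
        history.append(mean_loss)
        if stall >= patience:
            break
    return out, history


def one_hot(index: int, n_classes: int) -> np.ndarray:
    """Unit vector with a 1 at ``index`` (0-based)."""
    if not 0 <= index < n_classes:
        raise ValueError(f"class index {index} out of range 0..{n_classes - 1}")
    d = np.zeros(n_classes)
    d[index] = 1.0
    return d
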