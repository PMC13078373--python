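"""Feed-forward 1-3-2-1 tanh network for the intake-gain benchmark.

A small multilayer perceptron — one input (scaled ME intake), hidden layers
of 3 and 2 units, one output (scaled gain), hyperbolic tangent activation in
every layer *including the output* — trained on a 67/33 train/validation
split.  With biases the network has (1·3+3) + (3·2+2) + (2·1+1) = 17 free
parameters.

Because the output unit is a tanh, targets outside (-1, 1) are unreachable.
Inputs are z-score standardized; outputs are affinely mapped onto
[-0.8, 0.8] (midrange-centred) so every target sits strictly inside the
tanh range — a plain z-score would leave roughly a third of the targets
beyond |1| and cap the attainable fit.  Predictions invert the output map.
Training is full-batch gradient
descent with momentum and an accept/reject safeguard: a step that increases
the training loss is rolled back, the learning rate halved and the momentum
reset, so the loss over accepted steps is non-increasing.  Early stopping
monitors the validation loss with a patience window and the best-validation
weights are restored at the end.

Everything is deterministic given ``random_state``: the Xavier-uniform
initialization and the shuffle that assigns the validation split both come
from one seeded generator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .criteria import FitCriteria, criteria

HIDDEN_LAYERS = (3, 2)


def n_parameters(layer_sizes: Sequence[int]) -> int:
    """Weights plus biases for a fully connected net with these layer sizes."""
    return sum(
        n_in * n_out + n_out for n_in, n_out in zip(layer_sizes, layer_sizes[1:])
    )


class MLPGrowthRegressor(RegressorMixin, BaseEstimator):
    """From-scratch tanh MLP regressor, fixed 1-3-2-1 topology by default.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden-layer widths; (3, 2) gives the 1-3-2-1 network.
    validation_fraction : float
        Share of observations held out for early stopping; the validation
        count is round(n * fraction) after a seeded shuffle.
    learning_rate : float
        Initial step size on standardized data (adapted downward on
        rejected steps).
    momentum : float
        Classical momentum coefficient.
    max_epochs, patience : int
        Epoch cap and early-stopping patience on the validation loss.
    tol : float
        Stop when the training loss improves by less than this.
    random_state : int
        Seeds initialization and the split shuffle.

    Attributes
    ----------
    weights_, biases_ : lists of ndarrays, one per layer.
    training_criteria_, validation_criteria_ : FitCriteria per split
        (p counted as the 17 network parameters).
    n_parameters_ : int
    degenerate_ : bool
        True when the targets were constant and the model fell back to a
        mean predictor.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = HIDDEN_LAYERS,
        validation_fraction: float = 0.33,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        max_epochs: int = 20000,
        patience: int = 200,
        tol: float = 1e-14,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y lengths differ")
        n = x.size
        n_val = int(round(n * self.validation_fraction))
        if n_val < 1 or n - n_val < 1:
            raise ValueError(
                f"n={n} with validation_fraction={self.validation_fraction} "
                "leaves an empty split"
            )

        rng = np.random.default_rng(self.random_state)
        self.layer_sizes_ = (1, *self.hidden_layer_sizes, 1)
        self.n_parameters_ = n_parameters(self.layer_sizes_)

        perm = rng.permutation(n)
        self.val_indices_ = np.sort(perm[:n_val])
        self.train_indices_ = np.sort(perm[n_val:])

        self.input_mean_, self.input_scale_ = float(x.mean()), _scale(x)
        # output: midrange-centred map onto [-0.8, 0.8], inside the tanh range
        half_range = float(np.ptp(y)) / 2.0
        self.output_mean_ = float((y.max() + y.min()) / 2.0)
        self.output_scale_ = half_range / 0.8 if half_range > 0 else 1.0
        self.degenerate_ = bool(half_range == 0)

        W, B = _init_xavier(self.layer_sizes_, rng)
        if self.degenerate_:
            # constant targets: the zero network already predicts the mean
            W = [np.zeros_like(w) for w in W]
            B = [np.zeros_like(b) for b in B]
            self.weights_, self.biases_ = W, B
            self.loss_curve_ = [0.0]
            self.n_epochs_ = 0
            self._split_criteria(x, y)
            return self

        xs = (x - self.input_mean_) / self.input_scale_
        ys = (y - self.output_mean_) / self.output_scale_
        xt, yt = xs[self.train_indices_], ys[self.train_indices_]
        xv, yv = xs[self.val_indices_], ys[self.val_indices_]

        lr = self.learning_rate
        vel_W = [np.zeros_like(w) for w in W]
        vel_B = [np.zeros_like(b) for b in B]
        loss = _loss(W, B, xt, yt)
        best_val = _loss(W, B, xv, yv)
        best = ([w.copy() for w in W], [b.copy() for b in B])
        since_best = 0
        self.loss_curve_ = [loss]

        for epoch in range(self.max_epochs):
            gW, gB = _gradient(W, B, xt, yt)
            for i in range(len(W)):
                vel_W[i] = self.momentum * vel_W[i] - lr * gW[i]
                vel_B[i] = self.momentum * vel_B[i] - lr * gB[i]
            cand_W = [w + v for w, v in zip(W, vel_W)]
            cand_B = [b + v for b, v in zip(B, vel_B)]
            cand_loss = _loss(cand_W, cand_B, xt, yt)
            if cand_loss > loss:
                # reject: roll back, damp the step, kill the momentum
                lr *= 0.5
                vel_W = [np.zeros_like(w) for w in W]
                vel_B = [np.zeros_like(b) for b in B]
                if lr < 1e-12:
                    break
                continue
            # bold-driver recovery: cautiously regrow the step size
            lr = min(lr * 1.02, 10.0 * self.learning_rate)
            improved = loss - cand_loss
            W, B, loss = cand_W, cand_B, cand_loss
            self.loss_curve_.append(loss)

            val_loss = _loss(W, B, xv, yv)
            if val_loss < best_val - 1e-15:
                best_val = val_loss
                best = ([w.copy() for w in W], [b.copy() for b in B])
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
            if improved < self.tol:
                break

        self.weights_, self.biases_ = best
        self.n_epochs_ = len(self.loss_curve_) - 1
        self._split_criteria(x, y)
        return self

    def _split_criteria(self, x: np.ndarray, y: np.ndarray) -> None:
        pred = self.predict(x)
        p = self.n_parameters_
        self.training_criteria_ = criteria(
            y[self.train_indices_], pred[self.train_indices_], n_params=min(p, len(self.train_indices_) - 1)
        )
        self.validation_criteria_ = criteria(
            y[self.val_indices_], pred[self.val_indices_], n_params=min(p, len(self.val_indices_) - 1)
        )

    # -------------------------------------------------------------- predict

    def predict(self, X):
        check_is_fitted(self, "weights_")
        x = np.asarray(X, dtype=float).reshape(-1)
        xs = (x - self.input_mean_) / self.input_scale_
        out = _forward(self.weights_, self.biases_, xs)[-1].ravel()
        return out * self.output_scale_ + self.output_mean_

    # ------------------------------------------------------------ save/load

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "weights_")
        payload = {
            "layer_sizes": list(self.layer_sizes_),
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "input_scaler": [self.input_mean_, self.input_scale_],
            "output_scaler": [self.output_mean_, self.output_scale_],
            "random_state": self.random_state,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPGrowthRegressor":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        model = cls(
            hidden_layer_sizes=tuple(payload["layer_sizes"][1:-1]),
            random_state=payload["random_state"],
        )
        model.layer_sizes_ = tuple(payload["layer_sizes"])
        model.n_parameters_ = n_parameters(model.layer_sizes_)
        model.weights_ = [np.asarray(w, dtype=float) for w in payload["weights"]]
        model.biases_ = [np.asarray(b, dtype=float) for b in payload["biases"]]
        model.input_mean_, model.input_scale_ = payload["input_scaler"]
        model.output_mean_, model.output_scale_ = payload["output_scaler"]
        return model


# ------------------------------------------------------------------ numerics


def _scale(v: np.ndarray) -> float:
    s = float(v.std(ddof=0))
    return s if s > 0 else 1.0


def _init_xavier(layer_sizes, rng) -> tuple[list[np.ndarray], list[np.ndarray]]:
    W, B = [], []
    for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        W.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        B.append(np.zeros(n_out))
    return W, B


def _forward(W, B, x: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; tanh everywhere, output included."""
    acts = [np.asarray(x, dtype=float).reshape(-1, 1)]
    for w, b in zip(W, B):
        acts.append(np.tanh(acts[-1] @ w + b))
    return acts


def _loss(W, B, x: np.ndarray, y: np.ndarray) -> float:
    out = _forward(W, B, x)[-1].ravel()
    return float(np.mean((out - y) ** 2))


def _gradient(W, B, x: np.ndarray, y: np.ndarray):
    """Backpropagated gradient of the mean-squared loss w.r.t. W and B."""
    acts = _forward(W, B, x)
    n = x.size
    out = acts[-1]
    # dL/da_L for L = mean((a_L - y)^2)
    delta = 2.0 * (out - y.reshape(-1, 1)) / n
    gW = [np.empty_like(w) for w in W]
    gB = [np.empty_like(b) for b in B]
    for i in range(len(W) - 1, -1, -1):
        delta = delta * (1.0 - acts[i + 1] ** 2)  # tanh'
        gW[i] = acts[i].T @ delta
        gB[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ W[i].T
    return gW, gB
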