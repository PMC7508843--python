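"""Time-distributed weighted cross-entropy.

For a sequence of length ``l`` with targets ``y_t`` in {0, 1, 2} and
predictions ``yhat_t`` in (0, 1):

    loss = -(1/l) * sum_t (y_t * ln(yhat_t) + (1 - y_t) * ln(1 - yhat_t)) * lam[y_t]

``lam`` indexes a per-label weight vector; label 2 (padding) defaults to
weight 0, which masks padded positions.  The binary term is evaluated
literally for any numeric target, so nonzero ``lam[2]`` is permitted.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def weighted_cross_entropy(
    Y: np.ndarray, Yhat: np.ndarray, lam: tuple[float, float, float] = (1.0, 1.0, 0.0)
) -> float:
    """Mean over sequences of the time-distributed weighted cross-entropy.

    ``Y`` and ``Yhat`` are (B, l) (or (l,)); predictions are clipped to
    [EPS, 1 - EPS] before the logarithms.
    """
    Y = np.atleast_2d(np.asarray(Y))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: targets {Y.shape} vs predictions {Yhat.shape}")
    p = np.clip(Yhat, EPS, 1.0 - EPS)
    lam_arr = np.asarray(lam, dtype=float)
    w = lam_arr[Y.astype(int)]
    terms = (Y * np.log(p) + (1.0 - Y) * np.log(1.0 - p)) * w
    per_seq = -terms.sum(axis=1) / Y.shape[1]
    return float(per_seq.mean())


def loss_gradient_logits(
    Y: np.ndarray, Yhat: np.ndarray, lam: tuple[float, float, float] = (1.0, 1.0, 0.0)
) -> np.ndarray:
    """Gradient of the loss w.r.t. pre-sigmoid logits, averaged like the loss.

    For ``yhat = sigmoid(s)`` the per-timestep derivative is
    ``(yhat - y) * lam[y] / l`` (exact for any numeric target), divided by
    the batch size to match the batch-mean loss.
    """
    Y = np.atleast_2d(np.asarray(Y))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    B, l = Y.shape
    lam_arr = np.asarray(lam, dtype=float)
    w = lam_arr[Y.astype(int)]
    return (Yhat - Y) * w / (l * B)


def class_balance_weights(y: np.ndarray) -> tuple[float, float, float]:
    """Default label weights (1, #negatives/#positives, 0) from training
    targets (entries in {0, 1, 2}; label 2 ignored)."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise ValueError("degenerate labels: no progressor in training data")
    return (1.0, n_neg / n_pos if n_pos else 1.0, 0.0)
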