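"""Padding-based sequence augmentation.

A length-``n`` visit sequence yields ``n`` fixed-length training sequences:
the j-th contains the first j real visits followed by ``l - j`` post-padding
positions whose feature vector is all zeros and whose target is the padding
label 2.  Sequences longer than ``l`` are first truncated to their most
recent ``l`` visits.
"""

from __future__ import annotations

import numpy as np

#: Target value marking padded timesteps.
PAD_LABEL: int = 2


def augment_sequence(
    X: np.ndarray, y: np.ndarray, l: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand one sequence into its incremental padded prefixes.

    Parameters
    ----------
    X : (n, D) feature matrix, visits in time order.
    y : (n,) integer targets for each visit.
    l : padded sequence length.

    Returns
    -------
    Xa : (m, l, D) padded sequences, ``m = min(n, l)``.
    Ya : (m, l) targets, padding positions set to :data:`PAD_LABEL`.
    last_real : (m,) index of the last real timestep in each output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, D) and y must be (n,)")
    n, D = X.shape
    if n == 0:
        raise ValueError("cannot augment an empty sequence")
    if n > l:  # keep the most recent l visits
        X, y, n = X[-l:], y[-l:], l

    Xa = np.zeros((n, l, D), dtype=float)
    Ya = np.full((n, l), PAD_LABEL, dtype=int)
    for j in range(1, n + 1):
        Xa[j - 1, :j] = X[:j]
        Ya[j - 1, :j] = y[:j]
    last_real = np.arange(n)
    return Xa, Ya, last_real


def pad_single(X: np.ndarray, l: int) -> tuple[np.ndarray, int]:
    """Pad (or truncate to the most recent ``l`` visits) one sequence for
    inference.  Returns the (l, D) array and the index of the last real step."""
    X = np.asarray(X, dtype=float)
    n, D = X.shape
    if n == 0:
        raise ValueError("empty sequence")
    if n > l:
        X = X[-l:]
        n = l
    out = np.zeros((l, D), dtype=float)
    out[:n] = X
    return out, n - 1
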