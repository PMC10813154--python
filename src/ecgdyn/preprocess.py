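"""Lead normalisation and fixed-length windowing.

Each 10-s lead is first normalised, then de-meaned, then cut into
non-overlapping 1-s windows; every downstream quantity (sub-bands,
features) is computed per window.

Two normalisation conventions are provided:

``energy``
    y(n) = x(n) / sum_k x(k)^2 — division by the total energy.
``unit_energy``
    y(n) = x(n) / sqrt(sum_k x(k)^2) — the conventional scaling that
    leaves the signal with unit energy.

Both are followed by mean removal.  The two differ only by a positive
scale factor for a given input, which matters for the scale-sensitive
features (energy, entropies) but not for the scale-invariant ones.
"""

from __future__ import annotations

import numpy as np

__all__ = ["normalize_signal", "segment_windows", "DegenerateSignalError"]


class DegenerateSignalError(ValueError):
    """Raised for inputs on which the operation is undefined (e.g. all-zero)."""


def normalize_signal(x: np.ndarray, mode: str = "energy") -> np.ndarray:
    """Normalise a lead and remove its mean.

    Parameters
    ----------
    x : array-like
        Raw samples of one lead.
    mode : {"energy", "unit_energy"}
        Scaling convention (see module docstring).

    Returns
    -------
    numpy.ndarray
        Normalised, zero-mean copy of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateSignalError("empty signal")
    energy = float(np.sum(x * x))
    if energy == 0.0:
        raise DegenerateSignalError("all-zero signal cannot be normalised")
    if mode == "energy":
        y = x / energy
    elif mode == "unit_energy":
        y = x / np.sqrt(energy)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return y - y.mean()


def segment_windows(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Cut a lead into non-overlapping windows of ``window_s`` seconds.

    The trailing remainder shorter than one window is discarded, so the
    output is a ``(floor(N/W), W)`` array whose concatenation reproduces
    the first ``n_windows * W`` input samples exactly.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(fs * window_s))
    if w <= 0:
        raise ValueError("window length must be positive")
    n_windows = len(x) // w
    if n_windows < 1:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one window of {w}"
        )
    return x[: n_windows * w].reshape(n_windows, w)
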