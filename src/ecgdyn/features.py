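"""The 10 non-linear dynamics features computed on one sub-band segment.

Canonical feature order (fixed everywhere downstream):

====== =====================================================
ApEn   approximate entropy (Pincus, self-matches included)
CorrDim Grassberger-Procaccia correlation dimension
DFA    detrended fluctuation scaling exponent alpha
En     signal energy, sum |x|^2
H      Higuchi fractal dimension
EH     generalized Hurst exponent of order q
K      Katz fractal dimension
LogEn  log-energy entropy, sum log2 |x|^2
ELay   largest Lyapunov exponent (Rosenstein divergence fit)
ShaEn  Shannon (wavelet-style) energy entropy
====== =====================================================

All features are pure functions of ``(segment, params)``; degenerate
inputs (constant segments, vanishing variance) return the documented
sentinel values instead of NaN so the feature matrix is always finite.
Every hyperparameter lives in :class:`FeatureParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "FeatureParams", "FEATURE_NAMES", "approximate_entropy",
    "correlation_dimension", "detrended_fluctuation", "energy",
    "higuchi_fd", "hurst_exponent", "katz_fd", "log_energy_entropy",
    "lyapunov_exponent", "shannon_energy_entropy", "extract_all",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ApEn", "CorrDim", "DFA", "En", "H", "EH", "K", "LogEn", "ELay", "ShaEn",
)


@dataclass
class FeatureParams:
    """Hyperparameters of the 10 features.

    Defaults follow the standard literature choices: ApEn with m=2 and
    r = 0.2 x SD; correlation dimension in a 2-d delay embedding with a
    unit Theiler offset; first-order DFA on 12 log-spaced box sizes
    between 4 and N/4; Higuchi with kmax=10; generalized Hurst with
    q=2 over delays 2..19; Rosenstein Lyapunov fit over the first 10
    divergence steps.
    """

    apen_m: int = 2
    apen_r_factor: float = 0.2
    corrdim_embed: int = 2
    corrdim_delay: int = 1
    corrdim_theiler: int = 1
    corrdim_radii: int = 20
    dfa_order: int = 1
    dfa_scales: int = 12
    higuchi_kmax: int = 10
    hurst_q: int = 2
    hurst_taus: tuple[int, ...] = tuple(range(2, 20))
    lyap_embed: int = 5
    lyap_delay: int = 1
    lyap_min_steps: int = 10
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.apen_m < 1 or self.apen_r_factor <= 0:
            raise ValueError("apen_m >= 1 and apen_r_factor > 0 required")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if not self.hurst_taus:
            raise ValueError("hurst_taus must be non-empty")


def _fit_slope(logx: np.ndarray, logy: np.ndarray) -> float:
    """Least-squares slope of logy on logx."""
    if len(logx) < 2:
        return 0.0
    return float(np.polyfit(logx, logy, 1)[0])


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def approximate_entropy(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """ApEn(m, r) = Phi^m(r) - Phi^(m+1)(r), r = apen_r_factor x SD.

    Template matching uses the Chebyshev distance and includes
    self-matches (the original Pincus convention), so ApEn of a
    constant segment is exactly 0.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    m = p.apen_m
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"segment of {n} samples too short for ApEn with m={m}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = p.apen_r_factor * sd
    diff = np.abs(x[:, None] - x[None, :])

    def phi(mm: int) -> float:
        nt = n - mm + 1
        cheb = diff[:nt, :nt].copy()
        for k in range(1, mm):
            np.maximum(cheb, diff[k:k + nt, k:k + nt], out=cheb)
        counts = np.count_nonzero(cheb <= r, axis=1) / nt
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# Correlation dimension
# ---------------------------------------------------------------------------

def _delay_embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 2:
        raise ValueError("segment too short for the requested embedding")
    return np.column_stack([x[i * delay: i * delay + n] for i in range(dim)])


def correlation_dimension(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """Slope of log C(l) vs log l of the Grassberger-Procaccia sum.

    The correlation sum counts pairs of delay-embedded points closer
    than l, restricted to index offsets >= the Theiler offset k; the
    dimension is the least-squares slope over a log-spaced radius grid
    inside the scaling region (between the 2nd and 50th percentile of
    the pairwise distances).
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    emb = _delay_embed(x, p.corrdim_embed, p.corrdim_delay)
    M = len(emb)
    if M < 10:
        raise ValueError("fewer than 10 embedded points")
    d = pdist(emb)
    if p.corrdim_theiler > 1:
        # drop pairs with index offset below the Theiler window
        keep = np.ones(len(d), dtype=bool)
        pos = 0
        for i in range(M - 1):
            w = min(p.corrdim_theiler - 1, M - 1 - i)
            keep[pos: pos + w] = False
            pos += M - 1 - i
        d = d[keep]
    d = d[d > 0]
    if d.size < 10:
        return 0.0
    lo, hi = np.quantile(d, [0.02, 0.5])
    if not (lo > 0 and hi > lo):
        return 0.0
    radii = np.logspace(np.log10(lo), np.log10(hi), p.corrdim_radii)
    counts = np.searchsorted(np.sort(d), radii, side="right")
    mask = counts > 0
    if mask.sum() < 2:
        return 0.0
    c = counts[mask] / d.size
    return _fit_slope(np.log(radii[mask]), np.log(c))


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray, order: int) -> np.ndarray:
    y = np.cumsum(x - np.mean(x))
    out = np.empty(len(scales))
    for si, s in enumerate(scales):
        nb = len(y) // s
        boxes = y[: nb * s].reshape(nb, s)
        t = np.arange(s, dtype=float)
        # per-box polynomial detrend via a shared Vandermonde pseudo-inverse
        v = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(v, boxes.T, rcond=None)
        resid = boxes.T - v @ coef
        out[si] = np.sqrt(np.mean(resid ** 2))
    return out


def dfa_scale_grid(n: int, n_scales: int) -> np.ndarray:
    """Log-spaced integer box sizes from 4 to n/4 (unique, sorted)."""
    hi = max(n // 4, 5)
    grid = np.unique(np.round(np.logspace(np.log10(4), np.log10(hi),
                                          n_scales)).astype(int))
    return grid[grid >= 4]


def detrended_fluctuation(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """DFA scaling exponent alpha.

    The profile y(k) = cumsum(x - mean) is cut into non-overlapping
    boxes of each scale, detrended with a polynomial of ``dfa_order``,
    and alpha is the slope of log F(n) against log n, where F is the
    RMS residual.  White noise gives alpha ~ 0.5, a random walk ~ 1.5.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0.0:
        return 0.0
    scales = dfa_scale_grid(len(x), p.dfa_scales)
    if len(x) < 4 * scales[0]:
        raise ValueError("segment shorter than four minimum boxes")
    f = _dfa_fluctuations(x, scales, p.dfa_order)
    good = f > 0
    return _fit_slope(np.log(scales[good]), np.log(f[good]))


# ---------------------------------------------------------------------------
# Energy and entropies
# ---------------------------------------------------------------------------

def energy(x: np.ndarray) -> float:
    """Total energy sum |x(n)|^2."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def log_energy_entropy(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """Log-energy entropy sum_n log2 |x(n)|^2, floored at eps."""
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    return float(np.sum(np.log2(np.maximum(x * x, p.eps))))


def shannon_energy_entropy(
    x: np.ndarray, p: FeatureParams | None = None, normalized: bool = False
) -> float:
    """Shannon energy entropy -sum |x|^2 log2 |x|^2.

    The default operates on raw squared amplitudes (wavelet-entropy
    style); ``normalized=True`` first converts them to probabilities
    p(n) = |x|^2 / sum |x|^2, giving the classical Shannon entropy in
    bits.  Both coincide when the segment has unit energy.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    e = x * x
    if normalized:
        tot = e.sum()
        if tot == 0.0:
            return 0.0
        e = e / tot
    return float(-np.sum(e * np.log2(np.maximum(e, p.eps))))


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """Higuchi fractal dimension from averaged curve lengths L(k).

    Slope of ln L(k) vs ln(1/k) for k = 1..kmax; ~1 for smooth curves,
    ~2 for white noise.  Constant segments return 1.0 by convention.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    kmax = p.higuchi_kmax
    if n <= 2 * kmax:
        raise ValueError(f"segment of {n} samples too short for kmax={kmax}")
    if np.std(x) == 0.0:
        return 1.0
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    good = lk > 0
    if good.sum() < 2:
        return 1.0
    k_arr = np.arange(1, kmax + 1)[good]
    return _fit_slope(np.log(1.0 / k_arr), np.log(lk[good]))


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension K = log10(n') / (log10(n') + log10(d/L)).

    L is the total path length over unit abscissa steps, d the maximum
    Euclidean distance from the first point, n' = N - 1 the number of
    steps.  A straight line gives exactly 1; degenerate inputs return 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Katz dimension needs at least 3 samples")
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    L = float(np.sum(steps))
    i = np.arange(n, dtype=float)
    d = float(np.max(np.sqrt(i ** 2 + (x - x[0]) ** 2)[1:]))
    if d == 0.0 or L == 0.0:
        return 1.0
    n_steps = n - 1
    denom = np.log10(n_steps) + np.log10(d / L)
    if denom == 0.0:
        return 1.0
    return float(np.log10(n_steps) / denom)


# ---------------------------------------------------------------------------
# Hurst exponent
# ---------------------------------------------------------------------------

def hurst_exponent(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """Generalized Hurst exponent EH(q) from q-th order structure functions.

    The segment is treated as the increments of a walk: the moment
    ratio K_q(tau) = <|Y(t+tau) - Y(t)|^q> is computed on the profile
    Y = cumsum(x - mean), and EH is the regression slope of log K_q on
    log tau divided by q.  Uncorrelated increments give EH ~ 0.5;
    strongly trending segments approach 1.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    taus = np.asarray(p.hurst_taus, dtype=int)
    if len(x) <= 4 * taus.max():
        raise ValueError("segment too short for the requested tau range")
    if np.std(x) == 0.0:
        return 0.5
    y = np.cumsum(x - np.mean(x))
    kq = np.empty(len(taus))
    for i, tau in enumerate(taus):
        kq[i] = np.mean(np.abs(y[tau:] - y[:-tau]) ** p.hurst_q)
    good = kq > 0
    if good.sum() < 2:
        return 0.5
    slope = _fit_slope(np.log(taus[good]), np.log(kq[good]))
    return slope / p.hurst_q


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent
# ---------------------------------------------------------------------------

def _mean_period(x: np.ndarray) -> int:
    """Mean period from the dominant non-DC Fourier component."""
    spec = np.abs(np.fft.rfft(x - np.mean(x)))
    if len(spec) < 2:
        return 1
    k = int(np.argmax(spec[1:])) + 1
    return max(1, int(round(len(x) / k)))


def lyapunov_exponent(x: np.ndarray, p: FeatureParams | None = None) -> float:
    """Largest Lyapunov exponent per sample (Rosenstein estimator).

    Each delay-embedded point is paired with its nearest neighbour
    outside a Theiler window of one mean period; the mean log distance
    between pairs is tracked over ``lyap_min_steps`` steps and the
    exponent is the slope of that divergence curve, fitted only below
    the saturation level (half the attractor diameter).  Regular
    dynamics give ~0, chaotic dynamics a positive rate.  Returns 0
    when no valid neighbour pairs exist.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    if len(x) < 200:
        raise ValueError("Lyapunov estimation needs at least 200 samples")
    if np.std(x) == 0.0:
        return 0.0
    emb = _delay_embed(x, p.lyap_embed, p.lyap_delay)
    steps = p.lyap_min_steps
    M = len(emb) - steps
    if M < 20:
        return 0.0
    theiler = min(_mean_period(x), M // 4)
    dists = cdist(emb[:M], emb[:M])
    idx = np.arange(M)
    band = np.abs(idx[:, None] - idx[None, :]) <= theiler
    dists[band] = np.inf
    nn = np.argmin(dists, axis=1)
    d0 = dists[idx, nn]
    valid = np.isfinite(d0) & (d0 > 0)
    if valid.sum() < 10:
        return 0.0
    i_idx, j_idx = idx[valid], nn[valid]
    div = np.empty(steps + 1)
    for k in range(steps + 1):
        dk = np.linalg.norm(emb[i_idx + k] - emb[j_idx + k], axis=1)
        dk = np.maximum(dk, p.eps)
        div[k] = np.mean(np.log(dk))
    # fit below saturation: half the mean inter-point distance (log scale)
    finite = dists[np.isfinite(dists)]
    sat = np.log(np.mean(finite) / 2.0) if finite.size else np.inf
    keep = div <= sat
    keep[: 2] = True  # always keep the first two points
    ks = np.flatnonzero(keep)
    if len(ks) < 2:
        return 0.0
    return _fit_slope(ks.astype(float), div[ks])


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_all(x: np.ndarray, p: FeatureParams | None = None) -> dict[str, float]:
    """All 10 features of one segment, in canonical order.

    Deterministic given ``(x, p)``; any non-finite intermediate result
    is replaced by the feature's degenerate sentinel so the output is
    always finite.
    """
    p = p or FeatureParams()
    x = np.asarray(x, dtype=float)
    values = {
        "ApEn": approximate_entropy(x, p),
        "CorrDim": correlation_dimension(x, p),
        "DFA": detrended_fluctuation(x, p),
        "En": energy(x),
        "H": higuchi_fd(x, p),
        "EH": hurst_exponent(x, p),
        "K": katz_fd(x),
        "LogEn": log_energy_entropy(x, p),
        "ELay": lyapunov_exponent(x, p),
        "ShaEn": shannon_energy_entropy(x, p),
    }
    sentinels = {"ApEn": 0.0, "CorrDim": 0.0, "DFA": 0.0, "En": 0.0,
                 "H": 1.0, "EH": 0.5, "K": 1.0, "LogEn": 0.0,
                 "ELay": 0.0, "ShaEn": 0.0}
    return {
        name: (values[name] if np.isfinite(values[name]) else sentinels[name])
        for name in FEATURE_NAMES
    }
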