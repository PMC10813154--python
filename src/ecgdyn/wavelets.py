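"""Octave-band DWT decomposition of ECG windows into full-rate sub-bands.

A critically decimated wavelet filter bank of depth ``S`` (default 3,
Symlet7) splits each 1-s window into ``S + 1`` octave sub-bands.  With
the normalised angular frequency pi mapped to fs/2, band m = 0 is the
approximation band [0, pi/2^S] and band m >= 1 is the detail band
[pi/2^(S-m+1), pi/2^(S-m)]; frequency rises with m, so at fs = 1000 Hz
and S = 3 the bands are 0-62.5, 62.5-125, 125-250 and 250-500 Hz.

Each sub-band is returned as a full-rate series of the window length.
The default strategy reconstructs the band by zeroing every other
coefficient level and inverting the transform, which is exactly
length-preserving; cubic interpolation of the decimated coefficients is
available as an alternative resampling strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .records import ECGRecord

__all__ = ["FilterBank", "SubBandSpec", "SubBandSignals", "band_edges",
           "decompose_window", "decompose_record"]


@dataclass
class FilterBank:
    """Analysis filter pair and decomposition depth.

    The quadrature-mirror relation between the low- and high-pass
    impulse responses is asserted at construction.
    """

    wavelet_name: str = "sym7"
    S: int = 3
    boundary: str = "symmetric"
    hLP: np.ndarray = field(init=False, repr=False)
    hHP: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        w = pywt.Wavelet(self.wavelet_name)
        self.hLP = np.asarray(w.dec_lo, dtype=float)
        self.hHP = np.asarray(w.dec_hi, dtype=float)
        # QMF relation: hHP(n) = (-1)^n hLP(L-1-n)
        signs = (-1.0) ** np.arange(len(self.hLP))
        mirrored = signs * self.hLP[::-1]
        if not (np.allclose(self.hHP, mirrored, atol=1e-10)
                or np.allclose(self.hHP, -mirrored, atol=1e-10)):
            raise ValueError(
                f"wavelet {self.wavelet_name!r} filters violate the "
                "quadrature-mirror relation"
            )

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.wavelet_name)

    @property
    def n_bands(self) -> int:
        return self.S + 1

    def min_window_length(self) -> int:
        """Smallest window for which a depth-S decomposition is meaningful."""
        return (self.wavelet.dec_len - 1) * 2 ** self.S


@dataclass(frozen=True)
class SubBandSpec:
    """One octave band: index, normalised-frequency interval, Hz interval."""

    m: int
    band: tuple[Fraction, Fraction]  # in units of pi
    band_hz: tuple[float, float]

    @property
    def width_hz(self) -> float:
        return self.band_hz[1] - self.band_hz[0]


@dataclass
class SubBandSignals:
    """The S+1 full-rate sub-band series for one window."""

    bands: list[np.ndarray]
    spec: list[SubBandSpec]

    def __len__(self) -> int:
        return len(self.bands)


def band_edges(S: int, fs: float) -> list[SubBandSpec]:
    """Octave band intervals for depth ``S`` at sampling rate ``fs``.

    Band 0 is [0, pi/2^S]; band m >= 1 is [pi/2^(S-m+1), pi/2^(S-m)],
    with pi corresponding to fs/2.  The S+1 intervals tile (0, fs/2]
    exactly (checked with rational arithmetic in the tests).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    nyquist = fs / 2.0
    specs = []
    for m in range(S + 1):
        if m == 0:
            lo, hi = Fraction(0), Fraction(1, 2 ** S)
        else:
            lo, hi = Fraction(1, 2 ** (S - m + 1)), Fraction(1, 2 ** (S - m))
        specs.append(
            SubBandSpec(m=m, band=(lo, hi),
                        band_hz=(float(lo) * nyquist, float(hi) * nyquist))
        )
    return specs


def _coeff_index(m: int, S: int) -> int:
    # wavedec returns [cA_S, cD_S, cD_{S-1}, ..., cD_1]; band m=0 is cA_S,
    # band m>=1 (rising frequency) is cD_{S-m+1}, i.e. list index m.
    return m


def decompose_window(
    w: np.ndarray,
    bank: FilterBank | None = None,
    fs: float = 1000.0,
    resample: str = "reconstruct",
) -> SubBandSignals:
    """Split one window into S+1 full-rate sub-band signals.

    Parameters
    ----------
    w : array-like
        The window samples.
    bank : FilterBank
        Wavelet and depth; defaults to Symlet7 at S=3.
    fs : float
        Sampling rate, used only to label the bands in Hz.
    resample : {"reconstruct", "coef_interp"}
        ``reconstruct`` inverts the DWT keeping only one level at a
        time (band-limited reconstruction, sums back to the input);
        ``coef_interp`` cubic-interpolates each decimated coefficient
        sequence up to the window length.
    """
    bank = bank or FilterBank()
    w = np.asarray(w, dtype=float)
    n = len(w)
    if n < bank.min_window_length():
        raise ValueError(
            f"window of {n} samples is too short for a depth-{bank.S} "
            f"decomposition with {bank.wavelet_name} "
            f"(needs >= {bank.min_window_length()})"
        )
    coeffs = pywt.wavedec(w, bank.wavelet, mode=bank.boundary, level=bank.S)
    specs = band_edges(bank.S, fs)
    bands: list[np.ndarray] = []
    for m in range(bank.S + 1):
        idx = _coeff_index(m, bank.S)
        if resample == "reconstruct":
            keep = [c if i == idx else np.zeros_like(c) for i, c in enumerate(coeffs)]
            rec = pywt.waverec(keep, bank.wavelet, mode=bank.boundary)
            bands.append(rec[:n])
        elif resample == "coef_interp":
            c = coeffs[idx]
            if len(c) < 4:
                bands.append(np.interp(np.linspace(0, len(c) - 1, n),
                                       np.arange(len(c)), c))
            else:
                spline = CubicSpline(np.linspace(0.0, 1.0, len(c)), c)
                bands.append(spline(np.linspace(0.0, 1.0, n)))
        else:
            raise ValueError(f"unknown resample strategy {resample!r}")
    return SubBandSignals(bands=bands, spec=specs)


def decompose_record(
    rec: ECGRecord,
    bank: FilterBank | None = None,
    window_s: float = 1.0,
    resample: str = "reconstruct",
) -> dict[str, list[SubBandSignals]]:
    """Decompose every lead of a record, window by window.

    Returns ``{lead: [SubBandSignals per window]}`` in canonical lead
    order; each lead yields ``floor(N / (fs * window_s))`` windows.
    """
    from .preprocess import segment_windows

    bank = bank or FilterBank()
    out: dict[str, list[SubBandSignals]] = {}
    for lead, x in rec.leads.items():
        windows = segment_windows(x, rec.fs, window_s)
        out[lead] = [
            decompose_window(w, bank, fs=rec.fs, resample=resample)
            for w in windows
        ]
    return out
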