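"""Oscillatory power spectra of insect transits and the three polarimetric dataset modes.

Each observation carries a co-polarized and a de-polarized intensity waveform
sampled at 2 kHz.  Wingbeat modulation is summarized as a Welch power spectral
density evaluated on a fixed axis of 80 linearly spaced frequency bins between
25 Hz (the reciprocal of the minimum 40 ms transit) and 1000 Hz (Nyquist).

From a spectrum pair three feature constructions are derived, emulating three
acquisition scenarios:

``unpol``
    no polarimetry: the summed spectrum, area-normalized to unity,
``copol``
    co-polarized acquisition only, area-normalized to unity,
``dolp``
    the co-polarized spectrum normalized by the *total* area, so the area
    under the vector equals the degree of linear polarization (co-fraction)
    of the oscillatory signal.

The DoLP used throughout is the co-polarized fraction of oscillatory power,
sum(P_co) / sum(P_co + P_de) over 25-1000 Hz: 1 for perfectly
polarization-preserving (glossy) backscatter, 0.5 for fully randomized
polarization.  Note this differs from the conventional (co-de)/(co+de).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

FS_HZ = 2000.0
N_BINS = 80
F_MIN_HZ = 25.0
F_MAX_HZ = 1000.0

#: minimum waveform length accepted by :func:`welch_psd` (40 ms at 2 kHz)
MIN_SAMPLES = 80

# Welch parameters: segment length equals the 40 ms minimum observation,
# Gaussian window FWHM of half the segment, maximum overlap.
_NPERSEG = 80
_NOVERLAP = 79
_GAUSS_STD = (_NPERSEG / 2) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
# fine FFT grid from which the 80-bin axis is interpolated (7.8 Hz spacing,
# well below both the 12.3 Hz bin spacing and the ~50 Hz window main lobe)
_NFFT = 256

LOG_EPS = 1e-12


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum pair carries no power at all."""


@dataclass(frozen=True)
class FrequencyAxis:
    n_bins: int = N_BINS
    f_min: float = F_MIN_HZ
    f_max: float = F_MAX_HZ

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_bins)


#: the default axis shared by every spectrum in a run
AXIS = FrequencyAxis()
FREQS_HZ = AXIS.values


@dataclass
class SpectrumPair:
    """Co- and de-polarized Welch power spectra on the common 80-bin axis."""

    p_co: np.ndarray
    p_de: np.ndarray
    axis: FrequencyAxis = field(default_factory=FrequencyAxis)

    def __post_init__(self) -> None:
        self.p_co = np.asarray(self.p_co, dtype=float)
        self.p_de = np.asarray(self.p_de, dtype=float)
        if self.p_co.shape != (self.axis.n_bins,) or self.p_de.shape != (self.axis.n_bins,):
            raise ValueError("spectrum vectors must match the frequency axis length")
        if np.any(self.p_co < 0) or np.any(self.p_de < 0):
            raise ValueError("power spectra must be nonnegative")


def welch_psd(waveform: np.ndarray) -> np.ndarray:
    """Welch power spectral density of a 2 kHz waveform on the 80-bin axis.

    Segments of 80 samples with 79 overlapping samples (the maximum possible
    overlap) are tapered by a Gaussian window whose FWHM is half the segment
    length.  The averaged periodogram is computed on a fine FFT grid and
    interpolated onto the 80 linearly spaced bins spanning 25-1000 Hz.

    Two numerical choices: the mean of each segment is removed before
    windowing, so the strong quasi-DC component of the transit envelope does
    not leak through the short window's main lobe into the lowest bins; and
    the Nyquist ordinate of the one-sided density is doubled so a flat
    spectrum stays flat across the whole axis.

    Parameters
    ----------
    waveform
        Intensity samples at 2 kHz; at least 80 samples (a 40 ms transit).

    Returns
    -------
    ndarray of shape (80,) with nonnegative power values.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if x.size < MIN_SAMPLES:
        raise ValueError(
            f"waveform has {x.size} samples; at least {MIN_SAMPLES} (40 ms) required"
        )
    window = signal.windows.gaussian(_NPERSEG, std=_GAUSS_STD)
    freqs, pxx = signal.welch(
        x,
        fs=FS_HZ,
        window=window,
        nperseg=_NPERSEG,
        noverlap=_NOVERLAP,
        nfft=_NFFT,
        detrend="constant",
        scaling="density",
    )
    pxx = pxx.copy()
    pxx[-1] *= 2.0  # one-sided density: restore the un-mirrored Nyquist bin
    out = np.interp(FREQS_HZ, freqs, pxx)
    return np.maximum(out, 0.0)


def spectrum_pair(waveform_co: np.ndarray, waveform_de: np.ndarray) -> SpectrumPair:
    """Welch spectra of both polarization channels of one observation."""
    return SpectrumPair(p_co=welch_psd(waveform_co), p_de=welch_psd(waveform_de))


def build_datasets(pair: SpectrumPair) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three raw (pre-log) feature constructions from one spectrum pair.

    Returns ``(unpol, copol, dolp)`` where ``unpol`` and ``copol`` integrate
    to one and the ``dolp`` vector integrates to the observation's
    co-fraction DoLP.
    """
    total = float(np.sum(pair.p_co) + np.sum(pair.p_de))
    if total <= 0.0:
        raise DegenerateSpectrumError("spectrum pair has zero total power")
    unpol = (pair.p_co + pair.p_de) / total
    co_sum = float(np.sum(pair.p_co))
    if co_sum > 0.0:
        copol = pair.p_co / co_sum
    else:
        copol = np.zeros_like(pair.p_co)
    dolp = pair.p_co / total
    return unpol, copol, dolp


def observation_dolp(pair: SpectrumPair) -> float:
    """Co-polarized fraction of oscillatory power (25-1000 Hz) in [0, 1]."""
    total = float(np.sum(pair.p_co) + np.sum(pair.p_de))
    if total <= 0.0:
        raise DegenerateSpectrumError("spectrum pair has zero total power")
    return float(np.sum(pair.p_co) / total)


def lognorm(raw: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    """Natural log of an (already area-normalized) spectrum with a finite floor.

    ``eps`` is far below any physical bin mass of a unit-area spectrum and
    exists only to keep empty bins finite.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw spectrum must be nonnegative")
    return np.log(raw + eps)


def detrend(logspec: np.ndarray) -> np.ndarray:
    """Remove the least-squares line over bin index (visualization support only)."""
    y = np.asarray(logspec, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two bins to detrend")
    idx = np.arange(y.size, dtype=float)
    coeffs = np.polyfit(idx, y, deg=1)
    return y - np.polyval(coeffs, idx)


def feature_matrix(
    pairs: list[SpectrumPair], mode: str, eps: float = LOG_EPS
) -> np.ndarray:
    """Stacked log-transformed feature vectors for one dataset mode.

    Parameters
    ----------
    pairs
        Spectrum pairs, one per observation.
    mode
        One of ``unpol``, ``copol``, ``dolp``.
    """
    if mode not in ("unpol", "copol", "dolp"):
        raise ValueError(f"unknown dataset mode {mode!r}")
    rows = []
    for pair in pairs:
        unpol, copol, dolp = build_datasets(pair)
        raw = {"unpol": unpol, "copol": copol, "dolp": dolp}[mode]
        rows.append(lognorm(raw, eps))
    return np.asarray(rows)
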