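"""Broadband-gamma envelope extraction and related filtering.

The envelope estimator is a frequency-domain bandpass Hilbert transform:
the FFT of the signal is converted to the analytic spectrum (negative
frequencies zeroed, positive doubled), weighted by a band filter built from
paired logistic (sigmoid) flanks with a fixed half-width in Hz, inverse
transformed, and its magnitude taken.  The default band is 70-150 Hz with
1.5 Hz flanks; the analytic amplitude is smoothed with a third-order
Savitzky-Golay FIR of 151 ms frame length.

The FFT length equals the signal length (no padding); flank half-width is
fixed in Hz regardless of length.  The first and last half-frame of any
smoothed series is edge-contaminated and flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import expit


@dataclass(frozen=True)
class BandSpec:
    """Band edges and logistic-flank half-width, in Hz."""

    f_lo: float = 70.0
    f_hi: float = 150.0
    flank_halfwidth: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.flank_halfwidth <= 0:
            raise ValueError("flank half-width must be > 0")

    def validate_against_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(f"band upper edge {self.f_hi} Hz at or above Nyquist ({fs / 2} Hz)")


def sigmoid_band_weights(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    """Bandpass weights w(f) = sigma((f-f_lo)/h) * sigma((f_hi-f)/h).

    sigma is the logistic function, h the flank half-width; w = 0.5 at each
    band edge and saturates to 1 deep inside the band.
    """
    freqs = np.asarray(freqs, dtype=float)
    h = band.flank_halfwidth
    return expit((freqs - band.f_lo) / h) * expit((band.f_hi - freqs) / h)


def hilbert_bandpass_amplitude(x: np.ndarray, fs: float, band: BandSpec | None = None) -> np.ndarray:
    """Analytic amplitude of the band-limited signal (the envelope).

    Works on the last axis.  Linear in the input amplitude: doubling the
    signal doubles the envelope.
    """
    band = band or BandSpec()
    band.validate_against_fs(fs)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 4 * fs / band.f_lo:
        raise ValueError("signal too short for the requested band")
    spec = np.fft.fft(x, axis=-1)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    # analytic-signal construction: keep DC and Nyquist as-is, double
    # positive frequencies, zero negative ones, then apply band weights
    mult = np.zeros(n)
    mult[freqs > 0] = 2.0
    mult[0] = 1.0
    if n % 2 == 0:
        mult[n // 2] = 1.0
    weights = sigmoid_band_weights(np.abs(freqs), band)
    analytic = np.fft.ifft(spec * (mult * weights), axis=-1)
    return np.abs(analytic)


def bandlimit_voltage(x: np.ndarray, fs: float, band: BandSpec | None = None) -> np.ndarray:
    """Band-limited voltage trace (zero-phase), NOT its envelope.

    Applies the same sigmoid band weights symmetrically to positive and
    negative frequencies, so the output is real and has zero phase shift.
    Its analytic amplitude equals ``hilbert_bandpass_amplitude`` output.
    """
    band = band or BandSpec()
    band.validate_against_fs(fs)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.fft(x, axis=-1)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    weights = sigmoid_band_weights(np.abs(freqs), band)
    return np.real(np.fft.ifft(spec * weights, axis=-1))


def frame_ms_to_samples(frame_ms: float, fs: float) -> int:
    """Convert a frame length in ms to the nearest odd sample count.

    151 ms at 2 kHz -> 302 samples -> rounded to the nearest odd = 301.
    """
    n = int(round(frame_ms * fs / 1000.0))
    if n % 2 == 0:
        n -= 1
    return max(n, 3)


def savgol_smooth(x: np.ndarray, fs: float, order: int = 3, frame_ms: float = 151.0) -> np.ndarray:
    """Savitzky-Golay FIR smoothing along the last axis.

    Each output sample is the center value of the least-squares polynomial
    of the given order fit over the frame; polynomials of degree <= order
    pass through unchanged (away from edges, where the fit is one-sided).
    """
    frame = frame_ms_to_samples(frame_ms, fs)
    if frame <= order + 1:
        raise ValueError("frame shorter than order + 2 samples")
    return signal.savgol_filter(x, frame, order, axis=-1)


def edge_mask(n_samples: int, fs: float, frame_ms: float = 151.0) -> np.ndarray:
    """Boolean mask of samples whose smoothed value is edge-contaminated."""
    half = frame_ms_to_samples(frame_ms, fs) // 2
    mask = np.zeros(n_samples, dtype=bool)
    mask[:half] = True
    mask[n_samples - half :] = True
    return mask


def spectrogram_bands(
    f_min: float = 2.0, f_max: float = 200.0, n_bands: int = 40, rel_bandwidth: float = 0.10
) -> list[BandSpec]:
    """Log-spaced center frequencies with proportional (+/- rel) bandwidth."""
    centers = np.geomspace(f_min, f_max, n_bands)
    return [
        BandSpec(c * (1 - rel_bandwidth), c * (1 + rel_bandwidth), flank_halfwidth=1.5)
        for c in centers
    ]


def spectrogram(
    x: np.ndarray,
    fs: float,
    bands: list[BandSpec] | None = None,
    baseline_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of per-band envelopes, optionally as % change per frequency row.

    Returns (centers_hz, amplitude) where amplitude is (n_bands, n_samples).
    If ``baseline_idx`` is given, each row is converted to percent change
    from its own mean over those samples (per-frequency normalization).
    """
    bands = bands or spectrogram_bands(f_max=min(200.0, 0.45 * fs))
    rows = []
    for band in bands:
        env = hilbert_bandpass_amplitude(x, fs, band)
        if baseline_idx is not None:
            b = env[..., baseline_idx].mean()
            env = 100.0 * (env - b) / b
        rows.append(env)
    centers = np.array([(b.f_lo + b.f_hi) / 2 for b in bands])
    return centers, np.stack(rows)


def erp_filter(x: np.ndarray, fs: float, f_lo: float = 0.1, f_hi: float = 50.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass for event-related potentials."""
    n = np.asarray(x).shape[-1]
    if n < 10 * fs / f_lo / 10:
        raise ValueError("recording too short for the low corner frequency")
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)
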