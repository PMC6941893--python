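"""Referencing, line-noise removal, and channel/trial exclusion.

Re-referencing subtracts the common average of retained channels; line
noise is removed with zero-phase second-order Butterworth band-stop filters
at the mains frequency and its harmonics.  Channel and trial screening are
automated surrogates for visual inspection: channels are flagged by
relative line-noise power, trials by peak-amplitude z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording


@dataclass
class ExclusionReport:
    """What was removed and why; reproducible from config."""

    channels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "reason", "statistic"])
    )
    trials: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial", "reason", "statistic"])
    )

    @property
    def excluded_channel_labels(self) -> list[str]:
        return list(self.channels["label"])

    @property
    def excluded_trials(self) -> list[int]:
        return list(self.trials["trial"].astype(int))


def common_average_rereference(rec: Recording) -> Recording:
    """Subtract the per-sample mean over included channels from each of them.

    Excluded channels are left untouched.  The common average is computed
    over all retained channels, including the channel itself, so the mean
    across retained channels is exactly zero afterwards.  Idempotent.
    """
    inc = rec.included
    if inc.sum() < 2:
        raise ValueError("common-average reference requires >= 2 included channels")
    data = rec.data.copy()
    car = data[inc].mean(axis=0)
    data[inc] -= car
    return rec.copy_with(data=data, reference="common-average")


def notch_line_noise(
    rec: Recording,
    base_hz: float = 60.0,
    n_harmonics: int = 2,
    stop_halfwidth: float = 2.0,
) -> Recording:
    """Zero-phase 2nd-order Butterworth band-stops at base_hz and harmonics.

    ``n_harmonics`` counts harmonics above the fundamental (2 -> 60, 120,
    180 Hz).  Forward-backward filtering makes the net group delay zero.
    """
    nyq = rec.fs / 2.0
    freqs = [base_hz * k for k in range(1, n_harmonics + 2)]
    if freqs[-1] + stop_halfwidth >= nyq:
        raise ValueError("stop band overlaps Nyquist")
    if freqs[0] - stop_halfwidth <= 0:
        raise ValueError("stop band overlaps DC")
    data = rec.data.copy()
    for f0 in freqs:
        sos = signal.butter(
            2, [f0 - stop_halfwidth, f0 + stop_halfwidth], btype="bandstop", fs=rec.fs, output="sos"
        )
        data = signal.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data=data)


def _line_power(data: np.ndarray, fs: float, base_hz: float, halfwidth: float) -> np.ndarray:
    """Per-channel power in the +/- halfwidth band around base_hz (Welch)."""
    nper = int(min(data.shape[1], 4 * fs))
    f, pxx = signal.welch(data, fs=fs, nperseg=nper, axis=1)
    band = (f >= base_hz - halfwidth) & (f <= base_hz + halfwidth)
    return pxx[:, band].sum(axis=1)


def detect_bad_channels(
    rec: Recording,
    line_power_z_threshold: float = 5.0,
    base_hz: float = 60.0,
    halfwidth: float = 2.0,
) -> ExclusionReport:
    """Flag channels whose line-noise power is an outlier among channels.

    The statistic is a robust z-score (median/MAD) of log line-band power
    across channels; channels above the threshold are listed for exclusion.
    """
    if line_power_z_threshold <= 0:
        raise ValueError("threshold must be > 0")
    power = np.log(_line_power(rec.data, rec.fs, base_hz, halfwidth) + 1e-30)
    med = np.median(power)
    mad = np.median(np.abs(power - med)) * 1.4826
    z = (power - med) / max(mad, 1e-12)
    bad = np.flatnonzero(z > line_power_z_threshold)
    rep = ExclusionReport()
    rep.channels = pd.DataFrame(
        {
            "label": rec.channels["label"].to_numpy()[bad],
            "reason": "line-noise",
            "statistic": z[bad],
        }
    )
    return rep


def apply_channel_exclusions(rec: Recording, report: ExclusionReport) -> Recording:
    out = rec.copy_with()
    mask = out.channels["label"].isin(report.excluded_channel_labels)
    out.channels.loc[mask, "include"] = False
    return out


def reject_trials(epoch_data: np.ndarray, amplitude_z_threshold: float = 5.0) -> ExclusionReport:
    """Flag trials with outlying peak amplitude (inter-ictal-spike surrogate).

    ``epoch_data`` is (trials, channels, time) raw voltage.  Each trial's
    statistic is the maximum over channels of its peak absolute amplitude
    expressed as a robust z-score against that channel's across-trial
    distribution of peaks.
    """
    if amplitude_z_threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks = np.abs(epoch_data).max(axis=2)  # trials x channels
    med = np.median(peaks, axis=0)
    mad = np.median(np.abs(peaks - med), axis=0) * 1.4826
    z = (peaks - med) / np.maximum(mad, 1e-12)
    stat = z.max(axis=1)
    bad = np.flatnonzero(stat > amplitude_z_threshold)
    rep = ExclusionReport()
    rep.trials = pd.DataFrame({"trial": bad, "reason": "amplitude", "statistic": stat[bad]})
    return rep
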