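"""Event-locked epoching and group statistics.

Broadband-gamma activity (BGA) is expressed as percent change from a
pre-stimulus baseline (-500 to -100 ms before stimulus onset).  Responses
in production tasks are aligned to speech onset while the baseline stays
defined relative to stimulus onset, so the pipeline carries both alignments
per trial.

Group time courses use hierarchical averaging: electrodes are averaged
within each subject first, and the between-subject averages (with their SE)
carry the statistics.  Per-timepoint activation is tested with a one-tailed
one-sample t-test across subjects against zero and accepted at a
Benjamini-Hochberg FDR-corrected threshold.  Single-electrode window
activation is summarized as a z-score of the window of interest against the
baseline period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Recording, AnalysisConfig
from . import spectral

EPOCH_DTYPE = float


@dataclass
class EpochSet:
    """Trials x channels x time array with its alignment and units.

    times_ms is relative to the alignment event; windows are half-open in
    samples: a window of L ms at sampling rate fs contains exactly
    round(L * fs / 1000) samples.
    """

    data: np.ndarray
    fs: float
    times_ms: np.ndarray
    align: str  # 'stimulus' | 'speech'
    units: str  # 'uV' | 'envelope' | 'percent'
    channel_labels: np.ndarray
    trial_index: np.ndarray
    baseline_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window_idx(self, window: tuple[float, float]) -> np.ndarray:
        """Half-open [start, end) sample indices of a window in ms."""
        lo, hi = window
        if lo < self.times_ms[0] - 0.5 / self.fs * 1000 or hi > self.times_ms[-1] + 1000 / self.fs:
            raise ValueError(f"window {window} outside epoch extent")
        i0 = int(round((lo - self.times_ms[0]) * self.fs / 1000.0))
        n = int(round((hi - lo) * self.fs / 1000.0))
        return np.arange(i0, i0 + n)


@dataclass
class GroupTimecourse:
    """Two-stage (within-subject, then across-subject) group time course."""

    subject_means: np.ndarray  # (n_subjects, time)
    mean: np.ndarray
    se: np.ndarray
    times_ms: np.ndarray
    subjects: np.ndarray
    significance: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.subject_means.shape[0]


def epoch(
    data: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    align: str,
    window: tuple[float, float],
    channel_labels: np.ndarray | None = None,
) -> EpochSet:
    """Slice continuous (channels, samples) data into event-locked epochs.

    Alignment is nearest-sample; trials whose window falls outside the
    recording are dropped with a warning and do not appear in trial_index.
    """
    col = {"stimulus": "stim_onset_ms", "speech": "speech_onset_ms"}[align]
    t_evt = events[col].to_numpy(dtype=float)
    if np.all(~np.isfinite(t_evt)):
        raise ValueError(f"alignment column {col!r} has no usable values for align={align!r}")
    lo, hi = window
    n_samp = int(round((hi - lo) * fs / 1000.0))
    n_total = data.shape[1]
    starts = np.round(t_evt * fs / 1000.0).astype(float) + round(lo * fs / 1000.0)
    keep, slices = [], []
    for k, s in enumerate(starts):
        if not np.isfinite(s):
            continue
        s = int(s)
        if s < 0 or s + n_samp > n_total:
            continue
        keep.append(k)
        slices.append(data[:, s : s + n_samp])
    if len(keep) < len(t_evt):
        warnings.warn(f"dropped {len(t_evt) - len(keep)} trials outside the recording", stacklevel=2)
    if not keep:
        raise ValueError("no trials remain after windowing")
    arr = np.stack(slices)  # (trials, channels, time)
    times = lo + 1000.0 / fs * np.arange(n_samp)
    if channel_labels is None:
        channel_labels = np.array([f"ch{i}" for i in range(data.shape[0])])
    return EpochSet(
        data=arr.astype(EPOCH_DTYPE),
        fs=fs,
        times_ms=times,
        align=align,
        units="uV",
        channel_labels=np.asarray(channel_labels),
        trial_index=np.asarray(keep),
    )


def percent_change(
    epochs: EpochSet,
    baseline: tuple[float, float],
    baseline_epochs: EpochSet | None = None,
) -> EpochSet:
    """Convert envelope epochs to percent change from baseline.

    The baseline level B is the mean envelope over the baseline window,
    pooled across trials per channel.  The baseline window is defined
    relative to stimulus onset; pass stimulus-aligned epochs of the same
    trials via ``baseline_epochs`` when ``epochs`` is speech-aligned.
    """
    if epochs.units == "percent":
        raise ValueError("epochs already in percent-change units")
    ref = baseline_epochs if baseline_epochs is not None else epochs
    idx = ref.window_idx(baseline)
    common = np.intersect1d(epochs.trial_index, ref.trial_index)
    sel = np.isin(ref.trial_index, common)
    b = ref.data[sel][:, :, idx].mean(axis=(0, 2))  # per channel
    if np.any(b <= 0):
        raise ValueError("non-positive baseline level; input is not a true envelope")
    sel_e = np.isin(epochs.trial_index, common)
    out = 100.0 * (epochs.data[sel_e] - b[None, :, None]) / b[None, :, None]
    return EpochSet(
        data=out,
        fs=epochs.fs,
        times_ms=epochs.times_ms,
        align=epochs.align,
        units="percent",
        channel_labels=epochs.channel_labels,
        trial_index=epochs.trial_index[sel_e],
        baseline_ms=tuple(baseline),
    )


def filter_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Keep trials flagged correct and with the modal (most common) response."""
    return events[events["correct"] & events["modal"]].reset_index(drop=True)


def group_timecourse(traces: np.ndarray, subject_ids: np.ndarray, times_ms: np.ndarray) -> GroupTimecourse:
    """Average electrode traces within subject, then across subjects.

    SE is the standard error across subject means; with one subject the
    mean is returned and tests are disabled (SE = NaN).
    """
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    subj_means = np.stack([traces[subject_ids == s].mean(axis=0) for s in subjects])
    mean = subj_means.mean(axis=0)
    n = len(subjects)
    se = subj_means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
    return GroupTimecourse(
        subject_means=subj_means, mean=mean, se=se, times_ms=times_ms, subjects=subjects
    )


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def timepoint_significance(group: GroupTimecourse, q: float = 0.05) -> np.ndarray:
    """One-tailed (activation > 0) t-test per timepoint, BH-FDR over time.

    Degenerate zero-variance timepoints get p = 0.5 when the mean is zero
    (and are flagged with a warning), p -> 0/1 otherwise.
    """
    n = group.n_subjects
    if n < 3:
        raise ValueError("timepoint significance needs >= 3 subjects")
    mean = group.subject_means.mean(axis=0)
    sd = group.subject_means.std(axis=0, ddof=1)
    pvals = np.empty_like(mean)
    degen = sd == 0
    if degen.any():
        warnings.warn(f"{degen.sum()} zero-variance timepoints", stacklevel=2)
        pvals[degen] = np.where(mean[degen] > 0, 0.0, np.where(mean[degen] < 0, 1.0, 0.5))
    ok = ~degen
    t = mean[ok] / (sd[ok] / np.sqrt(n))
    pvals[ok] = stats.t.sf(t, df=n - 1)
    mask = bh_fdr(pvals, q)
    group.significance = mask
    return mask


def window_zscore(
    epochs: EpochSet,
    window: tuple[float, float],
    baseline: tuple[float, float],
    baseline_epochs: EpochSet | None = None,
) -> pd.DataFrame:
    """Per-electrode z of the window of interest against the baseline period.

    Per trial, the window mean and baseline mean are computed; then
    z = (mean of window means - mean of baseline means) / SD of baseline
    means, with a two-tailed normal p.  Returns one row per electrode with
    columns electrode, z, p, unstable (n_trials < 5 or zero baseline SD).
    """
    ref = baseline_epochs if baseline_epochs is not None else epochs
    widx = epochs.window_idx(window)
    bidx = ref.window_idx(baseline)
    wmeans = epochs.data[:, :, widx].mean(axis=2)  # trials x channels
    bmeans = ref.data[:, :, bidx].mean(axis=2)
    n_trials = epochs.n_trials
    bsd = bmeans.std(axis=0, ddof=1)
    diff = wmeans.mean(axis=0) - bmeans.mean(axis=0)
    unstable = (n_trials < 5) | (bsd == 0)
    z = np.zeros(epochs.data.shape[1])
    np.divide(diff, bsd, out=z, where=bsd > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[bsd == 0] = 1.0
    if np.any(bsd == 0):
        warnings.warn("zero baseline variability on some electrodes; z set to 0", stacklevel=2)
    return pd.DataFrame(
        {
            "electrode": epochs.channel_labels,
            "z": z,
            "p": p,
            "unstable": np.broadcast_to(unstable, z.shape),
        }
    )


def wilcoxon_contrast(a: np.ndarray, b: np.ndarray | None = None) -> float:
    """Two-sided Wilcoxon signed-rank p for paired subject means.

    Zero differences are dropped (Wilcoxon's original convention); the
    exact null distribution is used for n <= 25 (without ties), the normal
    approximation otherwise.  All-zero differences return p = 1.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    if b is not None and len(a) != len(np.asarray(b)):
        raise ValueError("paired samples must have equal length")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; no test performed", stacklevel=2)
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, method=method)
    except ValueError:
        res = stats.wilcoxon(d, method="approx")
    return float(res.pvalue)


def compute_erp(
    raw_epochs: EpochSet, subject_ids: np.ndarray, cfg: AnalysisConfig | None = None
) -> GroupTimecourse:
    """Event-related potential: trial-average, SG-smooth, hierarchical group.

    Input epochs must already be band-passed (0.1-50 Hz) voltage.
    """
    cfg = cfg or AnalysisConfig()
    per_channel = raw_epochs.data.mean(axis=0)  # channels x time
    smoothed = spectral.savgol_smooth(per_channel, raw_epochs.fs, cfg.sg_order, cfg.sg_frame_ms)
    return group_timecourse(smoothed, subject_ids, raw_epochs.times_ms)


def bga_epochs(
    rec: Recording,
    events: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    align: str = "speech",
) -> tuple[EpochSet, EpochSet]:
    """Full single-recording BGA pipeline: envelope -> smooth -> epoch -> %.

    Returns (aligned percent-change epochs, stimulus-aligned percent-change
    epochs); the latter carries the baseline definition and is used for
    pre-stimulus statistics.  Only included channels are processed.
    """
    cfg = cfg or AnalysisConfig()
    band = spectral.BandSpec(*cfg.band_hz, cfg.flank_halfwidth_hz)
    inc = rec.included
    env = spectral.hilbert_bandpass_amplitude(rec.data[inc], rec.fs, band)
    env = spectral.savgol_smooth(env, rec.fs, cfg.sg_order, cfg.sg_frame_ms)
    labels = rec.channels["label"].to_numpy()[inc]
    stim = epoch(env, rec.fs, events, "stimulus", cfg.epoch_ms, labels)
    stim_pct = percent_change(stim, cfg.baseline_ms)
    if align == "stimulus":
        return stim_pct, stim_pct
    aligned = epoch(env, rec.fs, events, align, cfg.epoch_ms, labels)
    aligned_pct = percent_change(aligned, cfg.baseline_ms, baseline_epochs=stim)
    return aligned_pct, stim_pct
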