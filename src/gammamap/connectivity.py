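"""Band-limited voltage correlations between electrode pairs.

Instantaneous correlation of 70-150 Hz band-limited voltage traces between
nearby electrode pairs discriminates volume conduction (correlation maximal
at 0 ms lag) from lagged coupling.  Per-trial Pearson correlations are
averaged across trials through the Fisher z transform; group inference uses
a Wilcoxon signed-rank test of per-subject mean correlations against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import wilcoxon_contrast
from .spectral import BandSpec, bandlimit_voltage

__all__ = ["PairCorrelation", "bandlimit_voltage", "pair_correlation", "group_pair_test",
           "closest_pairs"]


@dataclass
class PairCorrelation:
    """Lagged correlation profile of one electrode pair."""

    lags_ms: np.ndarray
    r: np.ndarray  # Fisher-z-averaged correlation per lag
    r_trials: np.ndarray  # (n_trials, n_lags)
    peak_lag_ms: float
    r0: float  # correlation at zero lag


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt(np.sum(xs**2) * np.sum(ys**2))
    if denom == 0:
        return np.nan
    return float(np.dot(xs, ys) / denom)


def pair_correlation(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag_ms: float = 100.0,
    trial_windows: list[tuple[int, int]] | None = None,
) -> PairCorrelation:
    """Lagged Pearson correlation of two traces, averaged over trial windows.

    For lag l (ms), r(l) correlates x(t) with y(t + l) within each trial
    window; per-trial r values are combined by Fisher-z averaging.  The
    peak lag maximizes |mean r|, ties toward the most negative lag (scan
    order).  Constant traces within a window yield NaN and are dropped
    from the average with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    max_shift = int(round(max_lag_ms * fs / 1000.0))
    if trial_windows is None:
        trial_windows = [(max_shift, len(x) - max_shift)]
    shifts = np.arange(-max_shift, max_shift + 1)
    lags_ms = shifts * 1000.0 / fs

    r_trials = np.full((len(trial_windows), len(shifts)), np.nan)
    for ti, (a, b) in enumerate(trial_windows):
        if a - max_shift < 0 or b + max_shift > len(x):
            raise ValueError("trial window too close to the recording edge for max_lag")
        xw = x[a:b]
        for si, s in enumerate(shifts):
            r_trials[ti, si] = _pearson(xw, y[a + s : b + s])
    if np.isnan(r_trials).all():
        raise ValueError("all trial windows are constant; correlation undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        zt = np.arctanh(np.clip(r_trials, -1 + 1e-12, 1 - 1e-12))
    r = np.tanh(np.nanmean(zt, axis=0))
    peak = int(np.argmax(np.abs(r)))
    return PairCorrelation(
        lags_ms=lags_ms,
        r=r,
        r_trials=r_trials,
        peak_lag_ms=float(lags_ms[peak]),
        r0=float(r[len(shifts) // 2]),
    )


def closest_pairs(
    electrodes: pd.DataFrame, region_a: str, region_b: str
) -> pd.DataFrame:
    """Per patient, the closest (Euclidean) electrode pair spanning two regions.

    Patients lacking electrodes in either region are omitted.  Returns one
    row per patient: patient, label_a, label_b, separation_mm.
    """
    rows = []
    for patient, grp in electrodes.groupby("patient"):
        ea = grp[grp["region"] == region_a]
        eb = grp[grp["region"] == region_b]
        if ea.empty or eb.empty:
            continue
        ca = ea[["x", "y", "z"]].to_numpy()
        cb = eb[["x", "y", "z"]].to_numpy()
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        rows.append(
            {
                "patient": patient,
                "label_a": ea["label"].iloc[i],
                "label_b": eb["label"].iloc[j],
                "separation_mm": float(d[i, j]),
            }
        )
    return pd.DataFrame(rows)


def group_pair_test(per_subject_r: np.ndarray) -> float:
    """Wilcoxon signed-rank p of per-subject Fisher-z correlations vs zero."""
    r = np.asarray(per_subject_r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie in (-1, 1)")
    if len(r) < 5:
        import warnings

        warnings.warn("fewer than 5 subjects; exact Wilcoxon p is coarse", stacklevel=2)
    return wilcoxon_contrast(np.arctanh(r))
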