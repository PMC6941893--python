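"""Synthetic stereo-EEG generator with known ground truth.

Produces the four ingredients of a multi-patient intracranial study on a
shared cortical surface: a parcellated mesh, linear depth-probe electrode
placements, trial event tables with behavioral response times, and raw
multichannel voltage traces.

The signal model per channel is::

    x(t) = b(t) + l(t) + g(t) * [1 + a(t)] + s(t)

where ``b`` is 1/f-shaped Gaussian background, ``l`` is line noise at the
mains frequency plus harmonics, ``g`` is a broadband gamma carrier
(bandpass-filtered white noise, 70-150 Hz by default, so the "broadband"
label is honest and phase is random across trials), ``a`` is the
task-locked fractional envelope gain (raised-cosine-ramped plateau per
trial, region-specific amplitude/latency/duration), and ``s`` holds
optional inter-ictal-like spike transients.  Channels whose region carries
no effect receive background only (``a = 0``).

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import signal
from scipy.stats import truncnorm

from .io import Recording
from .mesh import SurfaceMesh, geodesic_distances

MESH_RADIUS_MM = 40.0
#: sEEG probe geometry: platinum-iridium cylinder contacts 2.0 mm long,
#: separated by 1.5-2.43 mm gaps, so center-to-center pitch is 3.5-4.43 mm
CONTACT_LENGTH_MM = 2.0
CONTACT_GAP_RANGE_MM = (1.5, 2.43)
#: ramp time of the raised-cosine onset/offset of each trial's effect window
EFFECT_RAMP_MS = 50.0
#: response times below this floor are physiologically implausible
RT_FLOOR_MS = 200.0


@dataclass
class RegionEffect:
    """Task-locked broadband-gamma increase in one parcellation region.

    amplitude_pct is the plateau envelope gain in percent of the baseline
    gamma level; onset_ms is relative to the alignment event of each trial
    (``align`` is ``"speech"`` or ``"stimulus"``); jitter_frac scales a
    per-trial uniform amplitude perturbation.
    """

    region: str
    amplitude_pct: float
    onset_ms: float
    duration_ms: float
    jitter_frac: float = 0.1
    align: str = "speech"

    def __post_init__(self) -> None:
        if self.amplitude_pct < 0:
            raise ValueError("effect amplitude must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("effect duration must be > 0")
        if not 0 <= self.jitter_frac < 1:
            raise ValueError("jitter fraction must be in [0, 1)")
        if self.align not in ("speech", "stimulus"):
            raise ValueError("align must be 'speech' or 'stimulus'")


@dataclass
class BackgroundSpec:
    """Non-task signal components, amplitudes in microvolts."""

    one_over_f_exponent: float = 1.0
    background_rms_uv: float = 10.0
    line_freq_hz: float = 60.0
    line_amp_uv: float = 8.0
    n_harmonics: int = 2  # harmonics above the fundamental (120, 180 Hz)
    baseline_gamma_uv: float = 30.0  # RMS of the 70-150 Hz carrier
    gamma_band_hz: tuple[float, float] = (70.0, 150.0)
    spike_rate_per_min: float = 0.0
    spike_amp_factor: float = 10.0  # spike peak in units of background RMS


@dataclass
class GroundTruth:
    """Full specification of what the generator injects.

    Behavioral defaults are single-word production response times
    (reading: 978 +/- 221 ms; object naming uses 1192 +/- 245 ms).
    """

    effects: list[RegionEffect] = field(default_factory=list)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    rt_mean_ms: float = 978.0
    rt_sd_ms: float = 221.0

    def validate_against(self, mesh: SurfaceMesh) -> None:
        regions = set(np.unique(mesh.labels))
        for eff in self.effects:
            if eff.region not in regions:
                raise ValueError(f"effect region {eff.region!r} not in mesh parcellation")

    def effects_for(self, region: str) -> list[RegionEffect]:
        return [e for e in self.effects if e.region == region]


def probe_pitch_range_mm() -> tuple[float, float]:
    """Center-to-center contact spacing range implied by the probe geometry.

    Pitch = contact length + inter-contact gap.
    """
    lo, hi = CONTACT_GAP_RANGE_MM
    return (CONTACT_LENGTH_MM + lo, CONTACT_LENGTH_MM + hi)


def make_mesh(
    subdivision_level: int,
    n_regions: int,
    seed: int,
    region_names: list[str] | None = None,
) -> SurfaceMesh:
    """Icosphere mesh (~40 mm extent) with a contiguous random parcellation.

    The parcellation is a geodesic Voronoi partition around ``n_regions``
    seed vertices drawn uniformly, so every region is edge-connected and
    non-empty.  Ties in geodesic distance go to the lower region index.
    """
    if subdivision_level < 1:
        raise ValueError("subdivision_level must be >= 1")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=MESH_RADIUS_MM)
    vertices = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces, dtype=np.int64)
    if n_regions > len(vertices):
        raise ValueError("more regions requested than vertices available")
    if region_names is None:
        region_names = [f"R{i:02d}" for i in range(n_regions)]
    if len(region_names) != n_regions:
        raise ValueError("need one name per region")

    rng = np.random.default_rng(seed)
    seeds = rng.choice(len(vertices), size=n_regions, replace=False)
    mesh = SurfaceMesh(vertices, faces, np.array(["?"] * len(vertices)))
    dist = geodesic_distances(mesh, seeds)  # (n_regions, V)
    assignment = np.argmin(dist, axis=0)  # argmin takes the lowest index on ties
    mesh.labels = np.asarray(region_names, dtype=object)[assignment]
    return mesh


def place_electrodes(
    mesh: SurfaceMesh,
    n_patients: int,
    probes_per_patient: int,
    contacts_per_probe: int,
    pitch_mm: float,
    seed: int,
    target_regions: list[str] | None = None,
    target_jitter_deg: float = 8.0,
) -> pd.DataFrame:
    """Place linear depth probes across patients.

    Each probe is a straight chord between two surface points; contacts sit
    at equal ``pitch_mm`` spacing along it, starting 1 mm inside the entry
    point, so every contact lies within a few mm of the surface.  Entry
    points and directions are randomized per seed.  Each contact inherits
    the parcellation label of its nearest vertex.

    When ``target_regions`` is given, probe entry points aim at a random
    vertex of the targeted region (cycling through the list across a
    patient's probes) with ``target_jitter_deg`` of angular scatter.  This
    emulates clinical trajectories targeting shared anatomy across
    patients, which is what gives multi-patient vertex coverage on the
    shared surface; untargeted placement is uniform over the sphere.

    Returns a table with columns patient, probe, contact, label, x, y, z,
    region, include.
    """
    if pitch_mm <= 0:
        raise ValueError("pitch_mm must be > 0")
    if not 2 <= contacts_per_probe <= 20:
        raise ValueError("contacts_per_probe outside plausible range")
    rng = np.random.default_rng(seed)
    span = (contacts_per_probe - 1) * pitch_mm + 2.0
    center = mesh.vertices.mean(axis=0)
    radius = float(np.linalg.norm(mesh.vertices - center, axis=1).mean())
    if span > 2.0 * radius - 4.0:
        raise ValueError("mesh too small to host the requested probe length")

    verts = mesh.vertices
    rows = []
    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        for q in range(probes_per_patient):
            probe = chr(ord("A") + q)
            # probe = chord between two points on the bounding sphere; chord
            # length close to the probe span keeps all contacts near the
            # surface (small sagitta)
            chord = min(span + rng.uniform(2.0, 6.0), 2.0 * radius - 1.0)
            if target_regions:
                region = target_regions[q % len(target_regions)]
                cand = mesh.region_vertices(region)
                if cand.size == 0:
                    raise ValueError(f"target region {region!r} not in mesh parcellation")
                tgt = verts[rng.choice(cand)] - center
                a_dir = tgt / np.linalg.norm(tgt)
                jitter = np.deg2rad(target_jitter_deg) * rng.standard_normal(3)
                a_dir = a_dir + np.cross(jitter, a_dir)
                a_dir /= np.linalg.norm(a_dir)
            else:
                a_dir = rng.standard_normal(3)
                a_dir /= np.linalg.norm(a_dir)
            tangent = rng.standard_normal(3)
            tangent -= tangent.dot(a_dir) * a_dir
            tangent /= np.linalg.norm(tangent)
            theta = 2.0 * np.arcsin(chord / (2.0 * radius))
            b_dir = np.cos(theta) * a_dir + np.sin(theta) * tangent
            a = center + radius * a_dir
            b = center + radius * b_dir
            u = (b - a) / np.linalg.norm(b - a)
            for c in range(contacts_per_probe):
                xyz = a + u * (1.0 + c * pitch_mm)
                d2 = np.sum((verts - xyz) ** 2, axis=1)
                region = mesh.labels[int(np.argmin(d2))]
                rows.append(
                    {
                        "patient": patient,
                        "probe": probe,
                        "contact": c + 1,
                        "label": f"{patient}-{probe}{c + 1}",
                        "x": xyz[0],
                        "y": xyz[1],
                        "z": xyz[2],
                        "region": region,
                        "include": True,
                    }
                )
    return pd.DataFrame(rows)


def simulate_events(
    task: str,
    n_trials: int,
    rt_mean: float = 978.0,
    rt_sd: float = 221.0,
    iti: float = 3000.0,
    seed: int = 0,
    incorrect_frac: float = 0.0,
    nonmodal_frac: float = 0.0,
    t_start: float = 3000.0,
) -> pd.DataFrame:
    """Trial event table: stimulus onsets, speech onsets, response flags.

    Response times are truncated-normal draws (floor 200 ms).  For the
    listening task the speech-onset column is NaN: alignment must use the
    stimulus onset.  A configurable fraction of trials is flagged incorrect
    or non-modal-response for trial-filtering tests.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rt_mean <= 0:
        raise ValueError("rt_mean must be > 0")
    if rt_sd < 0:
        raise ValueError("rt_sd must be >= 0")
    rng = np.random.default_rng(seed)
    stim = t_start + iti * np.arange(n_trials)
    if task == "listening":
        speech = np.full(n_trials, np.nan)
        rts = np.full(n_trials, np.nan)
    else:
        if rt_sd == 0:
            rts = np.full(n_trials, float(rt_mean))
        else:
            a = (RT_FLOOR_MS - rt_mean) / rt_sd
            rts = truncnorm.rvs(a, np.inf, loc=rt_mean, scale=rt_sd, size=n_trials, random_state=rng)
        speech = stim + rts
    correct = np.ones(n_trials, dtype=bool)
    modal = np.ones(n_trials, dtype=bool)
    if incorrect_frac > 0:
        k = int(round(incorrect_frac * n_trials))
        correct[rng.choice(n_trials, size=k, replace=False)] = False
    if nonmodal_frac > 0:
        k = int(round(nonmodal_frac * n_trials))
        modal[rng.choice(n_trials, size=k, replace=False)] = False
    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "task": task,
            "stim_onset_ms": stim,
            "speech_onset_ms": speech,
            "rt_ms": rts,
            "correct": correct,
            "modal": modal,
        }
    )


def one_over_f_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    The spectrum is flattened below 1 Hz to keep the variance finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shaped[0] = 0.0
    x = np.fft.irfft(spec * shaped, n=n)
    return x * (rms / np.std(x))


def _gamma_carrier(
    n: int, fs: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x * (rms / np.std(x))


def _spike_waveform(fs: float) -> np.ndarray:
    """Biphasic transient: derivative of a Gaussian, ~80 ms footprint."""
    t = np.arange(-0.04, 0.04, 1.0 / fs)
    w = 0.012
    shape = -t * np.exp(-(t**2) / (2 * w**2))
    return shape / np.abs(shape).max()


def _effect_gain(
    n: int,
    fs: float,
    events: pd.DataFrame,
    effects: list[RegionEffect],
    rng: np.random.Generator,
) -> np.ndarray:
    """Fractional envelope gain a(t) summed over trials and effects."""
    gain = np.zeros(n)
    for eff in effects:
        col = "speech_onset_ms" if eff.align == "speech" else "stim_onset_ms"
        ramp = min(EFFECT_RAMP_MS, eff.duration_ms / 2.0)
        n_win = max(2, int(round(eff.duration_ms * fs / 1000.0)))
        win = signal.windows.tukey(n_win, alpha=min(1.0, 2.0 * ramp / eff.duration_ms))
        for t_evt in events[col].to_numpy():
            u = rng.uniform(-1.0, 1.0)  # drawn per trial even if NaN, keeps streams aligned
            if not np.isfinite(t_evt):
                continue
            i0 = int(round((t_evt + eff.onset_ms) * fs / 1000.0))
            if i0 < 0 or i0 + n_win > n:
                raise ValueError("event effect window outside recording duration")
            amp = (eff.amplitude_pct / 100.0) * (1.0 + eff.jitter_frac * u)
            gain[i0 : i0 + n_win] += amp * win
    return gain


def simulate_recording(
    electrodes: pd.DataFrame,
    events: pd.DataFrame,
    truth: GroundTruth,
    fs: float,
    seed: int,
    margin_ms: float = 3000.0,
) -> Recording:
    """Render the raw multichannel recording for one task run.

    Every electrode row becomes one channel.  Channels in regions named by
    ``truth.effects`` get trial-locked envelope gains on the gamma carrier;
    all channels share the background statistics (independent draws).
    """
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz to resolve the gamma band")
    bg = truth.background
    last = np.nanmax(
        np.concatenate([events["stim_onset_ms"].to_numpy(), events["speech_onset_ms"].to_numpy()])
    )
    max_end = max((e.onset_ms + e.duration_ms for e in truth.effects), default=0.0)
    n = int(np.ceil((last + max(margin_ms, max_end + 500.0)) * fs / 1000.0))
    t = np.arange(n) / fs

    rng = np.random.default_rng(seed)
    data = np.empty((len(electrodes), n))
    spike_shape = _spike_waveform(fs)
    for k, (_, row) in enumerate(electrodes.iterrows()):
        x = one_over_f_noise(n, fs, bg.one_over_f_exponent, bg.background_rms_uv, rng)
        for h in range(1, bg.n_harmonics + 2):
            f_h = bg.line_freq_hz * h
            if f_h >= fs / 2:
                break
            phase = rng.uniform(0, 2 * np.pi)
            x += (bg.line_amp_uv / h) * np.sin(2 * np.pi * f_h * t + phase)
        carrier = _gamma_carrier(n, fs, bg.gamma_band_hz, bg.baseline_gamma_uv, rng)
        gain = _effect_gain(n, fs, events, truth.effects_for(row["region"]), rng)
        x += carrier * (1.0 + gain)
        if bg.spike_rate_per_min > 0:
            n_spikes = rng.poisson(bg.spike_rate_per_min * (n / fs) / 60.0)
            for _ in range(n_spikes):
                i0 = rng.integers(0, n - len(spike_shape))
                x[i0 : i0 + len(spike_shape)] += (
                    bg.spike_amp_factor * bg.background_rms_uv * spike_shape
                )
        data[k] = x

    return Recording(data=data, fs=fs, channels=electrodes.reset_index(drop=True).copy())
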