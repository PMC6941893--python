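"""Containers and file I/O.

Conventions: times are milliseconds relative to recording start, frequencies
Hz, voltages microvolts.  Unit conversion happens only at the I/O boundary
(TSV files declare their time unit in a ``# time_unit:`` header comment).

Signals travel as HDF5 (lossless round trip); electrode and event tables as
TSV; meshes as GIfTI surface files with a TSV of per-vertex region labels
alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from io import StringIO
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .mesh import SurfaceMesh

logger = logging.getLogger("gammamap")

ELECTRODE_COLUMNS = ["patient", "probe", "contact", "label", "x", "y", "z", "region", "include"]
EVENT_COLUMNS = ["trial", "task", "stim_onset_ms", "speech_onset_ms", "rt_ms", "correct", "modal"]


@dataclass
class Recording:
    """Continuous multichannel recording.

    data : (n_channels, n_samples) float array, microvolts.
    fs : sampling rate, Hz.
    channels : per-channel metadata table (see ELECTRODE_COLUMNS).
    reference : 'original' or 'common-average'.
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("one metadata row per channel required")
        labels = self.channels["label"].to_numpy()
        if len(np.unique(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs

    @property
    def included(self) -> np.ndarray:
        return self.channels["include"].to_numpy(dtype=bool)

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            channels=self.channels.copy(),
            reference=kw.get("reference", self.reference),
        )


@dataclass
class AnalysisConfig:
    """Numeric constants of the analysis, with the study defaults.

    Windows are (start, end) ms pairs relative to the alignment event; the
    baseline window is always relative to stimulus onset.
    """

    band_hz: tuple[float, float] = (70.0, 150.0)
    flank_halfwidth_hz: float = 1.5
    sg_order: int = 3
    sg_frame_ms: float = 151.0
    baseline_ms: tuple[float, float] = (-500.0, -100.0)
    pre_window_ms: tuple[float, float] = (-500.0, -100.0)
    post_window_ms: tuple[float, float] = (200.0, 600.0)
    epoch_ms: tuple[float, float] = (-2000.0, 2000.0)
    fdr_q: float = 0.05
    mema_alpha: float = 0.01
    mema_iterations: int = 5000
    fwhm_mm: float = 3.0
    effect_floor_pct: float = 10.0
    movie_effect_floor_pct: float = 15.0
    min_patients: int = 3
    movie_width_ms: float = 150.0
    movie_step_ms: float = 10.0
    coverage_radius_mm: float = 10.0
    notch_base_hz: float = 60.0
    notch_harmonics: int = 2
    notch_halfwidth_hz: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("band_hz", "baseline_ms", "pre_window_ms", "post_window_ms", "epoch_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        if not 0 < self.fdr_q < 1 or not 0 < self.mema_alpha < 1:
            raise ValueError("q and alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        out = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# signals (HDF5)


def write_recording(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=rec.data)
        dset.attrs["units"] = "uV"
        f.attrs["fs_hz"] = rec.fs
        f.attrs["reference"] = rec.reference
        f.attrs["channels_json"] = rec.channels.to_json(orient="records")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs_hz"])
        reference = str(f.attrs["reference"])
        channels = pd.read_json(StringIO(f.attrs["channels_json"]), orient="records")
    return Recording(data=data, fs=fs, channels=channels, reference=reference)


# ---------------------------------------------------------------------------
# tables (TSV)


def _write_table(df: pd.DataFrame, path: Path, required: list[str], time_unit: str = "ms") -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# time_unit: {time_unit}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path: Path, required: list[str], time_cols: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    time_unit = "ms"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "time_unit:" in first:
                time_unit = first.split("time_unit:")[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table at {path} missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"table at {path} has unknown columns (kept): {extra}", stacklevel=2)
    if time_unit == "s":
        for col in time_cols:
            df[col] = df[col] * 1000.0
    elif time_unit != "ms":
        raise ValueError(f"unsupported time unit {time_unit!r}")
    return df


def write_electrodes(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, Path(path), ELECTRODE_COLUMNS)


def read_electrodes(path: str | Path) -> pd.DataFrame:
    return _read_table(Path(path), ELECTRODE_COLUMNS, time_cols=[])


def write_events(df: pd.DataFrame, path: str | Path, time_unit: str = "ms") -> None:
    df = df.copy()
    if time_unit == "s":
        for col in ("stim_onset_ms", "speech_onset_ms", "rt_ms"):
            df[col] = df[col] / 1000.0
    _write_table(df, Path(path), EVENT_COLUMNS, time_unit=time_unit)


def read_events(path: str | Path) -> pd.DataFrame:
    return _read_table(
        Path(path), EVENT_COLUMNS, time_cols=["stim_onset_ms", "speech_onset_ms", "rt_ms"]
    )


# ---------------------------------------------------------------------------
# meshes (GIfTI + label TSV)


def _labels_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".labels.tsv")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write geometry as GIfTI (.surf.gii) and labels as a TSV alongside."""
    path = Path(path)
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))
    pd.DataFrame({"vertex": np.arange(mesh.n_vertices), "region": mesh.labels}).to_csv(
        _labels_path(path), sep="\t", index=False
    )


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh not found: {path}")
    img = nib.load(str(path))
    vertices = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    lpath = _labels_path(path)
    if lpath.exists():
        labels = pd.read_csv(lpath, sep="\t")["region"].to_numpy()
    else:
        labels = np.array(["unknown"] * len(vertices))
    return SurfaceMesh(np.asarray(vertices, float), np.asarray(faces, np.int64), labels)


def write_ground_truth_sidecar(payload: dict, path: str | Path) -> None:
    """JSON sidecar recording the generator spec and seeds of a simulation."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
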