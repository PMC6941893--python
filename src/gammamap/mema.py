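"""Surface-based mixed-effects multilevel analysis (MEMA) population maps.

Electrode-level broadband-gamma estimates from many sparsely-sampled
patients are combined into per-vertex population maps on a shared cortical
surface.  Each vertex is fit with a two-level random-effects model: the
within-subject estimate (mean percent change over a window, with its
squared standard error) enters an inverse-variance-weighted mean whose
between-subject variance tau^2 is estimated by REML (DerSimonian-Laird on
non-convergence).  This accounts for sparse sampling and intra- and
inter-subject variability.

Spatial spreading uses a geodesic Gaussian kernel (default 3 mm FWHM) over
the mesh edge graph.  Family-wise error is controlled by cluster-extent
thresholding: white noise with the same dimension and smoothness as the
analyzed data is simulated (default 5000 iterations), smoothed, thresholded
at the vertex alpha, and the (1 - alpha) quantile of the maximal null
cluster size becomes the minimum cluster extent.  Static maps additionally
require coverage by at least three patients and an absolute group effect
above 10 percent; movie frames (150 ms windows, 10 ms spacing) use
uncorrected p < 0.01 and a 15 percent floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import minimize_scalar

from .epochs import EpochSet
from .io import AnalysisConfig
from .mesh import SurfaceMesh, cluster_sizes, geodesic_distances, label_clusters

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548
#: kernel support cutoff, in standard deviations of the Gaussian
KERNEL_CUTOFF_SIGMAS = 4.0


@dataclass
class MemaMap:
    """Per-vertex population map. Arrays span all vertices; NaN = no data."""

    effect: np.ndarray
    tau2: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_subjects: np.ndarray
    coverage_count: np.ndarray
    cluster_id: np.ndarray
    significant: np.ndarray
    extent_threshold: int | None = None
    window_ms: tuple[float, float] | None = None
    mode: str = "static"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(len(self.effect)),
                "effect_pct": self.effect,
                "tau2": self.tau2,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "n_subjects": self.n_subjects,
                "coverage": self.coverage_count,
                "cluster_id": self.cluster_id,
                "significant": self.significant,
            }
        )


def nearest_node(coord: np.ndarray, mesh: SurfaceMesh) -> int:
    """Index of the mesh vertex closest (Euclidean) to a coordinate.

    Ties are broken toward the lowest vertex index.
    """
    coord = np.asarray(coord, dtype=float)
    if coord.shape != (3,) or not np.isfinite(coord).all():
        raise ValueError("coordinate must be a finite (x, y, z) triple")
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    d2 = np.sum((mesh.vertices - coord) ** 2, axis=1)
    return int(np.argmin(d2))


def assign_electrodes(electrodes: pd.DataFrame, mesh: SurfaceMesh) -> np.ndarray:
    """Nearest-vertex index for every electrode row."""
    coords = electrodes[["x", "y", "z"]].to_numpy(dtype=float)
    return np.array([nearest_node(c, mesh) for c in coords])


def smoothing_matrix(mesh: SurfaceMesh, fwhm: float) -> sparse.csr_matrix:
    """Row-normalized geodesic Gaussian smoothing operator.

    Weights exp(-d^2 / 2 sigma^2) with sigma = FWHM / 2.355 and d the
    geodesic (edge-graph) distance, truncated at 4 sigma, normalized to
    unit row sum, so constant fields are fixed points.  Disconnected mesh
    components are smoothed independently by construction.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm * FWHM_TO_SIGMA
    cutoff = KERNEL_CUTOFF_SIGMAS * sigma
    d = geodesic_distances(mesh, np.arange(mesh.n_vertices), limit=cutoff)
    i, j = np.nonzero(np.isfinite(d))
    w = np.exp(-(d[i, j] ** 2) / (2.0 * sigma**2))
    mat = sparse.coo_matrix((w, (i, j)), shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    return sparse.diags(1.0 / rowsum) @ mat


def geodesic_gaussian_smooth(
    values: np.ndarray, mesh: SurfaceMesh, fwhm: float = 3.0
) -> np.ndarray:
    """Smooth a per-vertex field with the geodesic Gaussian kernel."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != mesh.n_vertices:
        raise ValueError("one value per vertex required")
    return smoothing_matrix(mesh, fwhm) @ values


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of between-subject variance; DL fallback."""
    n = len(y)

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))

    hi = max(10.0 * np.var(y) + np.max(v), 1e-6)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded")
    if res.success:
        return float(res.x)
    # DerSimonian-Laird fallback
    w = 1.0 / np.maximum(v, 1e-30)
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - (n - 1)) / max(c, 1e-30)))


def mema_fit(estimates: pd.DataFrame, n_vertices: int) -> MemaMap:
    """Random-effects meta-analysis per vertex.

    ``estimates`` has one row per (subject, vertex) with columns subject,
    vertex, estimate, variance.  Vertices with a single subject carry that
    estimate but no test (p = NaN); two-tailed p uses a t reference with
    n_subjects - 1 degrees of freedom.
    """
    shape = n_vertices
    effect = np.full(shape, np.nan)
    tau2 = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    tval = np.full(shape, np.nan)
    pval = np.full(shape, np.nan)
    nsub = np.zeros(shape, dtype=int)

    for vtx, grp in estimates.groupby("vertex"):
        y = grp["estimate"].to_numpy(dtype=float)
        v = np.maximum(grp["variance"].to_numpy(dtype=float), 0.0)
        n = len(y)
        nsub[vtx] = n
        if n == 1:
            effect[vtx] = y[0]
            continue
        t2 = _reml_tau2(y, v)
        w = 1.0 / (v + t2)
        if not np.all(np.isfinite(w)):  # all variances zero and estimates equal
            w = np.ones(n)
        mu = np.sum(w * y) / np.sum(w)
        s = 1.0 / np.sqrt(np.sum(w))
        effect[vtx] = mu
        tau2[vtx] = t2
        se[vtx] = s
        if s == 0:
            tval[vtx] = np.inf if mu != 0 else 0.0
            pval[vtx] = 0.0 if mu != 0 else 1.0
        else:
            tval[vtx] = mu / s
            pval[vtx] = 2.0 * stats.t.sf(np.abs(tval[vtx]), df=n - 1)

    return MemaMap(
        effect=effect,
        tau2=tau2,
        se=se,
        t=tval,
        p=pval,
        n_subjects=nsub,
        coverage_count=np.zeros(shape, dtype=int),
        cluster_id=np.full(shape, -1, dtype=int),
        significant=np.zeros(shape, dtype=bool),
    )


def coverage_mask(
    electrodes: pd.DataFrame,
    mesh: SurfaceMesh,
    radius_mm: float = 10.0,
    min_patients: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex patient count and coverage mask.

    A patient covers a vertex if any of their electrodes' nearest vertices
    lies within ``radius_mm`` geodesic distance of it.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    counts = np.zeros(mesh.n_vertices, dtype=int)
    if len(electrodes):
        vtx = assign_electrodes(electrodes, mesh)
        for _, rows in pd.DataFrame(
            {"patient": electrodes["patient"].to_numpy(), "vertex": vtx}
        ).groupby("patient"):
            d = geodesic_distances(mesh, rows["vertex"].unique(), limit=radius_mm)
            counts += np.isfinite(d).any(axis=0)
    return counts, counts >= min_patients


def cluster_extent_threshold(
    mesh: SurfaceMesh,
    fwhm: float,
    vertex_alpha: float = 0.01,
    fwer_alpha: float = 0.01,
    n_iter: int = 5000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> int:
    """Minimum cluster size (vertices) controlling family-wise error.

    Monte-Carlo simulation: white noise on the vertices, geodesically
    smoothed at the analysis FWHM and re-standardized to unit variance, is
    thresholded (two-tailed) at the vertex alpha; the maximal edge-connected
    supra-threshold cluster size inside the mask is recorded per iteration.
    The returned k is the smallest cluster size whose null exceedance
    probability is <= fwer_alpha, so requiring observed clusters >= k keeps
    FWER at or below fwer_alpha.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    smat = smoothing_matrix(mesh, fwhm)
    rownorm = np.sqrt(np.asarray(smat.multiply(smat).sum(axis=1)).ravel())
    crit = stats.norm.isf(vertex_alpha / 2.0)
    if mask is None:
        mask = np.ones(mesh.n_vertices, dtype=bool)
    rng = np.random.default_rng(seed)
    maxima = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        z = (smat @ rng.standard_normal(mesh.n_vertices)) / rownorm
        supra = (np.abs(z) > crit) & mask
        sizes = cluster_sizes(label_clusters(mesh, supra))
        maxima[it] = sizes.max() if sizes.size else 0
    for k in range(1, maxima.max() + 2):
        if np.mean(maxima >= k) <= fwer_alpha:
            return k
    return int(maxima.max() + 1)


def subject_vertex_estimates(
    epochs_pct: EpochSet,
    channels: pd.DataFrame,
    mesh: SurfaceMesh,
    window: tuple[float, float],
    fwhm: float = 3.0,
) -> pd.DataFrame:
    """Per-(subject, vertex) window estimates spread over the surface.

    Per electrode the estimate is the across-trial mean of the window-mean
    percent change and its variance the squared SEM.  Each subject's
    electrode estimates are indexed to the nearest vertex and spread to
    vertices within the geodesic Gaussian kernel support (weights
    exp(-d^2/2 sigma^2), normalized per vertex over that subject's
    electrodes); multiple electrodes of one subject thus combine
    fixed-effect before the between-subject model.
    """
    channels = channels.set_index("label").loc[np.asarray(epochs_pct.channel_labels)]
    idx = epochs_pct.window_idx(window)
    trial_means = epochs_pct.data[:, :, idx].mean(axis=2)  # trials x channels
    est = trial_means.mean(axis=0)
    var = trial_means.var(axis=0, ddof=1) / trial_means.shape[0]
    vtx = assign_electrodes(channels.reset_index(), mesh)

    sigma = fwhm * FWHM_TO_SIGMA
    cutoff = KERNEL_CUTOFF_SIGMAS * sigma
    rows = []
    for patient, sel in pd.Series(range(len(channels))).groupby(
        channels["patient"].to_numpy()
    ):
        ei = sel.to_numpy()
        d = geodesic_distances(mesh, vtx[ei], limit=cutoff)  # n_elec x V
        with np.errstate(invalid="ignore"):
            w = np.where(np.isfinite(d), np.exp(-(d**2) / (2 * sigma**2)), 0.0)
        wsum = w.sum(axis=0)
        covered = np.flatnonzero(wsum > 0)
        wn = w[:, covered] / wsum[covered]
        e_v = wn.T @ est[ei]
        v_v = (wn.T**2) @ var[ei]
        rows.append(
            pd.DataFrame(
                {
                    "subject": patient,
                    "vertex": covered,
                    "estimate": e_v,
                    "variance": v_v,
                    "n_electrodes": (w[:, covered] > 0).sum(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def mema_window_analysis(
    epochs_pct: EpochSet,
    channels: pd.DataFrame,
    mesh: SurfaceMesh,
    window: tuple[float, float],
    cfg: AnalysisConfig | None = None,
    mode: str = "static",
    extent_threshold: int | None = None,
    seed: int = 0,
) -> MemaMap:
    """One population map for one analysis window.

    Static mode applies the corrected criteria: vertex p < alpha, cluster
    extent >= the Monte-Carlo threshold, coverage >= min_patients, and
    |group effect| > the 10 percent floor.  Movie mode uses uncorrected
    p < alpha with the 15 percent floor and coverage, no cluster test.
    """
    cfg = cfg or AnalysisConfig()
    if mode not in ("static", "movie"):
        raise ValueError("mode must be 'static' or 'movie'")
    est = subject_vertex_estimates(epochs_pct, channels, mesh, window, cfg.fwhm_mm)
    mm = mema_fit(est, mesh.n_vertices)
    mm.window_ms = tuple(window)
    mm.mode = mode
    counts, cov = coverage_mask(channels, mesh, cfg.coverage_radius_mm, cfg.min_patients)
    mm.coverage_count = counts

    floor = cfg.effect_floor_pct if mode == "static" else cfg.movie_effect_floor_pct
    supra = np.zeros(mesh.n_vertices, dtype=bool)
    ok = np.isfinite(mm.p)
    supra[ok] = (mm.p[ok] < cfg.mema_alpha) & cov[ok]
    if mode == "static":
        if extent_threshold is None:
            extent_threshold = cluster_extent_threshold(
                mesh,
                cfg.fwhm_mm,
                vertex_alpha=cfg.mema_alpha,
                fwer_alpha=cfg.mema_alpha,
                n_iter=cfg.mema_iterations,
                seed=seed,
                mask=cov,
            )
        mm.extent_threshold = int(extent_threshold)
        mm.cluster_id = label_clusters(mesh, supra)
        sizes = cluster_sizes(mm.cluster_id)
        surviving = np.zeros(mesh.n_vertices, dtype=bool)
        for cid, size in enumerate(sizes):
            if size >= extent_threshold:
                surviving |= mm.cluster_id == cid
        mm.significant = surviving & (np.abs(np.nan_to_num(mm.effect)) > floor)
    else:
        mm.cluster_id = label_clusters(mesh, supra)
        mm.significant = supra & (np.abs(np.nan_to_num(mm.effect)) > floor)
    return mm


def movie_windows(
    epoch_extent: tuple[float, float], width_ms: float = 150.0, step_ms: float = 10.0
) -> list[tuple[float, float]]:
    """Sliding windows of ``width_ms`` at ``step_ms`` spacing inside the epoch.

    The number of frames is floor((extent - width) / step) + 1.
    """
    lo, hi = epoch_extent
    n = int(np.floor((hi - lo - width_ms) / step_ms)) + 1
    if n < 1:
        raise ValueError("epoch shorter than one movie window")
    return [(lo + k * step_ms, lo + k * step_ms + width_ms) for k in range(n)]


def mema_movie(
    epochs_pct: EpochSet,
    channels: pd.DataFrame,
    mesh: SurfaceMesh,
    cfg: AnalysisConfig | None = None,
    extent: tuple[float, float] | None = None,
) -> list[MemaMap]:
    """Sequence of movie-mode maps over sliding windows."""
    cfg = cfg or AnalysisConfig()
    if extent is None:
        extent = (float(epochs_pct.times_ms[0]), float(epochs_pct.times_ms[-1]))
    return [
        mema_window_analysis(epochs_pct, channels, mesh, win, cfg, mode="movie")
        for win in movie_windows(extent, cfg.movie_width_ms, cfg.movie_step_ms)
    ]
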