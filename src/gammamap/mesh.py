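"""Triangulated cortical surface meshes and geodesic primitives.

A :class:`SurfaceMesh` bundles vertices (mm), triangular faces and a
per-vertex parcellation label.  Geodesic distances are shortest paths over
the mesh edge graph (Dijkstra), which approximates the true polyhedral
geodesic to within one edge length -- adequate for smoothing kernels whose
FWHM is comparable to or larger than the edge length.

Vertex indices are 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra


@dataclass
class SurfaceMesh:
    """A closed triangulated surface with a per-vertex parcellation.

    Attributes
    ----------
    vertices : (V, 3) float array, coordinates in mm.
    faces : (F, 3) int array, vertex indices of each triangle.
    labels : (V,) array of region names (strings), one per vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray
    _edge_graph: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if len(self.labels) != len(self.vertices):
            raise ValueError("one label per vertex required")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        referenced = np.zeros(len(self.vertices), dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            n_orphan = int((~referenced).sum())
            raise ValueError(f"mesh has {n_orphan} vertices unreferenced by any face")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_regions(self) -> int:
        return len(np.unique(self.labels))

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + len(self.faces)

    def edge_graph(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of edge lengths (mm); cached."""
        if self._edge_graph is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            d = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
            g = sparse.coo_matrix((d, (i, j)), shape=(self.n_vertices, self.n_vertices))
            g = g.maximum(g.T).tocsr()
            self._edge_graph = g
        return self._edge_graph

    def region_vertices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


def geodesic_distances(
    mesh: SurfaceMesh, sources: np.ndarray, limit: float = np.inf
) -> np.ndarray:
    """Geodesic (edge-graph Dijkstra) distance from each source vertex.

    Returns an (n_sources, V) array; entries beyond ``limit`` are ``inf``.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    return dijkstra(mesh.edge_graph(), directed=False, indices=sources, limit=limit)


def label_clusters(mesh: SurfaceMesh, mask: np.ndarray) -> np.ndarray:
    """Label edge-connected components of a boolean vertex mask.

    Returns an (V,) int array: -1 outside the mask, otherwise a cluster id
    in 0..n_clusters-1.  Ids are assigned in scan order of the first vertex
    of each component.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_vertices,):
        raise ValueError("mask must have one entry per vertex")
    out = np.full(mesh.n_vertices, -1, dtype=int)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    sub = mesh.edge_graph()[np.ix_(idx, idx)]
    n, comp = connected_components(sub, directed=False)
    # relabel components by first appearance so ids are deterministic
    order = {}
    relabeled = np.empty_like(comp)
    for k, c in enumerate(comp):
        if c not in order:
            order[c] = len(order)
        relabeled[k] = order[c]
    out[idx] = relabeled
    return out


def cluster_sizes(cluster_ids: np.ndarray) -> np.ndarray:
    """Sizes (vertex counts) of clusters labelled 0..K-1; empty -> []."""
    ids = cluster_ids[cluster_ids >= 0]
    if ids.size == 0:
        return np.zeros(0, dtype=int)
    return np.bincount(ids)
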