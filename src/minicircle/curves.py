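"""Closed 3-D curves representing traced DNA minicircle backbones.

A :class:`ClosedCurve` is an ordered, cyclic sequence of vertex positions in
Angstroms.  The curve is implicitly closed: the last vertex connects back to
the first, and the first/last vertices are neighbours, never duplicates.
All curve geometry used elsewhere in the package (arc length, resampling,
subdivision, nearest-distance queries) lives here.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ClosedCurve", "align_closed_curves", "curve_rmsd"]


class ClosedCurve:
    """An ordered, cyclic list of 3-D vertex positions in Angstroms.

    Parameters
    ----------
    vertices : array-like, shape (n, 3)
        Vertex coordinates in Angstroms.  ``n >= 3``.  The polygon edge
        ``(n-1, 0)`` closes the loop; the first vertex must not repeat the
        last one.
    """

    def __init__(self, vertices: Iterable) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must have shape (n, 3), got {v.shape}")
        if v.shape[0] < 3:
            raise ValueError("a closed curve needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices contain non-finite values")
        if np.allclose(v[0], v[-1]):
            raise ValueError(
                "first and last vertex coincide; closed curves must not "
                "duplicate the closing vertex"
            )
        self.vertices = v

    # -- basic geometry ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def __len__(self) -> int:
        return self.n_vertices

    @property
    def edges(self) -> np.ndarray:
        """Edge vectors, ``edges[i] = v[i+1] - v[i]`` cyclically, shape (n, 3)."""
        return np.roll(self.vertices, -1, axis=0) - self.vertices

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edges, axis=1)

    def arc_length(self) -> float:
        """Total closed-polygon perimeter in Angstroms."""
        return float(self.edge_lengths.sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- resampling and refinement ----------------------------------------

    def resample(self, n: int) -> "ClosedCurve":
        """Resample to ``n`` vertices at uniform arc-length spacing.

        Vertex 0 of the result coincides with vertex 0 of the input; the
        remaining vertices are placed every ``L/n`` along the polyline.
        """
        if n < 3:
            raise ValueError("resampling needs n >= 3")
        seg = self.edge_lengths
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        targets = np.arange(n) * (total / n)
        closed = np.vstack([self.vertices, self.vertices[:1]])
        out = np.empty((n, 3))
        for k in range(3):
            out[:, k] = np.interp(targets, cum, closed[:, k])
        return ClosedCurve(out)

    def subdivide(self) -> "ClosedCurve":
        """Double the vertex count by inserting each edge's midpoint.

        Even output indices are the original vertices; odd indices are exact
        edge midpoints, so the polyline (and its perimeter) is unchanged.
        """
        v = self.vertices
        mid = 0.5 * (v + np.roll(v, -1, axis=0))
        out = np.empty((2 * len(v), 3))
        out[0::2] = v
        out[1::2] = mid
        return ClosedCurve(out)

    def dense_samples(self, spacing: float = 1.0) -> np.ndarray:
        """Points along the polyline roughly every ``spacing`` Angstroms."""
        n = max(int(np.ceil(self.arc_length() / spacing)), 3 * self.n_vertices)
        return self.resample(n).vertices

    # -- transforms --------------------------------------------------------

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "ClosedCurve":
        v = self.vertices * scale
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return ClosedCurve(v)

    def mirrored(self) -> "ClosedCurve":
        """Mirror image (negated x coordinate); flips curve chirality."""
        v = self.vertices.copy()
        v[:, 0] = -v[:, 0]
        return ClosedCurve(v)

    def reversed(self) -> "ClosedCurve":
        """Same polygon traversed in the opposite orientation."""
        return ClosedCurve(self.vertices[::-1].copy())

    # -- queries -----------------------------------------------------------

    def distance_tree(self, spacing: float = 1.0) -> cKDTree:
        """KD-tree over dense polyline samples, for distance-to-curve queries."""
        return cKDTree(self.dense_samples(spacing))

    def min_nonadjacent_distance(self, arc_exclusion: float) -> float:
        """Smallest distance between points separated by more than
        ``arc_exclusion`` Angstroms along the contour.

        Used to verify that a generated curve does not self-intersect at the
        tube-radius scale.
        """
        pts = self.dense_samples(spacing=2.0)
        n = len(pts)
        total = self.arc_length()
        ds = total / n
        k_excl = int(np.ceil(arc_exclusion / ds))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        sep = np.minimum(sep, n - sep)
        d[sep <= k_excl] = np.inf
        return float(d.min())

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ClosedCurve(n={self.n_vertices}, "
                f"length={self.arc_length():.1f} A)")


def align_closed_curves(a: ClosedCurve, b: ClosedCurve) -> tuple[float, int, bool]:
    """Best cyclic/orientation match between two same-size closed curves.

    Returns ``(mean_distance, shift, reversed)`` minimising the mean pairwise
    vertex distance over all cyclic index shifts of ``b`` and both traversal
    orientations.  No rigid-body superposition is applied: the curves are
    assumed to share a coordinate frame (e.g. the same density volume).
    """
    if a.n_vertices != b.n_vertices:
        raise ValueError(
            f"curves have different vertex counts ({a.n_vertices} vs "
            f"{b.n_vertices}); resample before aligning")
    va = a.vertices
    best = (np.inf, 0, False)
    for rev in (False, True):
        vb = b.vertices[::-1] if rev else b.vertices
        for shift in range(a.n_vertices):
            d = np.linalg.norm(va - np.roll(vb, -shift, axis=0), axis=1).mean()
            if d < best[0]:
                best = (float(d), shift, rev)
    return best


def curve_rmsd(curve: ClosedCurve, reference: ClosedCurve,
               spacing: float = 1.0) -> float:
    """Root-mean-square distance from a curve's vertices to a reference curve.

    The reference is sampled densely and each vertex of ``curve`` is matched
    to its nearest point on the reference polyline.  This measures how far
    the traced polygon strays from the true backbone without requiring equal
    vertex counts or a vertex correspondence.
    """
    tree = reference.distance_tree(spacing)
    d, _ = tree.query(curve.vertices)
    return float(np.sqrt(np.mean(d ** 2)))
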