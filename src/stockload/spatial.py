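"""Geographic coordinates in meters and distance-based Moran's eigenvector maps.

db-MEMs are orthogonal spatial basis functions: take the Euclidean distance
matrix among sites, truncate it at the longest edge of its minimum spanning
tree (distances beyond the threshold are replaced by four times the
threshold), double-center -D**2/2 and keep the eigenvectors with positive
eigenvalues.  They enter constrained ordinations as spatial covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

EARTH_RADIUS_M = 6_371_000.0

__all__ = ["geo_to_meters", "mst_longest_edge", "build_dbmem", "MemBasis"]


def geo_to_meters(lat, lon, alt=None, origin=None) -> np.ndarray:
    """Project latitude/longitude (degrees) to x/y meters on a local tangent
    plane (equirectangular about ``origin``, default the centroid); altitude
    passes through as z.  Adequate at the spatial extent of a lake survey.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
        raise ValueError("coordinates out of range")
    if origin is None:
        origin = (lat.mean(), lon.mean())
    lat0, lon0 = origin
    y = np.deg2rad(lat - lat0) * EARTH_RADIUS_M
    x = np.deg2rad(lon - lon0) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat0))
    if alt is None:
        return np.column_stack([x, y])
    return np.column_stack([x, y, np.asarray(alt, dtype=float)])


def mst_longest_edge(d: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of a distance matrix."""
    mst = minimum_spanning_tree(d)
    return float(mst.toarray().max())


@dataclass
class MemBasis:
    eigenvectors: np.ndarray     # sites x axes, orthonormal, centered
    eigenvalues: np.ndarray      # decreasing, strictly positive
    truncation_threshold: float

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


def build_dbmem(coords: np.ndarray, truncation: float | None = None,
                beyond_factor: float = 4.0) -> MemBasis:
    """Distance-based Moran's eigenvector map from site coordinates (meters).

    Parameters
    ----------
    coords : (n_sites, 2 or 3) array
    truncation : override for the truncation threshold; default is the
        longest minimum-spanning-tree edge, which keeps the connection graph
        minimally connected.
    beyond_factor : distances above the threshold are replaced by
        ``beyond_factor * threshold`` (4 is the conventional choice).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least three sites")
    d = squareform(pdist(coords))
    if truncation is None:
        truncation = mst_longest_edge(d)
    if truncation <= 0:
        raise ValueError("coincident sites give a zero truncation threshold; "
                         "jitter coordinates or supply a threshold")
    dt = np.where(d > truncation, beyond_factor * truncation, d)
    np.fill_diagonal(dt, 0.0)
    # Gower double-centering of -dt^2/2
    a = -0.5 * dt ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > 1e-9 * max(w.max(), 1e-30)
    return MemBasis(v[:, keep], w[keep], float(truncation))
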