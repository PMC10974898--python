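"""Optimal rigid superposition of paired point sets.

Implements the Kabsch algorithm: the proper rotation minimizing the paired
root-mean-square deviation is obtained from the singular value decomposition
of the cross-covariance matrix, with a sign flip on the smallest singular
direction when the raw optimum is a reflection.  Both point sets are centered
at their centroids before the rotation is solved; the reported translation is
the full map ``y_centroid - R @ x_centroid`` so that ``R @ x + t`` is the
optimally posed copy of ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuperposeResult", "rmsd_paired", "kabsch_fit", "rotation_about_axis"]

#: Singular values below this fraction of the largest are treated as zero
#: when deciding whether a point set is rank-deficient (collinear/degenerate).
_RANK_RTOL = 1e-9


@dataclass(frozen=True)
class SuperposeResult:
    """Rigid map ``x -> rotation @ x + translation`` and its paired RMSD."""

    rotation: np.ndarray  # (3, 3) proper rotation, det = +1
    translation: np.ndarray  # (3,) Angstrom
    rmsd: float  # Angstrom, over the n paired points after the map
    degenerate: bool = False  # True if the moving set was (near-)collinear

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid map to an (n, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def _as_points(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1 and arr.size == 3:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def rmsd_paired(x, y) -> float:
    """RMSD between two equally long point lists, without superposition.

    ``sqrt(mean_i |x_i - y_i|^2)`` over the n paired points.
    """
    xa = _as_points(x, "x")
    ya = _as_points(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"point counts differ: {len(xa)} vs {len(ya)}")
    if len(xa) == 0:
        raise ValueError("RMSD of zero points is undefined")
    return float(np.sqrt(np.mean(np.sum((xa - ya) ** 2, axis=1))))


def kabsch_fit(x, y) -> SuperposeResult:
    """Least-RMSD proper rotation + translation mapping points ``x`` onto ``y``.

    Parameters
    ----------
    x, y
        Paired (n, 3) coordinates, n >= 3.  ``x`` is the moving set.

    Returns
    -------
    SuperposeResult
        With ``rmsd == rmsd_paired(transform(x), y)`` to machine precision.
        ``degenerate`` is set when the centered moving set is rank < 2
        (collinear points); the fit is still returned and is optimal, but the
        rotation is only unique up to a spin about the degenerate axis.
    """
    xa = _as_points(x, "x")
    ya = _as_points(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"point counts differ: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise ValueError("kabsch_fit needs at least 3 paired points")

    xc = xa.mean(axis=0)
    yc = ya.mean(axis=0)
    x0 = xa - xc
    y0 = ya - yc

    # Cross-covariance; SVD gives the optimal orthogonal map, the d-flip
    # restricts it to a proper rotation (no reflection).
    cov = x0.T @ y0
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate covariance
        d = 1.0
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T

    smax = s[0] if s[0] > 0 else 1.0
    degenerate = bool(np.sum(s > _RANK_RTOL * smax) < 2)

    trans = yc - rot @ xc
    rmsd = rmsd_paired(xa @ rot.T + trans, ya)
    return SuperposeResult(rotation=rot, translation=trans, rmsd=rmsd, degenerate=degenerate)


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of ``angle`` radians
    about the (not necessarily unit) vector ``axis`` through the origin."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / norm
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )
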