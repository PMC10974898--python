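"""Independent superposition oracles for cross-checking the SVD path.

The quaternion (Horn) method solves the same optimal-rotation problem by an
eigendecomposition of a 4x4 key matrix, a genuinely different algorithm from
the Kabsch SVD route; because unit quaternions parametrize SO(3) only, it can
never return a reflection.  The brute-force sampler provides an upper-bound
reference over dense random rotations.
"""

import numpy as np


def horn_fit(x, y):
    """Optimal proper rotation/translation by quaternion eigendecomposition.

    Returns (rotation, translation, rmsd) minimizing the paired RMSD of
    ``rotation @ x + translation`` against ``y``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    s = x0.T @ y0
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    _, vec = np.linalg.eigh(key)
    qw, qx, qy, qz = vec[:, -1]
    rot = np.array(
        [
            [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
            [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
            [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)],
        ]
    )
    trans = yc - rot @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((x @ rot.T + trans - y) ** 2, axis=1))))
    return rot, trans, rmsd


def brute_force_min_rmsd(x, y, n_rotations=10000, seed=0):
    """Min RMSD over random proper rotations with optimal translation.

    An upper-bound oracle: the true optimum can only be lower.
    """
    from scipy.spatial.transform import Rotation

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x0 = x - x.mean(axis=0)
    y0 = y - y.mean(axis=0)
    best = np.inf
    mats = Rotation.random(n_rotations, random_state=seed).as_matrix()
    for rot in mats:
        r = np.sqrt(np.mean(np.sum((x0 @ rot.T - y0) ** 2, axis=1)))
        best = min(best, float(r))
    return best
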