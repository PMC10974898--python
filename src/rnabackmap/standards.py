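"""Idealized A-form standard nucleotides and helix constants.

The per-base standard fragments (the index-0 template of every base type)
are constructed at first use, deterministically, in three steps:

1. Ribose + backbone from internal coordinates: standard bond lengths and
   angles, a C3'-endo sugar (pseudorotation phase 18 deg, amplitude 38 deg),
   and A-form backbone torsions (gamma 54, beta 178, chi -158 deg).  The
   five-membered ring is solved by least squares against its target bonds,
   angles, and pseudorotation torsions; exocyclic atoms are attached with
   the stereochemical face taken from the chemical component dictionary so
   the D-ribose configuration is preserved.
2. The planar base ring is taken from the CCD ideal geometry (bundled with
   biotite, accurate for bond lengths/angles within the base) and docked
   rigidly onto three anchor positions generated from the glycosidic torsion.
3. The finished nucleotide is posed in a helical frame: a rigid placement is
   solved (deterministic multi-start least squares) such that propagating it
   with the A-form helix operator (twist 32.7 deg, rise 2.81 A about z)
   produces the canonical inter-residue backbone geometry -- O3'-P bond of
   1.60 A, standard flanking bond angles, epsilon/zeta/alpha torsions -- with
   a steric-clearance penalty keeping stacked neighbours outside hard-sphere
   contact.

All four base types share one backbone construction and one placement, so a
mixed-sequence strand propagated with the helix operator is covalently
continuous regardless of sequence.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy.optimize import least_squares

from .chem import BASE_ATOMS, STANDARD_BASES, VDW_RADII, element_of, glycosidic_nitrogen

__all__ = [
    "A_FORM_TWIST_DEG",
    "A_FORM_RISE",
    "helix_operator",
    "standard_nucleotide",
    "standard_fragment_coords",
]

#: A-form helical parameters used to propagate the standard nucleotide.
A_FORM_TWIST_DEG = 32.7
A_FORM_RISE = 2.81  # Angstrom per residue along the helix axis

# ---------------------------------------------------------------------------
# internal-coordinate targets (Angstrom / degrees)

_RING_BONDS = {
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.524,
    ("C4'", "O4'"): 1.451,
    ("O4'", "C1'"): 1.414,
}
_RING_ANGLES = {
    ("C4'", "O4'", "C1'"): 109.9,
    ("O4'", "C1'", "C2'"): 105.8,
    ("C1'", "C2'", "C3'"): 101.5,
    ("C2'", "C3'", "C4'"): 102.6,
    ("C3'", "C4'", "O4'"): 104.0,
}
_PSEUDOROTATION_PHASE = 18.0  # deg, C3'-endo
_PSEUDOROTATION_AMPLITUDE = 38.0  # deg

_TORSION_GAMMA = 54.0  # O5'-C5'-C4'-C3'
_TORSION_BETA = 178.0  # P-O5'-C5'-C4'
_TORSION_CHI = -158.0  # O4'-C1'-N9-C4 (purine) / O4'-C1'-N1-C2 (pyrimidine), anti

# inter-residue targets used by the helical placement solve
_BOND_O3P = 1.60  # the backmapping bond-repair target value
_ANGLE_C3_O3_P = 119.7
_ANGLE_O3_P_O5 = 104.0
_TORSION_EPSILON = -153.0  # C4'-C3'-O3'-P(+1)
_TORSION_ZETA = -71.0  # C3'-O3'-P(+1)-O5'(+1)
_TORSION_ALPHA = -68.0  # O3'-P(+1)-O5'(+1)-C5'(+1)

#: atom pairs across the O3'(i)-P(i+1) linkage excluded from clearance checks
_LINKAGE_EXCLUDE = {
    ("O3'", "P"), ("O3'", "OP1"), ("O3'", "OP2"), ("O3'", "O5'"), ("O3'", "C5'"),
    ("C3'", "P"), ("C3'", "O5'"), ("C3'", "OP1"), ("C3'", "OP2"),
    ("C4'", "P"), ("C2'", "P"),
}


def helix_operator(n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation advancing a residue ``n`` steps along the helix."""
    ang = math.radians(A_FORM_TWIST_DEG) * n
    c, s = math.cos(ang), math.sin(ang)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, A_FORM_RISE * n])


# ---------------------------------------------------------------------------
# elementary constructions


def _angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def _torsion(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    # IUPAC sign convention (matches biotite.structure.dihedral)
    return math.degrees(math.atan2(-np.dot(m, n2), np.dot(n1, n2)))


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D with |CD|=bond, angle(B,C,D), torsion(A,B,C,D)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return c + basis @ d_local


def _attach(r, nbr_a, nbr_b, bond: float, ang_a: float, ang_b: float, side: float) -> np.ndarray:
    """Place an exocyclic atom X bonded to ring atom ``r``.

    ``ang_a``/``ang_b`` are the target angles nbr_a-r-X and nbr_b-r-X in
    degrees; ``side`` (+1/-1) picks the face relative to the plane
    (nbr_a, r, nbr_b), with the normal taken as u_a x u_b.
    """
    ua = nbr_a - r
    ua /= np.linalg.norm(ua)
    ub = nbr_b - r
    ub /= np.linalg.norm(ub)
    n = np.cross(ua, ub)
    n /= np.linalg.norm(n)
    ca = math.cos(math.radians(ang_a))
    cb = math.cos(math.radians(ang_b))
    # d = alpha*ua + beta*ub + gamma*n with d.ua = ca, d.ub = cb, |d| = 1
    g = np.dot(ua, ub)
    mat = np.array([[1.0, g], [g, 1.0]])
    alpha, beta = np.linalg.solve(mat, np.array([ca, cb]))
    rad = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * g)
    gamma = math.sqrt(max(rad, 0.0)) * (1.0 if side >= 0 else -1.0)
    d = alpha * ua + beta * ub + gamma * n
    return r + bond * d / np.linalg.norm(d)


def _side_sign(r, nbr_a, nbr_b, x) -> float:
    """Which face of the (nbr_a, r, nbr_b) plane atom ``x`` lies on."""
    ua = nbr_a - r
    ub = nbr_b - r
    n = np.cross(ua, ub)
    return 1.0 if np.dot(x - r, n) >= 0 else -1.0


# ---------------------------------------------------------------------------
# CCD reference geometry (bond lengths/angles and stereochemical faces only;
# the CCD ideal conformation itself has a flat ribose and is not used as-is)


@functools.lru_cache(maxsize=None)
def _ccd_coords(base_type: str) -> dict[str, np.ndarray]:
    import biotite.structure.info as info

    array = info.residue(base_type)
    array = array[array.element != "H"]
    return {name: coord.copy() for name, coord in zip(array.atom_name, array.coord)}


# ---------------------------------------------------------------------------
# ribose + backbone construction


def _solve_ring() -> dict[str, np.ndarray]:
    """Least-squares C3'-endo ribose ring (C1', C2', C3', C4', O4')."""
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    p_phase = math.radians(_PSEUDOROTATION_PHASE)
    tau = _PSEUDOROTATION_AMPLITUDE
    nu = [tau * math.cos(p_phase + math.radians(144.0) * (j - 2)) for j in range(5)]
    torsion_targets = {
        ("C4'", "O4'", "C1'", "C2'"): nu[0],
        ("O4'", "C1'", "C2'", "C3'"): nu[1],
        ("C1'", "C2'", "C3'", "C4'"): nu[2],
        ("C2'", "C3'", "C4'", "O4'"): nu[3],
        ("C3'", "C4'", "O4'", "C1'"): nu[4],
    }

    idx = {n: i for i, n in enumerate(names)}

    def unpack(x):
        return x.reshape(5, 3)

    def residuals(x):
        pos = unpack(x)
        res = []
        for (a, b), target in _RING_BONDS.items():
            res.append(np.linalg.norm(pos[idx[a]] - pos[idx[b]]) - target)
        for (a, b, c), target in _RING_ANGLES.items():
            res.append(math.radians(_angle(pos[idx[a]], pos[idx[b]], pos[idx[c]]) - target))
        for (a, b, c, d), target in torsion_targets.items():
            tors = _torsion(pos[idx[a]], pos[idx[b]], pos[idx[c]], pos[idx[d]])
            res.append(0.5 * math.radians(((tors - target + 180.0) % 360.0) - 180.0))
        return np.array(res)

    # start from a regular pentagon in xy with a small out-of-plane twist
    start = np.zeros((5, 3))
    for i in range(5):
        theta = 2 * math.pi * i / 5
        start[i] = [1.25 * math.cos(theta), 1.25 * math.sin(theta), 0.05 * (-1) ** i]
    sol = least_squares(residuals, start.ravel(), method="lm", xtol=1e-15, ftol=1e-15)
    pos = unpack(sol.x)
    return {n: pos[idx[n]] for n in names}


@functools.lru_cache(maxsize=None)
def _build_local_nucleotide(base_type: str) -> tuple[tuple[str, tuple[float, float, float]], ...]:
    """Full heavy-atom standard nucleotide in an arbitrary local frame."""
    ccd = _ccd_coords(base_type)
    pos = dict(_solve_ring())

    def ccd_side(r, a, b, x):
        return _side_sign(ccd[r], ccd[a], ccd[b], ccd[x])

    # exocyclic substituents; faces copied from the CCD so stereochemistry
    # (D-ribose, beta-glycoside) is preserved
    pos["C5'"] = _attach(
        pos["C4'"], pos["C3'"], pos["O4'"], 1.510, 115.5, 109.2,
        ccd_side("C4'", "C3'", "O4'", "C5'"),
    )
    pos["O3'"] = _attach(
        pos["C3'"], pos["C4'"], pos["C2'"], 1.423, 113.0, 111.0,
        ccd_side("C3'", "C4'", "C2'", "O3'"),
    )
    pos["O2'"] = _attach(
        pos["C2'"], pos["C3'"], pos["C1'"], 1.413, 110.7, 108.4,
        ccd_side("C2'", "C3'", "C1'", "O2'"),
    )
    n_name = glycosidic_nitrogen(base_type)
    pos[n_name] = _attach(
        pos["C1'"], pos["O4'"], pos["C2'"], 1.470, 108.2, 114.0,
        ccd_side("C1'", "O4'", "C2'", n_name),
    )

    # 5' arm: gamma and beta torsions
    pos["O5'"] = _nerf(pos["C3'"], pos["C4'"], pos["C5'"], 1.440, 111.5, _TORSION_GAMMA)
    pos["P"] = _nerf(pos["C4'"], pos["C5'"], pos["O5'"], 1.593, 120.9, _TORSION_BETA)
    # the O3'(i-1) substituent of P sits at torsion alpha; OP1/OP2 stagger it
    pos["OP1"] = _nerf(pos["C5'"], pos["O5'"], pos["P"], 1.485, 108.1, _TORSION_ALPHA + 120.0)
    pos["OP2"] = _nerf(pos["C5'"], pos["O5'"], pos["P"], 1.485, 108.3, _TORSION_ALPHA - 120.0)

    # dock the rigid CCD base onto chi-derived anchors
    if base_type in ("A", "G"):
        anchor2, anchor3 = "C4", "C8"
    else:
        anchor2, anchor3 = "C2", "C6"
    bond2 = float(np.linalg.norm(ccd[anchor2] - ccd[n_name]))
    bond3 = float(np.linalg.norm(ccd[anchor3] - ccd[n_name]))
    ang2 = _angle(ccd["C1'"], ccd[n_name], ccd[anchor2])
    ang3 = _angle(ccd["C1'"], ccd[n_name], ccd[anchor3])
    t2 = _nerf(pos["O4'"], pos["C1'"], pos[n_name], bond2, ang2, _TORSION_CHI)
    t3 = _nerf(pos["O4'"], pos["C1'"], pos[n_name], bond3, ang3, _TORSION_CHI + 180.0)

    from .superpose import kabsch_fit  # local import avoids cycle at load time

    base_names = list(BASE_ATOMS[base_type])
    src = np.array([ccd[n_name], ccd[anchor2], ccd[anchor3]])
    dst = np.array([pos[n_name], t2, t3])
    fit = kabsch_fit(src, dst)
    for name in base_names:
        pos[name] = fit.transform(ccd[name][None, :])[0]

    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]
    order += base_names
    return tuple((n, tuple(float(v) for v in pos[n])) for n in order)


# ---------------------------------------------------------------------------
# helical placement


def _placement_residuals(params, backbone, clearance_atoms):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    trans = params[3:]
    h_rot, h_trans = helix_operator(1)

    def place(p):
        return rot @ p + trans

    def nxt(p):
        return h_rot @ place(p) + h_trans

    o3 = place(backbone["O3'"])
    c3 = place(backbone["C3'"])
    c4 = place(backbone["C4'"])
    p1 = nxt(backbone["P"])
    o5_1 = nxt(backbone["O5'"])
    c5_1 = nxt(backbone["C5'"])

    def wrap(x):
        return ((x + 180.0) % 360.0) - 180.0

    res = [
        np.linalg.norm(o3 - p1) - _BOND_O3P,
        2.0 * math.radians(_angle(c3, o3, p1) - _ANGLE_C3_O3_P),
        2.0 * math.radians(_angle(o3, p1, o5_1) - _ANGLE_O3_P_O5),
        0.7 * math.radians(wrap(_torsion(c4, c3, o3, p1) - _TORSION_EPSILON)),
        0.7 * math.radians(wrap(_torsion(c3, o3, p1, o5_1) - _TORSION_ZETA)),
        0.7 * math.radians(wrap(_torsion(o3, p1, o5_1, c5_1) - _TORSION_ALPHA)),
    ]

    # steric clearance of residue 0 against residues +1 and +2 (hinge
    # penalties; fixed residual count so LM can run)
    names = list(clearance_atoms)
    placed = {n: place(clearance_atoms[n]) for n in names}
    for step in (1, 2):
        s_rot, s_trans = helix_operator(step)
        moved = {n: s_rot @ placed[n] + s_trans for n in names}
        for a in names:
            for b in names:
                if step == 1 and ((a, b) in _LINKAGE_EXCLUDE):
                    res.append(0.0)
                    continue
                lim = VDW_RADII[element_of(a)] + VDW_RADII[element_of(b)] + 0.05
                d = np.linalg.norm(placed[a] - moved[b])
                res.append(3.0 * max(0.0, lim - d))
    return np.array(res)


def _natural_screw(local: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Initial placement from the nucleotide's own screw propagation.

    The 3'-neighbour's backbone is continued from residue 0 by NeRF using the
    target inter-residue geometry; the rigid map residue0 -> residue1 is then
    a screw motion whose axis is aligned to z to seed the optimizer.
    """
    from .superpose import kabsch_fit

    p1 = _nerf(local["C4'"], local["C3'"], local["O3'"], _BOND_O3P,
               _ANGLE_C3_O3_P, _TORSION_EPSILON)
    o5_1 = _nerf(local["C3'"], local["O3'"], p1, 1.593, _ANGLE_O3_P_O5, _TORSION_ZETA)
    c5_1 = _nerf(local["O3'"], p1, o5_1, 1.440, 120.9, _TORSION_ALPHA)
    c4_1 = _nerf(p1, o5_1, c5_1, 1.510, 111.5, _TORSION_BETA)
    c3_1 = _nerf(o5_1, c5_1, c4_1, 1.524, 115.5, _TORSION_GAMMA)

    src = np.array([local["P"], local["O5'"], local["C5'"], local["C4'"], local["C3'"]])
    dst = np.array([p1, o5_1, c5_1, c4_1, c3_1])
    fit = kabsch_fit(src, dst)
    rm, tm = fit.rotation, fit.translation

    # screw axis of x -> rm x + tm
    w = np.array([rm[2, 1] - rm[1, 2], rm[0, 2] - rm[2, 0], rm[1, 0] - rm[0, 1]])
    sin_t = np.linalg.norm(w) / 2.0
    cos_t = (np.trace(rm) - 1.0) / 2.0
    axis = w / np.linalg.norm(w)
    rise = float(np.dot(axis, tm))
    if rise < 0:  # orient the axis along the advance direction
        axis = -axis
        rise = -rise
    theta = math.atan2(sin_t, cos_t) * (1.0 if np.dot(w, axis) >= 0 else -1.0)
    # a point on the axis: (I - rm) c = tm - rise*axis, solved in the plane
    # orthogonal to the axis (the axial component of c is free)
    a_mat = np.eye(3) - rm
    rhs = tm - rise * axis
    c_pt, *_ = np.linalg.lstsq(a_mat + np.outer(axis, axis), rhs, rcond=None)

    # frame change: axis -> z, axis point -> origin
    z = axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, z)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    x = seed - np.dot(seed, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    q = np.vstack([x, y, z])  # rows: new basis
    del theta  # handedness is taken up by the optimizer polish
    return q, -q @ c_pt


@functools.lru_cache(maxsize=None)
def _helical_placement() -> tuple[np.ndarray, np.ndarray]:
    """Rigid map posing the local-frame nucleotide in the helix frame.

    Solved once, deterministically: the nucleotide's natural screw axis is
    aligned to z as the initial guess, then polished by least squares
    against the imposed helix operator (guanine supplies the clearance
    terms; it has the largest base).  Gauge-fixed so the P atom sits on the
    +x axis at z = 0.
    """
    from scipy.spatial.transform import Rotation

    local = {n: np.array(c) for n, c in _build_local_nucleotide("G")}
    backbone = {k: local[k] for k in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                                      "C3'", "O3'", "C2'", "O2'", "C1'")}
    q0, t0 = _natural_screw(backbone)
    x0 = np.concatenate([Rotation.from_matrix(q0).as_rotvec(), t0])
    sol = least_squares(
        _placement_residuals, x0, args=(backbone, local),
        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=6000,
    )
    rot = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    trans = sol.x[3:].copy()

    # gauge fix: P on the +x axis, at z = 0
    p = rot @ local["P"] + trans
    phi = math.atan2(p[1], p[0])
    c, s = math.cos(-phi), math.sin(-phi)
    gauge = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rot = gauge @ rot
    trans = gauge @ trans
    trans[2] -= (rot @ local["P"] + trans)[2]
    return rot, trans


@functools.lru_cache(maxsize=None)
def standard_nucleotide(base_type: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of the standard A-form nucleotide, helix frame.

    The helix axis is z; applying :func:`helix_operator` ``i`` times yields
    residue ``i`` of an ideal strand.
    """
    if base_type not in STANDARD_BASES:
        raise ValueError(f"not a standard base type: {base_type!r}")
    rot, trans = _helical_placement()
    local = _build_local_nucleotide(base_type)
    return {n: rot @ np.array(c) + trans for n, c in local}


def standard_fragment_coords(base_type: str) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Standard nucleotide plus the P position of the 3'-adjacent residue."""
    coords = standard_nucleotide(base_type)
    h_rot, h_trans = helix_operator(1)
    next_p = h_rot @ coords["P"] + h_trans
    return {n: c.copy() for n, c in coords.items()}, next_p
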