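"""Elementary 3D geometry for nucleic-acid structures.

Idealized planar base templates, base reference frames, signed torsion
angles, internal-coordinate (NeRF) atom placement and least-squares rigid
superposition.  Everything downstream (annotation, eRMSD, helical
parameters, the synthetic A-form builder) is built on the conventions
defined here.

Two frame conventions coexist:

* the *ring frame* (``base_frame``): origin at the centroid of the
  six-membered ring, x toward the Watson-Crick edge, z along the base
  normal.  Used for pairing/stacking classification and for eRMSD.
* the *standard frame* (``standard_frame``): the standard nucleic-acid
  base reference frame in which an ideal Watson-Crick pair is generated
  by a 180 deg rotation of the partner about the x axis.  Used by the
  helical-parameter code and the A-form builder.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


# ---------------------------------------------------------------------------
# Idealized planar bases, standard reference frame coordinates (x, y; z = 0).
# Ring + exocyclic heavy atoms and the glycosidic C1'.  In this frame an
# ideal Watson-Crick pair is formed by mapping the partner through
# (x, y, z) -> (x, -y, -z); the resulting donor-acceptor distances are
# 2.87-3.02 A (asserted in the test suite).
# ---------------------------------------------------------------------------

_BASE_XY: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124), "C1'": (-2.479, 5.346),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), "C1'": (-2.477, 5.399),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068), "C1'": (-2.477, 5.402),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053), "C1'": (-2.481, 5.354),
    },
}

#: atoms of the six-membered ring, used for the ring frame of every base
RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

#: glycosidic nitrogen and the chi-reference ring atom
GLYCOSIDIC = {"A": ("N9", "C4"), "G": ("N9", "C4"),
              "C": ("N1", "C2"), "U": ("N1", "C2")}

# Hydrogen construction recipes: H attached to X, placed in the base plane
# along the external bisector of (Y-X-Z) at the given bond length.
_H_RECIPES: dict[str, list[tuple[str, str, str, str, float]]] = {
    "A": [("H2", "C2", "N1", "N3", 1.08), ("H8", "C8", "N7", "N9", 1.08),
          ("H61", "N6", "C6", "C6", 1.01), ("H62", "N6", "C6", "C6", 1.01)],
    "G": [("H1", "N1", "C2", "C6", 1.01), ("H8", "C8", "N7", "N9", 1.08),
          ("H21", "N2", "C2", "C2", 1.01), ("H22", "N2", "C2", "C2", 1.01)],
    "C": [("H5", "C5", "C4", "C6", 1.08), ("H6", "C6", "C5", "N1", 1.08),
          ("H41", "N4", "C4", "C4", 1.01), ("H42", "N4", "C4", "C4", 1.01)],
    "U": [("H3", "N3", "C2", "C4", 1.01), ("H5", "C5", "C4", "C6", 1.08),
          ("H6", "C6", "C5", "N1", 1.08)],
}

#: imino donor (heavy atom, proton) for the two imino-bearing bases
IMINO = {"G": ("N1", "H1"), "U": ("N3", "H3")}


def _build_planar_base(base: str) -> dict[str, np.ndarray]:
    xy = _BASE_XY[base]
    coords = {n: np.array([x, y, 0.0]) for n, (x, y) in xy.items()}
    for name, x, y, z, blen in _H_RECIPES[base]:
        px, py, pz = coords[x], coords[y], coords[z]
        if y == z:  # amino H pair: split +-60 deg about the C-N axis, in plane
            axis = coords[x] - coords[y]
            axis /= np.linalg.norm(axis)
            perp = np.array([-axis[1], axis[0], 0.0])
            sign = 1.0 if name.endswith("1") else -1.0
            direction = np.cos(np.pi / 3) * axis + sign * np.sin(np.pi / 3) * perp
        else:
            direction = 2 * px - py - pz
            direction = direction / np.linalg.norm(direction)
        coords[name] = px + blen * direction
    return coords


#: full planar templates in standard-frame coordinates (z = 0 plane)
BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    b: _build_planar_base(b) for b in "ACGU"
}

# Ring-frame convention: origin at 6-ring centroid; x toward the WC edge
# (the -y direction of the standard frame), z = standard-frame z.
_RING_FRAME_AXES = np.array([
    [0.0, 1.0, 0.0],
    [-1.0, 0.0, 0.0],
    [0.0, 0.0, 1.0],
])  # columns: x_ring, y_ring, z_ring expressed in standard coordinates


def ring_template(base: str) -> np.ndarray:
    """6-ring atom coordinates in ring-frame coordinates, shape (6, 3)."""
    pts = np.array([BASE_TEMPLATES[base][a] for a in RING6])
    centroid = pts.mean(axis=0)
    return (pts - centroid) @ _RING_FRAME_AXES


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix R, translation t, rmsd) such that
    ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    rmsd = rssd / np.sqrt(len(mobile))
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t, rmsd


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-8:
        raise GeometryError("coincident consecutive points in torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("collinear points: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2n
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle_deg(p1, p2, p3) -> float:
    """Angle at p2 between p1 and p3, degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from reference atoms a-b-c with internal coordinates.

    ``bond`` = |c-D| (A), ``angle`` = b-c-D (deg), ``torsion`` = a-b-c-D (deg).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Idealized A-form ribose-phosphate backbone, attached rigidly in each
# base's standard-frame coordinates.  The placement torsions below were
# solved once by least squares so that a helix-symmetric strand (twist
# +32.8 deg, rise 2.8 A about +z) exhibits backbone torsions inside the
# canonical A-form windows (alpha -69, beta -180, gamma 51, delta 84,
# epsilon -157, zeta -63, chi -154 deg) with a near-ideal O3'-P linkage
# (1.58 A).  The geometry is idealized, not fibre-diffraction data.
# ---------------------------------------------------------------------------

_BB_PARAMS = {
    "chi": -153.728,   # O4'-C1'-N-Cref
    "t2": 92.763,      # C2'-C1'-N-Cref
    "nu1": -40.293,    # O4'-C1'-C2'-C3'
    "nu2": 31.156,     # C1'-C2'-C3'-C4'
    "t_o3": -230.101,  # C1'-C2'-C3'-O3'
    "t_c5": -164.933,  # C2'-C3'-C4'-C5'
    "gamma": 50.567,   # C3'-C4'-C5'-O5'
    "beta": -179.703,  # C4'-C5'-O5'-P
}

_BACKBONE_CACHE: dict[str, dict[str, np.ndarray]] = {}


def _tetrahedral_h(center, neighbours, bond=1.09):
    """Positions completing a tetrahedral center, opposite the neighbours."""
    units = [(n - center) / np.linalg.norm(n - center) for n in neighbours]
    if len(units) == 3:
        d = -sum(units)
        return [center + bond * d / np.linalg.norm(d)]
    b1, b2 = units
    bis = -(b1 + b2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    half = np.radians(54.75)
    return [center + bond * (np.cos(half) * bis + s * np.sin(half) * perp)
            for s in (1.0, -1.0)]


def backbone_template(base: str) -> dict[str, np.ndarray]:
    """Ribose + phosphate atoms (incl. sugar hydrogens) in the
    standard-frame coordinates of the given base."""
    if base in _BACKBONE_CACHE:
        return {k: v.copy() for k, v in _BACKBONE_CACHE[base].items()}
    p = _BB_PARAMS
    T = BASE_TEMPLATES[base]
    n_name, ref_name = GLYCOSIDIC[base]
    N, Cref, C1 = T[n_name], T[ref_name], T["C1'"]
    bb: dict[str, np.ndarray] = {}
    bb["O4'"] = nerf_place(Cref, N, C1, 1.414, 108.2, p["chi"])
    bb["C2'"] = nerf_place(Cref, N, C1, 1.529, 113.4, p["t2"])
    bb["C3'"] = nerf_place(bb["O4'"], C1, bb["C2'"], 1.525, 101.3, p["nu1"])
    bb["C4'"] = nerf_place(C1, bb["C2'"], bb["C3'"], 1.524, 102.6, p["nu2"])
    bb["O3'"] = nerf_place(C1, bb["C2'"], bb["C3'"], 1.423, 109.5, p["t_o3"])
    bb["C5'"] = nerf_place(bb["C2'"], bb["C3'"], bb["C4'"], 1.510, 115.5, p["t_c5"])
    bb["O5'"] = nerf_place(bb["C3'"], bb["C4'"], bb["C5'"], 1.440, 110.2, p["gamma"])
    bb["P"] = nerf_place(bb["C4'"], bb["C5'"], bb["O5'"], 1.593, 120.9, p["beta"])
    bb["OP1"] = nerf_place(bb["C5'"], bb["O5'"], bb["P"], 1.485, 108.1, -100.0)
    bb["OP2"] = nerf_place(bb["C5'"], bb["O5'"], bb["P"], 1.485, 108.1, 135.0)
    bb["O2'"] = nerf_place(bb["C4'"], bb["C3'"], bb["C2'"], 1.413, 110.0,
                           p["nu2"] - 122.0)
    bb["H1'"], = _tetrahedral_h(C1, [N, bb["O4'"], bb["C2'"]])
    bb["H2'"], = _tetrahedral_h(bb["C2'"], [C1, bb["C3'"], bb["O2'"]])
    bb["H3'"], = _tetrahedral_h(bb["C3'"], [bb["C2'"], bb["C4'"], bb["O3'"]])
    bb["H4'"], = _tetrahedral_h(bb["C4'"], [bb["C3'"], bb["O4'"], bb["C5'"]])
    h5a, h5b = _tetrahedral_h(bb["C5'"], [bb["C4'"], bb["O5'"]])
    bb["H5'"], bb["H5''"] = h5a, h5b
    _BACKBONE_CACHE[base] = bb
    return {k: v.copy() for k, v in bb.items()}


#: element symbol from a PDB-v3 RNA atom name
def element_of(name: str) -> str:
    return "H" if name.startswith("H") else name[0]
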