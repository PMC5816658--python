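"""Weighted observables over an RNA ensemble.

Three families of observables, each reported as a *stability*: the
weight-summed fraction of snapshots in which a geometric criterion
holds (imino hydrogen bonds, base-pair and stacking annotations), and
helical rise/twist of a stem.

Stabilities are linear in the weight vector, lie in [0, 1], and reduce
to plain occurrence fractions under uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import IMINO, GeometryError, angle_deg
from .structure import Conformation, Ensemble, check_simplex


# ---------------------------------------------------------------------------
# Imino hydrogen bonds
# ---------------------------------------------------------------------------

#: acceptor atoms offered by each base to an imino donor (joint set for U)
ACCEPTOR_ATOMS = {"A": ("N1",), "C": ("N3",), "G": ("O6",), "U": ("O2", "O4")}

#: geometric criterion: donor-acceptor < 3.5 A and H-donor-acceptor < 30 deg
HBOND_DISTANCE_MAX = 3.5
HBOND_ANGLE_MAX = 30.0


@dataclass(frozen=True)
class HBondSpec:
    """An imino hydrogen bond: donor residue (G: H1 on N1, U: H3 on N3)
    against a set of acceptor atoms on the partner residue."""

    donor: int                      # author number; base must be G or U
    acceptor: int                   # author number
    acceptor_atoms: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.donor}->{self.acceptor}:{','.join(self.acceptor_atoms)}"


def _imino_proton(conf: Conformation, donor_num: int, proxy: bool):
    res = conf.residue_by_author(donor_num)
    if res.base not in IMINO:
        raise ValueError(f"residue {res.base}{donor_num} has no imino proton")
    heavy, proton = IMINO[res.base]
    d_pos = res.atom(heavy).position
    if res.has_atom(proton):
        return d_pos, res.atom(proton).position
    if not proxy:
        raise GeometryError(
            f"residue {res.base}{donor_num}: imino proton {proton} absent; "
            "add protons or enable heavy-atom proxy mode"
        )
    # proxy: proton on the in-plane external bisector of the two ring
    # neighbours of the donor nitrogen, 1.01 A out
    nbrs = {"G": ("C2", "C6"), "U": ("C2", "C4")}[res.base]
    v = 2 * d_pos - res.atom(nbrs[0]).position - res.atom(nbrs[1]).position
    return d_pos, d_pos + 1.01 * v / np.linalg.norm(v)


def hbond_present(conf: Conformation, spec: HBondSpec,
                  proxy_protons: bool = False) -> bool:
    """True iff the imino hydrogen bond is formed toward at least one
    acceptor atom of the set."""
    d_pos, h_pos = _imino_proton(conf, spec.donor, proxy_protons)
    acc_res = conf.residue_by_author(spec.acceptor)
    atoms = spec.acceptor_atoms or ACCEPTOR_ATOMS[acc_res.base]
    for name in atoms:
        a_pos = acc_res.atom(name).position
        if np.linalg.norm(d_pos - a_pos) < HBOND_DISTANCE_MAX \
                and angle_deg(h_pos, d_pos, a_pos) < HBOND_ANGLE_MAX:
            return True
    return False


def hbond_stability(ensemble: Ensemble, weights, spec: HBondSpec,
                    proxy_protons: bool = False) -> float:
    """Weight-summed occurrence of the hydrogen bond, in [0, 1]."""
    w = check_simplex(weights, len(ensemble))
    return float(sum(
        wt for wt, conf in zip(w, ensemble.conformations)
        if hbond_present(conf, spec, proxy_protons)
    ))


def imino_table(ensemble: Ensemble, weights, pair_list,
                proxy_protons: bool = False) -> pd.DataFrame:
    """Hydrogen-bond stability table: one row per (donor, acceptor) pair
    in input order, with the acceptor atom set implied by the acceptor
    base (U partners offer the joint {O2, O4} set)."""
    seq = {r.author_number: r.base for r in ensemble.conformations[0].residues}
    rows = []
    for donor, acceptor in pair_list:
        spec = HBondSpec(donor=donor, acceptor=acceptor,
                         acceptor_atoms=ACCEPTOR_ATOMS[seq[acceptor]])
        rows.append({
            "donor": f"{seq[donor]}{donor}",
            "acceptor": f"{seq[acceptor]}{acceptor}",
            "acceptor_atoms": ", ".join(spec.acceptor_atoms),
            "stability": hbond_stability(ensemble, weights, spec, proxy_protons),
        })
    return pd.DataFrame(rows, columns=["donor", "acceptor", "acceptor_atoms",
                                       "stability"])


# ---------------------------------------------------------------------------
# Base-pair / stacking annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Geometric thresholds of the pairing/stacking classifier (one
    place to change them; defaults calibrated on ideal A-form geometry)."""

    max_center_distance: float = 10.0   #: ring-center screen, A
    pair_max_z: float = 2.0             #: coplanarity |z| bound, A (both frames)
    pair_max_inplane: float = 8.0       #: in-plane ring-center reach, A
    contact_max: float = 3.4            #: inter-base N/O contact bound, A
    stack_min_z: float = 2.0            #: stacking |z| window, A
    stack_max_z: float = 5.0
    stack_max_inplane: float = 4.5      #: ring-center overlap proxy, A
    wc_sector: tuple[float, float] = (-60.0, 60.0)        #: degrees
    hoogsteen_sector: tuple[float, float] = (60.0, 180.0)  #: sugar = remainder


@dataclass(frozen=True)
class PairAnnotation:
    i: int          # author number, i < j
    j: int
    kind: str       # 'pair' | 'stack'
    code: str       # e.g. 'WWc', 'HSt' | 'upward', 'downward', 'outward', 'inward'

    def involves(self, a: int, b: int) -> bool:
        return {self.i, self.j} == {a, b}


_EDGE_ATOMS = {  # polar edge atoms considered for hydrogen-bond-like contacts
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}


def _edge_code(azimuth_deg: float, cfg: AnnotationConfig) -> str:
    lo, hi = cfg.wc_sector
    if lo <= azimuth_deg < hi:
        return "W"
    lo, hi = cfg.hoogsteen_sector
    if lo <= azimuth_deg < hi:
        return "H"
    return "S"


def annotate(conf: Conformation,
             cfg: AnnotationConfig | None = None) -> list[PairAnnotation]:
    """Classify all interacting residue pairs of one conformation.

    Pairing requires near-coplanarity in both base frames, an in-plane
    partner position, and at least one inter-base polar contact; the
    category combines the edge sector seen from each base (W/H/S) with
    the cis/trans orientation of the base normals.  Stacking requires a
    vertical ring-center separation within a window in both frames plus
    in-plane overlap; its direction comes from the signs of the partner
    z coordinates: (+,-) upward, (-,+) downward, (-,-) outward, (+,+)
    inward.
    """
    cfg = cfg or AnnotationConfig()
    frames = []
    for res in conf.residues:
        try:
            frames.append(conf.base_frame(res))
        except GeometryError:
            frames.append(None)
    out: list[PairAnnotation] = []
    n = len(conf.residues)
    for a in range(n):
        for b in range(a + 1, n):
            fi, fj = frames[a], frames[b]
            if fi is None or fj is None:
                continue
            if np.linalg.norm(fi.origin - fj.origin) > cfg.max_center_distance:
                continue
            rij = fi.to_frame(fj.origin)   # partner center in i's frame
            rji = fj.to_frame(fi.origin)
            zi, zj = rij[2], rji[2]
            rho_i = float(np.hypot(rij[0], rij[1]))
            rho_j = float(np.hypot(rji[0], rji[1]))
            ri, rj = conf.residues[a], conf.residues[b]
            if abs(zi) <= cfg.pair_max_z and abs(zj) <= cfg.pair_max_z \
                    and rho_i <= cfg.pair_max_inplane \
                    and rho_j <= cfg.pair_max_inplane \
                    and _polar_contact(ri, rj, cfg.contact_max):
                edge_i = _edge_code(np.degrees(np.arctan2(rij[1], rij[0])), cfg)
                edge_j = _edge_code(np.degrees(np.arctan2(rji[1], rji[0])), cfg)
                orient = "c" if fi.axes[:, 2] @ fj.axes[:, 2] < 0 else "t"
                out.append(PairAnnotation(
                    i=ri.author_number, j=rj.author_number,
                    kind="pair", code=edge_i + edge_j + orient))
            elif cfg.stack_min_z < abs(zi) < cfg.stack_max_z \
                    and cfg.stack_min_z < abs(zj) < cfg.stack_max_z \
                    and min(rho_i, rho_j) < cfg.stack_max_inplane:
                signs = (zi > 0, zj > 0)
                code = {(True, False): "upward", (False, True): "downward",
                        (False, False): "outward", (True, True): "inward"}[signs]
                out.append(PairAnnotation(
                    i=ri.author_number, j=rj.author_number, kind="stack", code=code))
    return out


def _polar_contact(ri, rj, cutoff: float) -> bool:
    pi = ri.coords([a for a in _EDGE_ATOMS[ri.base] if ri.has_atom(a)])
    pj = rj.coords([a for a in _EDGE_ATOMS[rj.base] if rj.has_atom(a)])
    d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=-1)
    return bool(d.min() < cutoff)


def annotation_stability(ensemble: Ensemble, weights, kind: str, code: str,
                         pair: tuple[int, int],
                         cfg: AnnotationConfig | None = None) -> float:
    """Weight-summed presence of an annotation for one residue pair.

    For stacks the direction is interpreted for the (i, j) order given:
    asking for (j, i) flips upward <-> downward.
    """
    w = check_simplex(weights, len(ensemble))
    a, b = pair
    want = code
    if kind == "stack" and a > b:
        want = {"upward": "downward", "downward": "upward"}.get(code, code)
        a, b = b, a
    total = 0.0
    for wt, conf in zip(w, ensemble.conformations):
        for ann in annotate(conf, cfg):
            if ann.kind == kind and ann.involves(a, b) and _code_matches(ann, want):
                total += wt
                break
    return total


def _code_matches(ann: PairAnnotation, code: str) -> bool:
    if ann.kind == "stack":
        return ann.code == code
    if len(code) == 2:  # edge-only query, orientation-insensitive
        return {ann.code[0], ann.code[1]} == {code[0], code[1]}
    return ann.code == code or (ann.code[1] + ann.code[0] + ann.code[2]) == code


def annotation_table(ensemble: Ensemble, weights,
                     cfg: AnnotationConfig | None = None) -> pd.DataFrame:
    """All annotations seen anywhere in the ensemble with their stabilities."""
    w = check_simplex(weights, len(ensemble))
    acc: dict[tuple, float] = {}
    for wt, conf in zip(w, ensemble.conformations):
        for ann in annotate(conf, cfg):
            key = (ann.i, ann.j, ann.kind, ann.code)
            acc[key] = acc.get(key, 0.0) + wt
    rows = [{"i": i, "j": j, "kind": k, "code": c, "stability": s}
            for (i, j, k, c), s in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["i", "j", "kind", "code", "stability"])


# ---------------------------------------------------------------------------
# Helical parameters
# ---------------------------------------------------------------------------

@dataclass
class HelicalStep:
    step: tuple[int, int]   # author numbers of the first pair's strand-1 side
    rise: float             # A
    twist: float            # degrees


@dataclass
class HelicalSummary:
    steps: list[HelicalStep] = field(default_factory=list)

    @property
    def mean_rise(self) -> float:
        return float(np.mean([s.rise for s in self.steps]))

    @property
    def mean_twist(self) -> float:
        return float(np.mean([s.twist for s in self.steps]))


def _pair_frame(conf: Conformation, pair):
    """Mean base-pair frame: average of the two standard base frames
    after flipping the second about its x axis."""
    (a, b) = pair
    o1, r1 = conf.standard_frame(a)
    o2, r2 = conf.standard_frame(b)
    flip = np.diag([1.0, -1.0, -1.0])
    mean_rot = Rotation.from_matrix([r1, r2 @ flip]).mean().as_matrix()
    return (o1 + o2) / 2.0, mean_rot


def helical_parameters(conf: Conformation, pair_list) -> HelicalSummary:
    """Rise and twist per step of an ordered stem pair list.

    Per step: rise = projection of the inter-pair origin displacement on
    the mean pair normal; twist = rotation about that normal between the
    consecutive pair frames.
    """
    pair_list = list(pair_list)
    if len(pair_list) < 2:
        raise ValueError("need at least two pairs for a helical step")
    frames = [_pair_frame(conf, p) for p in pair_list]
    summary = HelicalSummary()
    for k in range(len(frames) - 1):
        (o1, r1), (o2, r2) = frames[k], frames[k + 1]
        normal = r1[:, 2] + r2[:, 2]
        normal /= np.linalg.norm(normal)
        rise = float((o2 - o1) @ normal)
        x1 = r1[:, 0] - (r1[:, 0] @ normal) * normal
        x2 = r2[:, 0] - (r2[:, 0] @ normal) * normal
        x1 /= np.linalg.norm(x1)
        x2 /= np.linalg.norm(x2)
        twist = float(np.degrees(np.arctan2(np.cross(x1, x2) @ normal, x1 @ x2)))
        summary.steps.append(HelicalStep(
            step=(pair_list[k][0], pair_list[k + 1][0]), rise=rise, twist=twist))
    return summary


def ensemble_helical_parameters(ensemble: Ensemble, pair_list,
                                weights=None) -> tuple[float, float]:
    """Weighted ensemble averages of mean rise (A) and mean twist (deg)."""
    w = check_simplex(weights, len(ensemble)) if weights is not None \
        else ensemble.effective_weights()
    rises, twists = [], []
    for conf in ensemble.conformations:
        s = helical_parameters(conf, pair_list)
        rises.append(s.mean_rise)
        twists.append(s.mean_twist)
    return float(np.array(rises) @ w), float(np.array(twists) @ w)
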