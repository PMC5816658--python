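"""Synthetic-data generators: ideal A-form hairpins, perturbed
ensembles with planted conformational states, NOE experiments with a
known feasibility structure, and reactivity profiles with stated error
rates.

These generators stand in for the inputs the pipeline normally takes
from experiment (an NMR bundle or MD trajectory, a NOE table, a
footprinting gel) while keeping the ground truth known, so that every
downstream stage can be tested quantitatively.  The geometry is
idealized (see :func:`build_a_form`), not force-field sampled.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .footprint import PROBEABLE, ReactivityProfile, SecondaryStructure
from .restraints import (NOE_CLASSES, NOEMatrix, NOERestraint,
                         back_calculate_noe, proton_selector)
from .structure import Atom, Conformation, Ensemble, Residue

#: PDB-conventional atom order within a residue
_BACKBONE_ORDER = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                   "C3'", "O3'", "C2'", "O2'", "C1'")

#: in-plane shear applied to the flipped partner of a wobble/mismatch so
#: that the hydrogen-bonding atoms come within contact distance
_PAIR_SHEAR = {
    ("G", "U"): np.array([2.577, 0.491, 0.0]),    # N1(G)-O2(U), O6(G)-N3(U)
    ("U", "G"): np.array([-2.577, 0.491, 0.0]),
    ("U", "U"): np.array([2.382, 1.851, 0.0]),    # N3-H3...O2 / O4...H3-N3
}

_FLIP = np.diag([1.0, -1.0, -1.0])


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _residue_atoms(base: str) -> list[tuple[str, np.ndarray]]:
    """(name, standard-frame position) in PDB-conventional order."""
    bb = geometry.backbone_template(base)
    tmpl = geometry.BASE_TEMPLATES[base]
    bb["C1'"] = tmpl["C1'"]
    out = [(n, bb[n]) for n in _BACKBONE_ORDER]
    out += [(n, p) for n, p in tmpl.items() if n != "C1'" and not n.startswith("H")]
    out += [(n, p) for n, p in tmpl.items() if n.startswith("H")]
    out += [(n, bb[n]) for n in ("H1'", "H2'", "H3'", "H4'", "H5'", "H5''")]
    return out


def _place_residue(number: int, base: str, rot: np.ndarray, trans: np.ndarray,
                   chain_id: str = "A") -> Residue:
    atoms = [Atom(name=n, element=geometry.element_of(n), position=rot @ p + trans)
             for n, p in _residue_atoms(base)]
    return Residue(author_number=number, base=base, chain_id=chain_id, atoms=atoms)


def build_a_form(structure: SecondaryStructure, rise: float = 2.8,
                 twist: float = 32.8) -> Conformation:
    """Idealized hairpin/duplex coordinates for a nested secondary
    structure: one A-form helix (optionally with 5'/3' overhangs and a
    terminal loop), all atoms needed downstream present.

    Paired bases are placed pair-frame-first on a straight helix axis
    (rotation ``twist`` and translation ``rise`` per base-pair step), so
    the stated rise/twist are recovered exactly by construction; real
    A-form x-displacement and base inclination are not modelled.  Loop
    residues follow a circular arc over the helix end -- a continuity
    heuristic, not a physical loop conformation.  Wobble and U:U pairs
    are sheared in-plane onto their characteristic hydrogen bonds.
    """
    if not structure.is_nested():
        raise ValueError("pseudoknotted structure not supported")
    pairs = structure.pairs
    numbers = list(structure.numbers)
    placements: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if pairs:
        i0, j0 = pairs[0]
        for k, (i, j) in enumerate(pairs):
            rot = _rz(k * twist)
            trans = np.array([0.0, 0.0, k * rise])
            placements[i] = (rot, trans)
            shear = _PAIR_SHEAR.get(
                (structure.base(i), structure.base(j)), np.zeros(3))
            placements[j] = (rot @ _FLIP, trans + rot @ shear)
        # overhangs continue the two strands beyond the outermost pair
        for step, n in enumerate(sorted((m for m in numbers if m < i0),
                                        reverse=True), start=1):
            placements[n] = (_rz(-step * twist), np.array([0.0, 0.0, -step * rise]))
        for step, n in enumerate(sorted(m for m in numbers if m > j0), start=1):
            placements[n] = (_rz(-step * twist) @ _FLIP,
                             np.array([0.0, 0.0, -step * rise]))
        i_in, j_in = pairs[-1]
        loop = [n for n in numbers if i_in < n < j_in]
        unplaced = [n for n in numbers
                    if n not in placements and n not in loop]
        if unplaced:
            raise NotImplementedError(
                f"bulge/internal-loop positions {unplaced} not supported by "
                "the single-helix builder")
        ktop = len(pairs) - 1
        m = len(loop)
        arch = 2.0 + 0.6 * m
        for s, n in enumerate(loop, start=1):
            frac = s / (m + 1)
            rot = _rz((ktop + s) * twist) @ _rx(np.pi * frac)
            trans = np.array([0.0, 0.0, ktop * rise + arch * np.sin(np.pi * frac)])
            placements[n] = (rot, trans)
    else:
        for k, n in enumerate(numbers):  # extended single strand
            placements[n] = (_rz(k * twist), np.array([0.0, 0.0, k * rise]))
    residues = [
        _place_residue(n, structure.base(n), *placements[n]) for n in numbers
    ]
    return Conformation(residues=residues, model_id=1)


# ---------------------------------------------------------------------------
# Planted-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """One planted conformational state: a rigid displacement (and
    optional in-place rotation about each base normal) of a residue set,
    default the loop."""

    name: str
    fraction: float
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # A, global frame
    base_spin: float = 0.0                               # deg about base normal
    residues: tuple[int, ...] | None = None              # None = loop residues


@dataclass
class EnsembleSpec:
    structure: SecondaryStructure
    n_snapshots: int = 100
    noise: float = 0.3              #: atomwise Gaussian noise sigma, A
    states: list[StateSpec] = field(default_factory=lambda: [StateSpec("native", 1.0)])
    rise: float = 2.8
    twist: float = 32.8

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        total = sum(s.fraction for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")


@dataclass
class GroundTruth:
    labels: np.ndarray              #: per-snapshot state index
    state_names: list[str]
    state_templates: list[Conformation]
    fractions: np.ndarray

    def state_mask(self, state: int) -> np.ndarray:
        return self.labels == state


def _loop_residues(structure: SecondaryStructure) -> tuple[int, ...]:
    if not structure.pairs:
        return tuple(structure.numbers)
    i_in, j_in = structure.pairs[-1]
    return tuple(n for n in structure.numbers if i_in < n < j_in)


def _apply_state(conf: Conformation, state: StateSpec,
                 structure: SecondaryStructure) -> Conformation:
    conf = copy.deepcopy(conf)
    targets = state.residues if state.residues is not None \
        else _loop_residues(structure)
    shift = np.asarray(state.shift, float)
    for res in conf.residues:
        if res.author_number not in targets:
            continue
        if state.base_spin:
            frame = conf.base_frame(res)
            rot = geometry.Rotation.from_rotvec(
                np.radians(state.base_spin) * frame.axes[:, 2]).as_matrix()
            for a in res.atoms:
                a.position = frame.origin + rot @ (a.position - frame.origin)
        for a in res.atoms:
            a.position = a.position + shift
    return conf


def largest_remainder_counts(fractions, total: int) -> np.ndarray:
    """Integer state counts matching target fractions exactly in sum."""
    fractions = np.asarray(fractions, float)
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for idx in np.argsort(-rem)[: total - counts.sum()]:
        counts[idx] += 1
    return counts


def generate_ensemble(spec: EnsembleSpec, seed: int = 0) -> tuple[Ensemble, GroundTruth]:
    """Planted-state ensemble: state counts by largest-remainder
    rounding, label order shuffled and atomwise Gaussian noise added,
    all reproducibly from the seed."""
    rng = np.random.default_rng(seed)
    templates = []
    base_conf = build_a_form(spec.structure, rise=spec.rise, twist=spec.twist)
    for st in spec.states:
        templates.append(_apply_state(base_conf, st, spec.structure))
    counts = largest_remainder_counts([s.fraction for s in spec.states],
                                      spec.n_snapshots)
    labels = np.repeat(np.arange(len(spec.states)), counts)
    labels = rng.permutation(labels)
    confs = []
    for t, lab in enumerate(labels):
        conf = copy.deepcopy(templates[lab])
        conf.model_id = t + 1
        if spec.noise > 0:
            for res in conf.residues:
                for a in res.atoms:
                    a.position = a.position + rng.normal(0.0, spec.noise, 3)
        confs.append(conf)
    truth = GroundTruth(
        labels=labels,
        state_names=[s.name for s in spec.states],
        state_templates=templates,
        fractions=np.asarray([s.fraction for s in spec.states]),
    )
    return Ensemble(conformations=confs), truth


# ---------------------------------------------------------------------------
# Planted NOE experiments
# ---------------------------------------------------------------------------

@dataclass
class NOEDesign:
    n_violated: int = 7         #: restraints the uniform ensemble must violate
    n_satisfied: int = 13       #: restraints satisfied from the start
    margin: float = 0.15        #: relative NOE margin around the class bound
    discriminating_state: int = 0   #: state whose geometry satisfies the bounds


@dataclass
class PlantedNOEExperiment:
    restraints: list[NOERestraint]
    noe: NOEMatrix
    noe_exp: np.ndarray
    violated_ids: list[str]
    w_star: float               #: minimum feasible weight of the design state

    @property
    def n_restraints(self) -> int:
        return len(self.restraints)


_NOE_PROTONS = {"A": ("H1'", "H2", "H8"), "G": ("H1'", "H8", "H1"),
                "C": ("H1'", "H5", "H6"), "U": ("H1'", "H5", "H6", "H3")}


def plant_noe_experiment(ensemble: Ensemble, truth: GroundTruth,
                         design: NOEDesign | None = None,
                         candidate_residues=None) -> PlantedNOEExperiment:
    """Build an NOE restraint set with a known feasibility structure.

    Scans proton pairs around the region that differs between the
    planted states and assigns intensity classes so that exactly
    ``n_violated`` restraints are violated by the uniform-weight
    ensemble average yet satisfiable by upweighting the discriminating
    state, plus ``n_satisfied`` restraints that start out satisfied.
    Returns the restraints, the back-calculated matrix, the bounds, and
    the feasibility boundary w* (the minimum total weight of the
    discriminating state compatible with all bounds, from state-mean
    NOE values).
    """
    design = design or NOEDesign()
    conf0 = ensemble.conformations[0]
    if candidate_residues is None:
        candidate_residues = [r.author_number for r in conf0.residues]
    cands = []
    seq = {r.author_number: r.base for r in conf0.residues}
    for a in candidate_residues:
        for b in candidate_residues:
            if b <= a:
                continue
            for pa in _NOE_PROTONS[seq[a]]:
                for pb in _NOE_PROTONS[seq[b]]:
                    cands.append(NOERestraint(
                        proton_a=proton_selector(a, pa),
                        proton_b=proton_selector(b, pb),
                        noe_class=NOE_CLASSES["weak"]))
    matrix = back_calculate_noe(ensemble, cands)
    mask_a = truth.state_mask(design.discriminating_state)
    if not mask_a.any() or mask_a.all():
        raise ValueError("non-discriminating design: need two populated states")
    mean_all = matrix.values.mean(axis=0)
    mean_a = matrix.values[mask_a].mean(axis=0)
    mean_b = matrix.values[~mask_a].mean(axis=0)
    max_t = matrix.values.max(axis=0)
    chosen: list[tuple[int, str]] = []
    used: set[int] = set()
    m = design.margin
    for label in ("weak", "medium", "strong"):
        exp_c = NOE_CLASSES[label].noe_exp
        for k in range(len(cands)):
            if len(chosen) >= design.n_violated:
                break
            if k in used:
                continue
            if (mean_all[k] <= exp_c * (1 - m)
                    and mean_a[k] >= exp_c * (1 + m)
                    and max_t[k] >= exp_c * (1 + m / 2)):
                chosen.append((k, label))
                used.add(k)
        if len(chosen) >= design.n_violated:
            break
    if len(chosen) < design.n_violated:
        raise ValueError(
            f"non-discriminating design: only {len(chosen)} of "
            f"{design.n_violated} violated restraints could be planted")
    sat: list[tuple[int, str]] = []
    for label in ("weak", "medium", "strong"):
        exp_c = NOE_CLASSES[label].noe_exp
        for k in range(len(cands)):
            if len(sat) >= design.n_satisfied:
                break
            if k in used:
                continue
            if min(mean_all[k], mean_a[k], mean_b[k]) >= exp_c * (1 + m):
                sat.append((k, label))
                used.add(k)
        if len(sat) >= design.n_satisfied:
            break
    if len(sat) < design.n_satisfied:
        raise ValueError("could not plant enough satisfied restraints")
    picks = chosen + sat
    restraints = [
        NOERestraint(proton_a=cands[k].proton_a, proton_b=cands[k].proton_b,
                     noe_class=NOE_CLASSES[label])
        for k, label in picks
    ]
    values = matrix.values[:, [k for k, _ in picks]]
    noe = NOEMatrix(values=values,
                    restraint_ids=[r.rid for r in restraints],
                    snapshot_ids=matrix.snapshot_ids)
    noe_exp = np.array([r.noe_class.noe_exp for r in restraints])
    w_star = 0.0
    for col, (k, label) in enumerate(chosen):
        exp_c = noe_exp[col]
        denom = mean_a[k] - mean_b[k]
        if denom > 0:
            w_star = max(w_star, (exp_c - mean_b[k]) / denom)
    return PlantedNOEExperiment(
        restraints=restraints, noe=noe, noe_exp=noe_exp,
        violated_ids=[noe.restraint_ids[c] for c in range(design.n_violated)],
        w_star=float(w_star),
    )


# ---------------------------------------------------------------------------
# Reactivity simulation
# ---------------------------------------------------------------------------

def simulate_reactivity(structure: SecondaryStructure,
                        false_positive: float, false_negative: float,
                        seed: int = 0, primer_region=()) -> ReactivityProfile:
    """Reactivity calls from a known secondary structure.

    Unpaired probeable positions come out reactive with probability
    1 - false_negative; paired positions with probability
    false_positive; every other probeable position reads protected.
    """
    if not (0 <= false_positive < 1 and 0 <= false_negative < 1):
        raise ValueError("error rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    paired = structure.paired_positions()
    calls: dict[str, dict[int, str]] = {"DMS": {}, "CMCT": {}}
    for reagent, bases in PROBEABLE.items():
        for k, n in enumerate(structure.numbers):
            if structure.sequence[k] not in bases:
                continue
            if n in paired:
                reactive = rng.random() < false_positive
            else:
                reactive = rng.random() >= false_negative
            calls[reagent][n] = "reactive" if reactive else "protected"
    profile = ReactivityProfile(sequence=structure.sequence,
                                numbers=structure.numbers, calls=calls)
    if primer_region:
        profile.force_unprobed(primer_region)
    return profile
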