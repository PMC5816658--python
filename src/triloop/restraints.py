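"""NOE and torsion restraints: data model, rule-based builders,
r^-6 back-calculation and violation statistics.

NOE cross-peak intensities translate into class-bounded distance
restraints (strong/medium/weak); because the NOE is proportional to
r^-6, an ensemble satisfies restraint i when the weighted average
<NOE_i> = sum_t W(t)/r_i(t)^6 is at least 1/r_hi^6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import torsion_angle, GLYCOSIDIC
from .structure import Conformation, Ensemble, check_simplex


# ---------------------------------------------------------------------------
# NOE classes and restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NOEClass:
    label: str
    r_lo: float
    r_hi: float

    def __post_init__(self):
        if not self.r_lo < self.r_hi:
            raise ValueError("r_lo must be < r_hi")

    @property
    def noe_exp(self) -> float:
        """Lower bound on the NOE value, 1/r_hi^6 (A^-6)."""
        return self.r_hi ** -6


#: the three intensity classes used to bound proton-proton distances
STRONG = NOEClass("strong", 1.8, 3.6)
MEDIUM = NOEClass("medium", 2.6, 5.0)
WEAK = NOEClass("weak", 3.5, 6.5)
NOE_CLASSES = {c.label: c for c in (STRONG, MEDIUM, WEAK)}


@dataclass(frozen=True)
class NOERestraint:
    """A proton-pair (or equivalent-proton-group pair) distance restraint."""

    proton_a: tuple[int, tuple[str, ...]]  # (author number, proton names)
    proton_b: tuple[int, tuple[str, ...]]
    noe_class: NOEClass
    exchangeable: bool = False

    def __post_init__(self):
        if self.proton_a == self.proton_b:
            raise ValueError("restraint between a proton group and itself")

    @property
    def rid(self) -> str:
        def fmt(sel):
            num, names = sel
            return f"{num}:{'/'.join(names)}"
        return f"{fmt(self.proton_a)}--{fmt(self.proton_b)}"


def proton_selector(author_number: int, names) -> tuple[int, tuple[str, ...]]:
    if isinstance(names, str):
        names = (names,)
    return (author_number, tuple(names))


def _resolve(conf: Conformation, selector) -> np.ndarray:
    num, names = selector
    res = conf.residue_by_author(num)
    expanded = []
    for n in names:
        if n.endswith("*"):
            expanded += [a.name for a in res.atoms
                         if a.name.startswith(n[:-1]) and a.name.startswith("H")]
        elif res.has_atom(n):
            expanded.append(n)
    if not expanded:
        raise KeyError(
            f"proton selector {names} resolves to no atom in residue "
            f"{res.base}{num}"
        )
    return res.coords(expanded)


def back_calculate_noe(ensemble: Ensemble, noe_restraints) -> "NOEMatrix":
    """Back-calculate NOE_i(t) = sum over equivalent-proton pairs of
    r^-6 (A^-6) for every snapshot t and restraint i.

    The group-summation convention sums r^-6 over all proton-pair
    combinations of the two groups (see ``group_convention`` of
    :func:`noe_value` for the center-averaging alternative).
    """
    noe_restraints = list(noe_restraints)
    values = np.empty((len(ensemble), len(noe_restraints)))
    for t, conf in enumerate(ensemble.conformations):
        for i, rst in enumerate(noe_restraints):
            values[t, i] = noe_value(conf, rst)
    return NOEMatrix(
        values=values,
        restraint_ids=[r.rid for r in noe_restraints],
        snapshot_ids=[c.model_id for c in ensemble.conformations],
    )


def noe_value(conf: Conformation, rst: NOERestraint,
              group_convention: str = "sum") -> float:
    """NOE value of one restraint in one conformation, A^-6."""
    pa = _resolve(conf, rst.proton_a)
    pb = _resolve(conf, rst.proton_b)
    if group_convention == "sum":
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        return float(np.sum(d ** -6.0))
    if group_convention == "center":
        d = np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0))
        return float(d ** -6.0)
    raise ValueError(f"unknown group convention {group_convention!r}")


@dataclass
class NOEMatrix:
    """Snapshots x restraints table of back-calculated NOE values (A^-6)."""

    values: np.ndarray
    restraint_ids: list[str]
    snapshot_ids: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("NOE matrix must be rectangular")
        if np.any(self.values <= 0):
            raise ValueError("NOE matrix entries must be strictly positive")

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[0]

    @property
    def n_restraints(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snapshot\t" + "\t".join(self.restraint_ids) + "\n")
            for sid, row in zip(self.snapshot_ids, self.values):
                fh.write(str(sid) + "\t" + "\t".join(f"{v:.10e}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "NOEMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            sids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                sids.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        return cls(values=np.array(rows), restraint_ids=header, snapshot_ids=sids)


def effective_distance(noe_values, weights) -> float:
    """r^-6-weighted effective distance (A): (sum_t W(t) NOE(t))^(-1/6)."""
    w = check_simplex(weights)
    avg = float(np.asarray(noe_values, float) @ w)
    return avg ** (-1.0 / 6.0)


# ---------------------------------------------------------------------------
# Torsion restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionRestraint:
    angle: str  # alpha, beta, gamma, delta, epsilon, zeta, chi
    author_number: int
    center: float
    halfwidth: float

    def __post_init__(self):
        if self.angle not in TORSION_ATOMS:
            raise ValueError(f"unknown torsion angle {self.angle!r}")
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")

    @property
    def rid(self) -> str:
        return f"{self.angle}{self.author_number}"


#: atom names and residue offsets (0 = own residue) defining each torsion
TORSION_ATOMS = {
    "alpha": (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)),
    "beta": (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    "gamma": (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    "delta": (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    "epsilon": (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),
    "zeta": (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),
    "chi": None,  # base-type dependent, see measure_torsion
}

#: restraint windows (center, halfwidth) encoding the refinement rules
TORSION_WINDOWS = {
    "alpha": (0.0, 120.0), "zeta": (0.0, 120.0),
    "beta": (180.0, 40.0), "gamma": (60.0, 40.0), "epsilon": (235.0, 65.0),
    "delta": (85.0, 30.0), "chi": (-120.0, 90.0),
}

#: which backbone angles are applied to helical residues only
HELICAL_BACKBONE = ("alpha", "beta", "gamma", "epsilon", "zeta")


def measure_torsion(conf: Conformation, rst: TorsionRestraint) -> float:
    """Measure a named backbone/glycosidic torsion (degrees) in a model."""
    idx = {r.author_number: k for k, r in enumerate(conf.residues)}
    k = idx[rst.author_number]
    if rst.angle == "chi":
        res = conf.residues[k]
        glyc_n, ref = GLYCOSIDIC[res.base]
        pts = [res.atom("O4'").position, res.atom("C1'").position,
               res.atom(glyc_n).position, res.atom(ref).position]
    else:
        pts = []
        for name, off in TORSION_ATOMS[rst.angle]:
            kk = k + off
            if kk < 0 or kk >= len(conf.residues):
                raise KeyError(f"{rst.rid}: neighbour residue out of chain")
            pts.append(conf.residues[kk].atom(name).position)
    return torsion_angle(*pts)


def circular_violation(measured: float, center: float, halfwidth: float) -> float:
    """Degrees outside the circular window [center-hw, center+hw]."""
    d = (measured - center + 180.0) % 360.0 - 180.0
    return max(0.0, abs(d) - halfwidth)


def build_torsion_restraints(sequence: dict[int, str], helical_residues,
                             loop_excluded) -> list[TorsionRestraint]:
    """Encode the torsion-restraint construction rules.

    ``sequence``: author number -> base letter (keys in chain order).
    delta applies to every nucleotide; chi to every nucleotide except
    ``loop_excluded``; the five backbone angles to ``helical_residues``
    only, with angles undefined at the chain termini (missing neighbour
    phosphate) dropped.
    """
    numbers = sorted(sequence)
    for num, base in sequence.items():
        if base not in "ACGU":
            raise ValueError(f"unknown base {base!r} at {num}")
    helical = set(helical_residues)
    loop = set(loop_excluded)
    if not loop <= set(numbers):
        raise ValueError("loop_excluded outside the sequence range")
    out = []
    five_prime, three_prime = numbers[0], numbers[-1]
    for num in numbers:
        c, hw = TORSION_WINDOWS["delta"]
        out.append(TorsionRestraint("delta", num, c, hw))
        if num not in loop:
            c, hw = TORSION_WINDOWS["chi"]
            out.append(TorsionRestraint("chi", num, c, hw))
        if num in helical:
            for ang in HELICAL_BACKBONE:
                if ang == "alpha" and num == five_prime:
                    continue  # needs O3' of the (absent) preceding residue
                if ang in ("epsilon", "zeta") and num == three_prime:
                    continue  # needs the (absent) following phosphate
                c, hw = TORSION_WINDOWS[ang]
                out.append(TorsionRestraint(ang, num, c, hw))
    return out


def torsion_count_breakdown(restraints) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in restraints:
        counts[r.angle] = counts.get(r.angle, 0) + 1
    counts["backbone"] = sum(counts.get(a, 0) for a in HELICAL_BACKBONE)
    counts["total"] = len(list(restraints))
    return counts


# ---------------------------------------------------------------------------
# Hydrogen-bond restraints for canonical pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondRestraint:
    donor: tuple[int, str]     # (author number, heavy atom)
    acceptor: tuple[int, str]
    window: tuple[float, float] = (2.7, 3.1)

    def __post_init__(self):
        if self.donor[0] == self.acceptor[0]:
            raise ValueError("donor and acceptor must be in distinct residues")


#: donor/acceptor heavy-atom pairs per canonical pair type, written for the
#: first-named base; G:U wobble uses N1(G)-O2(U) and O6(G)-N3(U)
_HBOND_RULES = {
    ("G", "C"): [("N1", "N3"), ("N2", "O2"), ("O6", "N4")],
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("G", "U"): [("N1", "O2"), ("O6", "N3")],
}


def build_wc_hbond_restraints(pairs, whitelist=()) -> list[HBondRestraint]:
    """Hydrogen-bond restraints for a base-pair list.

    ``pairs``: iterable of ((author_number_a, base_a), (author_number_b,
    base_b)).  3 restraints per G:C, 2 per A:U, 2 per G:U wobble;
    unrecognized pair types raise unless listed in ``whitelist`` (as
    frozenset of the two bases), in which case they contribute none.
    """
    out = []
    for (na, ba), (nb, bb) in pairs:
        key, swap = None, False
        if (ba, bb) in _HBOND_RULES:
            key = (ba, bb)
        elif (bb, ba) in _HBOND_RULES:
            key, swap = (bb, ba), True
        if key is None:
            if frozenset((ba, bb)) in {frozenset(w) for w in whitelist}:
                continue
            raise ValueError(f"unrecognized pair type {ba}{na}:{bb}{nb}")
        if swap:
            na, nb = nb, na
        for atom_a, atom_b in _HBOND_RULES[key]:
            out.append(HBondRestraint(donor=(na, atom_a), acceptor=(nb, atom_b)))
    return out


# ---------------------------------------------------------------------------
# Violation statistics
# ---------------------------------------------------------------------------

@dataclass
class ViolationReport:
    distance_violations: dict[str, float] = field(default_factory=dict)
    dihedral_violations: dict[str, float] = field(default_factory=dict)
    unsatisfied: list[str] = field(default_factory=list)

    @property
    def max_distance_violation(self) -> float:
        return max(self.distance_violations.values(), default=0.0)

    @property
    def max_dihedral_violation(self) -> float:
        return max(self.dihedral_violations.values(), default=0.0)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "max_distance_violation_A": self.max_distance_violation,
            "max_dihedral_violation_deg": self.max_dihedral_violation,
            "n_unsatisfied": len(self.unsatisfied),
            "unsatisfied": self.unsatisfied,
            "distance_violations": self.distance_violations,
            "dihedral_violations": self.dihedral_violations,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def violation_report(target, noe_restraints=(), torsion_restraints=(),
                     weights=None, tolerance: float = 0.0) -> ViolationReport:
    """Violation statistics of a conformation or an ensemble.

    Distance violation of restraint i is max(0, effective_distance - r_hi)
    (for a single conformation the plain r^-6-summed distance); dihedral
    violation is the circular distance from the restraint window, with
    per-model values maximized over the ensemble.
    """
    if isinstance(target, Conformation):
        ens = Ensemble(conformations=[target])
        w = np.array([1.0])
    else:
        ens = target
        w = check_simplex(weights, len(ens)) if weights is not None \
            else ens.effective_weights()
    report = ViolationReport()
    noe_restraints = list(noe_restraints)
    if noe_restraints:
        noe = back_calculate_noe(ens, noe_restraints)
        for i, rst in enumerate(noe_restraints):
            d_eff = effective_distance(noe.values[:, i], w)
            report.distance_violations[rst.rid] = max(0.0, d_eff - rst.noe_class.r_hi)
    for rst in torsion_restraints:
        worst = 0.0
        for conf in ens.conformations:
            worst = max(worst, circular_violation(
                measure_torsion(conf, rst), rst.center, rst.halfwidth))
        report.dihedral_violations[rst.rid] = worst
    report.unsatisfied = sorted(
        [k for k, v in report.distance_violations.items() if v > tolerance]
        + [k for k, v in report.dihedral_violations.items() if v > tolerance]
    )
    return report


# ---------------------------------------------------------------------------
# Flat-text restraint tables (tab-separated: res_a atom_a res_b atom_b class)
# ---------------------------------------------------------------------------

def write_noe_table(restraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("res_a\tatom_a\tres_b\tatom_b\tclass\n")
        for r in restraints:
            fh.write(f"{r.proton_a[0]}\t{','.join(r.proton_a[1])}\t"
                     f"{r.proton_b[0]}\t{','.join(r.proton_b[1])}\t"
                     f"{r.noe_class.label}\n")


def read_noe_table(path) -> list[NOERestraint]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("res_a"):
            raise ValueError(f"{path}: missing restraint-table header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            ra, aa, rb, ab, label = line.rstrip("\n").split("\t")
            out.append(NOERestraint(
                proton_a=proton_selector(int(ra), tuple(aa.split(","))),
                proton_b=proton_selector(int(rb), tuple(ab.split(","))),
                noe_class=NOE_CLASSES[label],
            ))
    return out
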