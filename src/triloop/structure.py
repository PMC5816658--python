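"""Coordinate data model and multi-model PDB I/O for RNA ensembles.

The containers mirror what an NMR bundle or an MD trajectory of a single
RNA chain needs: an :class:`Ensemble` of :class:`Conformation` objects
sharing one topology, each an ordered list of :class:`Residue` objects
carrying author numbering (the numbering used in the source experiments,
e.g. 64-92 for the 29-nt hairpin construct).

PDB reading/writing is delegated to biotite; the containers here add the
invariant checks and the selection/superposition conveniences the rest of
the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from . import geometry
from .geometry import GeometryError, RING6, GLYCOSIDIC, ring_template, superpose


class TopologyError(ValueError):
    """Inconsistent atom sets or residue topology across models."""


class PDBParseError(ValueError):
    """Malformed PDB content."""


BACKBONE_ATOMS = frozenset(
    ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]
)


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class Residue:
    author_number: int
    base: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        if self.base not in "ACGU":
            raise ValueError(f"unknown base {self.base!r}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.base}{self.author_number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names) -> np.ndarray:
        return np.array([self.atom(n).position for n in names])


@dataclass
class BaseFrame:
    """Orthonormal frame attached to a base: origin at the 6-ring centroid,
    x toward the Watson-Crick edge, z along the base normal."""

    origin: np.ndarray
    axes: np.ndarray  # columns are the x, y, z axes in global coordinates

    def to_frame(self, point: np.ndarray) -> np.ndarray:
        """Express a global point in this frame."""
        return (np.asarray(point, float) - self.origin) @ self.axes


@dataclass
class Conformation:
    residues: list[Residue]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def residue_by_author(self, number: int) -> Residue:
        for r in self.residues:
            if r.author_number == number:
                return r
        raise KeyError(f"no residue with author number {number}")

    def base_frame(self, residue: Residue | int) -> BaseFrame:
        """Least-squares fit of the residue's observed 6-ring onto the
        idealized planar template of its base type."""
        if isinstance(residue, int):
            residue = self.residue_by_author(residue)
        missing = [a for a in RING6 if not residue.has_atom(a)]
        if missing:
            raise GeometryError(
                f"residue {residue.base}{residue.author_number}: "
                f"missing ring atom(s) {missing}"
            )
        obs = residue.coords(RING6)
        tmpl = ring_template(residue.base)
        R, t, _ = superpose(tmpl, obs)
        return BaseFrame(origin=obs.mean(axis=0), axes=R)

    def standard_frame(self, residue: Residue | int) -> tuple[np.ndarray, np.ndarray]:
        """Standard base reference frame (origin, axes) from a fit of the
        observed ring onto the standard-frame template coordinates."""
        if isinstance(residue, int):
            residue = self.residue_by_author(residue)
        obs = residue.coords(RING6)
        tmpl = np.array([geometry.BASE_TEMPLATES[residue.base][a] for a in RING6])
        R, t, _ = superpose(tmpl, obs)
        return t, R


@dataclass
class Ensemble:
    conformations: list[Conformation]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.conformations:
            ref = self.conformations[0]
            for c in self.conformations[1:]:
                if c.sequence != ref.sequence or len(c) != len(ref):
                    raise TopologyError("conformations differ in sequence/length")
                for ra, rb in zip(ref.residues, c.residues):
                    if [a.name for a in ra.atoms] != [a.name for a in rb.atoms]:
                        raise TopologyError(
                            f"atom naming differs at residue {ra.author_number}"
                        )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            check_simplex(self.weights, len(self.conformations))

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def sequence(self) -> str:
        return self.conformations[0].sequence

    def uniform_weights(self) -> np.ndarray:
        return np.full(len(self), 1.0 / len(self))

    def effective_weights(self) -> np.ndarray:
        return self.weights if self.weights is not None else self.uniform_weights()


def check_simplex(w: np.ndarray, n: int | None = None, tol: float = 1e-9) -> np.ndarray:
    w = np.asarray(w, float)
    if n is not None and len(w) != n:
        raise ValueError(f"weight vector length {len(w)} != {n}")
    if np.any(w < -tol) or abs(w.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    return np.clip(w, 0.0, None)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_RNA_RES_NAMES = {"A": "A", "C": "C", "G": "G", "U": "U",
                  "RA": "A", "RC": "C", "RG": "G", "RU": "U",
                  "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U"}

_SOLVENT = {"HOH", "WAT", "NA", "CL", "MG", "K", "SO4"}


def read_pdb_models(path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    HETATM/solvent records are skipped; alternate locations are resolved
    to the highest-occupancy variant; author numbering is preserved.
    """
    try:
        pdb = bpdb.PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite reports the offending line
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    mask = ~stack.hetero & np.isin(
        np.char.upper(stack.res_name.astype("U5")), list(_RNA_RES_NAMES)
    )
    if not mask.any():
        raise PDBParseError(f"{path}: no RNA ATOM records")
    stack = stack[..., mask]
    confs = []
    for m in range(stack.stack_depth()):
        arr = stack[m]
        residues: list[Residue] = []
        current_key = None
        for i in range(arr.array_length()):
            key = (arr.chain_id[i], arr.res_id[i])
            if key != current_key:
                residues.append(Residue(
                    author_number=int(arr.res_id[i]),
                    base=_RNA_RES_NAMES[str(arr.res_name[i]).upper()],
                    chain_id=str(arr.chain_id[i]),
                ))
                current_key = key
            residues[-1].atoms.append(Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).capitalize(),
                position=arr.coord[i].copy(),
            ))
        confs.append(Conformation(residues=residues, model_id=m + 1))
    try:
        return Ensemble(conformations=confs)
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from exc


def write_pdb_models(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB file."""
    if len(ensemble) == 0:
        raise ValueError("cannot write an empty ensemble")
    n_atoms = sum(len(r.atoms) for r in ensemble.conformations[0].residues)
    for r in ensemble.conformations[0].residues:
        for a in r.atoms:
            if len(a.name) > 4:
                raise ValueError(f"atom name {a.name!r} exceeds 4 characters")
    coord = np.zeros((len(ensemble), n_atoms, 3))
    template = bst.AtomArray(n_atoms)
    i = 0
    for r in ensemble.conformations[0].residues:
        for a in r.atoms:
            template.chain_id[i] = r.chain_id
            template.res_id[i] = r.author_number
            template.res_name[i] = r.base
            template.atom_name[i] = a.name
            template.element[i] = a.element.upper()
            template.hetero[i] = False
            i += 1
    for m, conf in enumerate(ensemble.conformations):
        j = 0
        for r in conf.residues:
            for a in r.atoms:
                coord[m, j] = a.position
                j += 1
    stack = bst.AtomArrayStack(len(ensemble), n_atoms)
    for annot in template.get_annotation_categories():
        stack.set_annotation(annot, template.get_annotation(annot))
    stack.coord = coord
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections and ensemble RMSD
# ---------------------------------------------------------------------------

def select_atoms(conf: Conformation, residues=None, atom_class: str = "heavy"):
    """Yield (residue, atom) pairs for an author-number range / atom class.

    ``residues``: iterable of author numbers (None = all).
    ``atom_class``: 'heavy' | 'backbone' | 'base' | 'all'.
    """
    residues = None if residues is None else set(residues)
    for r in conf.residues:
        if residues is not None and r.author_number not in residues:
            continue
        for a in r.atoms:
            is_h = a.element == "H" or a.name.startswith("H")
            if atom_class == "heavy" and is_h:
                continue
            if atom_class == "backbone" and (is_h or a.name not in BACKBONE_ATOMS):
                continue
            if atom_class == "base" and (is_h or a.name in BACKBONE_ATOMS):
                continue
            yield r, a


def _selection_coords(conf: Conformation, residues, atom_class) -> np.ndarray:
    pts = [a.position for _, a in select_atoms(conf, residues, atom_class)]
    if not pts:
        raise ValueError("empty atom selection")
    return np.array(pts)


def rmsd_after_superposition(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal-superposition RMSD between two matched coordinate sets."""
    _, _, rmsd = superpose(coords_b, coords_a)
    return rmsd


def pairwise_rmsd(ensemble: Ensemble, residues=None, atom_class: str = "heavy") -> float:
    """Mean RMSD over all unordered model pairs, superposing each pair on
    the selected atoms themselves (per-region convention)."""
    if len(ensemble) < 2:
        raise ValueError("need at least two conformations")
    sel = [_selection_coords(c, residues, atom_class) for c in ensemble.conformations]
    vals = []
    for i in range(len(sel)):
        for j in range(i + 1, len(sel)):
            vals.append(rmsd_after_superposition(sel[i], sel[j]))
    return float(np.mean(vals))


def pairwise_rmsd_global_superposition(
    ensemble: Ensemble, residues=None, atom_class: str = "heavy",
    superpose_residues=None, superpose_class: str = "heavy",
) -> float:
    """Alternative convention: superpose each model pair on one selection
    (default: all heavy atoms) and measure RMSD on another."""
    if len(ensemble) < 2:
        raise ValueError("need at least two conformations")
    fit = [_selection_coords(c, superpose_residues, superpose_class)
           for c in ensemble.conformations]
    meas = [_selection_coords(c, residues, atom_class) for c in ensemble.conformations]
    vals = []
    for i in range(len(fit)):
        for j in range(i + 1, len(fit)):
            R, t, _ = superpose(fit[j], fit[i])
            moved = meas[j] @ R.T + t
            vals.append(float(np.sqrt(np.mean(np.sum((meas[i] - moved) ** 2, axis=1)))))
    return float(np.mean(vals))
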