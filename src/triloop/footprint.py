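"""Chemical-probing (DMS/CMCT) data model and secondary-structure logic.

DMS methylates N1 of adenines and N3 of cytosines; CMCT methylates N3
of uridines and (weakly) N1 of guanines.  Methylation requires solvent
access, so reactive positions are read as unpaired and protected
positions as (usually) paired.  Reactivity is modelled categorically
(reactive / weak / protected / unprobed) as read off footprinting gels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


#: bases each reagent can probe
PROBEABLE = {"DMS": frozenset("AC"), "CMCT": frozenset("UG")}

CALLS = ("unprobed", "protected", "weak", "reactive")
_CALL_LEVEL = {c: k for k, c in enumerate(CALLS)}


@dataclass
class SecondaryStructure:
    """Author-numbered sequence plus a nested base-pair list."""

    sequence: str
    numbers: tuple[int, ...]
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.numbers = tuple(self.numbers)
        if len(self.sequence) != len(self.numbers):
            raise ValueError("sequence and numbering lengths differ")
        seen: set[int] = set()
        norm = []
        for i, j in self.pairs:
            if i > j:
                i, j = j, i
            for n in (i, j):
                if n not in self.numbers:
                    raise ValueError(f"paired position {n} outside sequence")
                if n in seen:
                    raise ValueError(f"position {n} in more than one pair")
                seen.add(n)
            norm.append((i, j))
        self.pairs = sorted(norm)

    def base(self, number: int) -> str:
        return self.sequence[self.numbers.index(number)]

    def paired_positions(self) -> set[int]:
        return {n for p in self.pairs for n in p}

    def is_nested(self) -> bool:
        for a, b in self.pairs:
            for c, d in self.pairs:
                if a < c < b < d:
                    return False
        return True

    def to_dotbracket(self) -> str:
        if not self.is_nested():
            raise ValueError("pseudoknotted structure has no dot-bracket form")
        idx = {n: k for k, n in enumerate(self.numbers)}
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[idx[i]] = "("
            chars[idx[j]] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str,
                        first_number: int = 1) -> "SecondaryStructure":
        if len(sequence) != len(dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")
        numbers = tuple(range(first_number, first_number + len(sequence)))
        stack: list[int] = []
        pairs = []
        for k, ch in enumerate(dotbracket):
            if ch == "(":
                stack.append(k)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {k}")
                pairs.append((numbers[stack.pop()], numbers[k]))
            elif ch != ".":
                raise ValueError(f"unexpected character {ch!r} in dot-bracket")
        if stack:
            raise ValueError("unbalanced '(' in dot-bracket")
        return cls(sequence=sequence, numbers=numbers, pairs=pairs)


def pair_stem_segments(sequence: str, numbers, segment_a, segment_b) -> SecondaryStructure:
    """Pair two equal-length segments in antiparallel register (first of
    a with last of b, and so on)."""
    a = list(segment_a)
    b = list(segment_b)
    if len(a) != len(b):
        raise ValueError("stem segments must have equal length")
    return SecondaryStructure(
        sequence=sequence, numbers=tuple(numbers),
        pairs=[(i, j) for i, j in zip(a, reversed(b))])


@dataclass
class PairTypeCounts:
    gc: int = 0
    au: int = 0
    gu: int = 0
    other: int = 0

    @property
    def total(self) -> int:
        return self.gc + self.au + self.gu + self.other


def count_pair_types(structure: SecondaryStructure) -> PairTypeCounts:
    """Census of the pair list by base letters (orientation-insensitive)."""
    counts = PairTypeCounts()
    for i, j in structure.pairs:
        kinds = frozenset((structure.base(i), structure.base(j)))
        if kinds == frozenset("GC"):
            counts.gc += 1
        elif kinds == frozenset("AU"):
            counts.au += 1
        elif kinds == frozenset("GU"):
            counts.gu += 1
        else:
            counts.other += 1
    return counts


# ---------------------------------------------------------------------------
# Reactivity profiles
# ---------------------------------------------------------------------------

@dataclass
class ReactivityProfile:
    """Per-nucleotide categorical reactivity calls for DMS and CMCT."""

    sequence: str
    numbers: tuple[int, ...]
    calls: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.numbers = tuple(self.numbers)
        for reagent in ("DMS", "CMCT"):
            self.calls.setdefault(reagent, {})
        for reagent, by_pos in self.calls.items():
            for num, call in by_pos.items():
                if call not in CALLS:
                    raise ValueError(f"unknown call {call!r}")
                base = self.sequence[self.numbers.index(num)]
                if call != "unprobed" and base not in PROBEABLE[reagent]:
                    raise ValueError(
                        f"{reagent} cannot probe {base}{num}")

    def call(self, reagent: str, number: int) -> str:
        return self.calls[reagent].get(number, "unprobed")

    def combined_call(self, number: int) -> str:
        """The stronger of the two reagent calls at a position."""
        return max((self.call(r, number) for r in ("DMS", "CMCT")),
                   key=_CALL_LEVEL.get)

    def probed_positions(self) -> list[int]:
        return [n for n in self.numbers if self.combined_call(n) != "unprobed"]

    def force_unprobed(self, numbers) -> None:
        """Mask positions (e.g. the primer-hybridization region)."""
        for reagent in self.calls:
            for n in numbers:
                self.calls[reagent][n] = "unprobed"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tbase\tDMS\tCMCT\n")
            for k, n in enumerate(self.numbers):
                fh.write(f"{n}\t{self.sequence[k]}\t{self.call('DMS', n)}\t"
                         f"{self.call('CMCT', n)}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReactivityProfile":
        numbers, seq, dms, cmct = [], [], {}, {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                n, b, d, c = line.rstrip("\n").split("\t")
                n = int(n)
                numbers.append(n)
                seq.append(b)
                dms[n], cmct[n] = d, c
        return cls(sequence="".join(seq), numbers=tuple(numbers),
                   calls={"DMS": dms, "CMCT": cmct})


def to_fold_constraints(profile: ReactivityProfile,
                        strength_threshold: str = "reactive") -> list[int]:
    """Positions to force single-stranded for an external folding engine.

    A position qualifies when either reagent calls it at or above the
    threshold level ('reactive', or 'weak' to also include weak calls).
    Use :func:`write_fold_constraints` for the text format.
    """
    level = _CALL_LEVEL[strength_threshold]
    if level < _CALL_LEVEL["weak"]:
        raise ValueError("threshold must be 'weak' or 'reactive'")
    return [n for n in profile.numbers
            if _CALL_LEVEL[profile.combined_call(n)] >= level]


def write_fold_constraints(positions, path) -> None:
    """Constraint file: one 'P <n> 0 1' line per single-stranded
    position (the prohibit-pairing dialect of common folding engines)."""
    with open(path, "w") as fh:
        for n in positions:
            fh.write(f"P {n} 0 1\n")


@dataclass
class ConsistencyReport:
    conflicts: list[int] = field(default_factory=list)   # reactive AND paired
    warnings: list[int] = field(default_factory=list)    # protected AND unpaired
    n_probed: int = 0

    @property
    def fraction(self) -> float:
        if self.n_probed == 0:
            return 1.0
        return 1.0 - len(self.conflicts) / self.n_probed


def consistency(structure: SecondaryStructure, profile: ReactivityProfile,
                strict_protection: bool = False) -> ConsistencyReport:
    """Score a secondary structure against probing calls.

    Hard conflicts are reactive positions inside pairs; protected
    unpaired positions are soft warnings by default (protection can
    arise from tertiary burial) and only count as conflicts with
    ``strict_protection``.
    """
    if profile.numbers != structure.numbers:
        raise ValueError("structure and profile cover different positions")
    paired = structure.paired_positions()
    report = ConsistencyReport()
    for n in profile.probed_positions():
        report.n_probed += 1
        call = profile.combined_call(n)
        if call == "reactive" and n in paired:
            report.conflicts.append(n)
        elif call == "protected" and n not in paired:
            report.warnings.append(n)
    if strict_protection:
        report.conflicts = sorted(report.conflicts + report.warnings)
        report.warnings = []
    return report
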