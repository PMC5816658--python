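"""Packaged study fixtures: the two hairpin constructs and their
experimentally established regions.

The 38-nt construct spans nucleotides 59-96 of the inverted SINE B2
effector domain; the refined 29-nt construct spans 64-92.  The stem
runs C64-U75 against A81-G92 (seven G:C, three A:U, one G:U wobble and
one U:U mismatch) and is closed by the GUG triloop G77-U78-G79; the
adjacent U76:A80 pair is dynamic (no observable imino signal).
"""

from __future__ import annotations

from .footprint import ReactivityProfile, SecondaryStructure, pair_stem_segments

SEQ_38 = "GGUAACCUCGUGGUGGUUGUGAACCACCAUGUGGAUGG"
FIRST_38 = 59   # author number of the first residue of the 38-mer

SEQ_29 = "CCUCGUGGUGGUUGUGAACCACCAUGUGG"
FIRST_29 = 64

#: triloop residues
LOOP = (77, 78, 79)

#: stem strand ranges (author numbers, inclusive)
STEM_5P = tuple(range(64, 76))   # C64..U75
STEM_3P = tuple(range(81, 93))   # A81..G92

#: dynamic A:U pair adjacent to the triloop
DYNAMIC_PAIR = (76, 80)

#: the U:U mismatch inside the stem
UU_MISMATCH = (66, 90)

#: 13-nt apical fragment used as the motif-search template
TEMPLATE_RANGE = tuple(range(72, 85))   # U72..A84


def sequence_map(which: str = "29") -> dict[int, str]:
    """Author number -> base letter for the chosen construct."""
    seq, first = (SEQ_29, FIRST_29) if which == "29" else (SEQ_38, FIRST_38)
    return {first + k: b for k, b in enumerate(seq)}


def stem_pairs(include_dynamic: bool = False) -> list[tuple[int, int]]:
    """The stem pair list C64:G92 ... U75:A81 (12 pairs including the
    U66:U90 mismatch); ``include_dynamic`` appends U76:A80."""
    pairs = [(i, j) for i, j in zip(STEM_5P, reversed(STEM_3P))]
    if include_dynamic:
        pairs.append(DYNAMIC_PAIR)
    return pairs


def canonical_stem_pairs() -> list[tuple[int, int]]:
    """Stem pairs that carry imino-observable hydrogen bonds (the 12
    stem pairs minus the U66:U90 mismatch)."""
    return [p for p in stem_pairs() if p != UU_MISMATCH]


def secondary_structure(which: str = "29",
                        include_dynamic: bool = False) -> SecondaryStructure:
    seq, first = (SEQ_29, FIRST_29) if which == "29" else (SEQ_38, FIRST_38)
    return SecondaryStructure(
        sequence=seq,
        numbers=tuple(range(first, first + len(seq))),
        pairs=stem_pairs(include_dynamic),
    )


def stem_structure_for_census(which: str = "29") -> SecondaryStructure:
    """The imino-supported stem pairing used for the pair-type census."""
    return secondary_structure(which, include_dynamic=False)


#: helical residues carrying backbone torsion restraints: the stem minus
#: the loop-adjacent A:U pairs (backbone restraints were omitted for
#: U75-A81)
HELICAL_RESIDUES = tuple(range(64, 75)) + tuple(range(82, 93))


def imino_pair_list() -> list[tuple[int, int]]:
    """The donor -> acceptor rows of the hydrogen-bond stability table,
    in published order.  The published table names the 9th-row donor
    'C71'; position 71 of the sequence is G (the G71:C85 pair), so the
    donor here is G71."""
    return [
        (66, 90), (68, 88), (69, 87), (70, 86), (71, 85), (72, 84),
        (73, 83), (74, 82), (75, 81), (76, 80), (77, 79), (79, 77),
        (88, 68), (89, 67), (90, 66), (91, 65), (92, 64),
    ]


def probing_profile(which: str = "29") -> ReactivityProfile:
    """Categorical footprinting calls for the hairpin region.

    Loop nucleotides G77, U78, G79 react with CMCT and A80 with DMS;
    A81 is weakly DMS-reactive; all stem nucleotides up to C64/G92
    (including the U66:U90 mismatch) are protected.  Overhang residues
    of the 38-mer are left unprobed.
    """
    seq = sequence_map(which)
    dms: dict[int, str] = {}
    cmct: dict[int, str] = {}
    protected = set(STEM_5P) | set(STEM_3P) | {76}
    for n, b in seq.items():
        if n in (77, 78, 79) and b in "UG":
            cmct[n] = "reactive"
        elif n == 80:
            dms[n] = "reactive"
        elif n == 81:
            dms[n] = "weak"
        elif n in protected:
            if b in "AC":
                dms[n] = "protected"
            if b in "UG":
                cmct[n] = "protected"
    return ReactivityProfile(
        sequence="".join(seq[n] for n in sorted(seq)),
        numbers=tuple(sorted(seq)),
        calls={"DMS": dms, "CMCT": cmct},
    )
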