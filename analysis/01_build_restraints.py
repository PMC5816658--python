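"""Build the NMR-derived restraint set for the 29-nt hairpin.

Encodes the refinement rules (sugar pucker for every nucleotide,
glycosidic windows outside the GUG triloop, the five backbone windows
for the helical stem, Watson-Crick/wobble hydrogen bonds for the
imino-supported pairs) and writes the restraint tables plus a count
breakdown to results/.
"""

from pathlib import Path

from triloop import fixtures as fx
from triloop.restraints import (build_torsion_restraints,
                                build_wc_hbond_restraints,
                                torsion_count_breakdown)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    torsions = build_torsion_restraints(fx.sequence_map("29"),
                                        fx.HELICAL_RESIDUES, fx.LOOP)
    counts = torsion_count_breakdown(torsions)
    ss = fx.secondary_structure("29")
    hbonds = build_wc_hbond_restraints(
        [((i, ss.base(i)), (j, ss.base(j)))
         for i, j in fx.canonical_stem_pairs()])

    with open(RESULTS / "torsion_restraints.tsv", "w") as fh:
        fh.write("angle\tresidue\tcenter_deg\thalfwidth_deg\n")
        for t in torsions:
            fh.write(f"{t.angle}\t{t.author_number}\t{t.center}\t{t.halfwidth}\n")
    with open(RESULTS / "hbond_restraints.tsv", "w") as fh:
        fh.write("donor_res\tdonor_atom\tacceptor_res\tacceptor_atom\tlo_A\thi_A\n")
        for h in hbonds:
            fh.write(f"{h.donor[0]}\t{h.donor[1]}\t{h.acceptor[0]}\t"
                     f"{h.acceptor[1]}\t{h.window[0]}\t{h.window[1]}\n")
    with open(RESULTS / "restraint_counts.tsv", "w") as fh:
        fh.write("quantity\tcount\n")
        for key in ("delta", "chi", "backbone", "total"):
            fh.write(f"{key}\t{counts[key]}\n")
        fh.write(f"hydrogen_bonds\t{len(hbonds)}\n")

    print("Restraint construction for the 29-mer (authors 64-92):")
    print(f"  sugar pucker (delta) restraints: {counts['delta']}")
    print(f"  glycosidic (chi) restraints:     {counts['chi']} "
          f"(triloop {fx.LOOP} excluded)")
    print(f"  backbone restraints:             {counts['backbone']} "
          "(22 helical residues x 5 angles, terminus-undefined dropped)")
    print(f"  hydrogen-bond restraints:        {len(hbonds)} "
          "(7 G:C x3 + 3 A:U x2 + 1 G:U x2)")
    print(f"wrote {RESULTS}/restraint_counts.tsv and the two tables")


if __name__ == "__main__":
    main()
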