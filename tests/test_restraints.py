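"""Restraint builders, r^-6 back-calculation and violation statistics."""

import numpy as np
import pytest

from triloop import fixtures as fx
from triloop.restraints import (MEDIUM, NOE_CLASSES, STRONG, WEAK,
                                NOERestraint, back_calculate_noe,
                                build_torsion_restraints,
                                build_wc_hbond_restraints, effective_distance,
                                noe_value, proton_selector, read_noe_table,
                                torsion_count_breakdown, violation_report,
                                write_noe_table)
from triloop.structure import Atom, Conformation, Ensemble, Residue
from triloop.synth import EnsembleSpec, generate_ensemble


def test_noe_class_bounds_fixed():
    assert (STRONG.r_lo, STRONG.r_hi) == (1.8, 3.6)
    assert (MEDIUM.r_lo, MEDIUM.r_hi) == (2.6, 5.0)
    assert (WEAK.r_lo, WEAK.r_hi) == (3.5, 6.5)


# ---------------------------------------------------------------------------
# builder counts on the 29-mer
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def torsions_29():
    return build_torsion_restraints(fx.sequence_map("29"),
                                    fx.HELICAL_RESIDUES, fx.LOOP)


def test_sugar_pucker_restraint_count(torsions_29):
    """One delta restraint per nucleotide of the 29-mer."""
    assert torsion_count_breakdown(torsions_29)["delta"] == 29


def test_glycosidic_restraint_count(torsions_29):
    """chi restraints for every nucleotide except the GUG triloop."""
    assert torsion_count_breakdown(torsions_29)["chi"] == 26


def test_backbone_breakdown_reported(torsions_29):
    """22 helical residues x 5 angles minus the three terminus-undefined
    angles (alpha at the 5' end; epsilon, zeta at the 3' end)."""
    counts = torsion_count_breakdown(torsions_29)
    assert counts["alpha"] == 21 and counts["epsilon"] == 21 \
        and counts["zeta"] == 21
    assert counts["beta"] == 22 and counts["gamma"] == 22
    assert counts["backbone"] == 107


def test_builder_pure_function_of_inputs(torsions_29):
    again = build_torsion_restraints(fx.sequence_map("29"),
                                     tuple(reversed(fx.HELICAL_RESIDUES)),
                                     set(fx.LOOP))
    assert sorted(r.rid for r in again) == sorted(r.rid for r in torsions_29)


def test_empty_helical_set_keeps_delta_chi_rules():
    rs = build_torsion_restraints(fx.sequence_map("29"), (), fx.LOOP)
    counts = torsion_count_breakdown(rs)
    assert counts["backbone"] == 0
    assert counts["delta"] == 29 and counts["chi"] == 26


def test_hbond_restraints_for_the_stem():
    """The 11 imino-supported stem pairs (minus the U:U mismatch) give
    3 per G:C + 2 per A:U + 2 per G:U = 29 restraints."""
    ss = fx.secondary_structure("29")
    pairs = [((i, ss.base(i)), (j, ss.base(j)))
             for i, j in fx.canonical_stem_pairs()]
    assert len(build_wc_hbond_restraints(pairs)) == 29


@pytest.mark.parametrize("pair,expected", [
    ((("G", 1), ("C", 2)), 3),
    ((("A", 1), ("U", 2)), 2),
    ((("G", 1), ("U", 2)), 2),
])
def test_hbond_counts_per_pair_type(pair, expected):
    (ba, na), (bb, nb) = pair
    out = build_wc_hbond_restraints([((na, ba), (nb, bb))])
    assert len(out) == expected


def test_hbond_noncanonical_pairs():
    assert build_wc_hbond_restraints([]) == []
    uu = [((66, "U"), (90, "U"))]
    with pytest.raises(ValueError):
        build_wc_hbond_restraints(uu)
    assert build_wc_hbond_restraints(uu, whitelist=[("U", "U")]) == []


# ---------------------------------------------------------------------------
# NOE back-calculation
# ---------------------------------------------------------------------------

def _two_proton_conformation(d):
    """Two residues, one proton each (plus ring atoms so topology checks
    pass is unnecessary here: NOE resolution only needs the protons)."""
    r1 = Residue(1, "G", "A", [Atom("H8", "H", np.zeros(3))])
    r2 = Residue(2, "C", "A", [Atom("H5", "H", np.array([d, 0.0, 0.0]))])
    return Conformation(residues=[r1, r2])


def test_noe_closed_form_and_scaling():
    rst = NOERestraint(proton_selector(1, "H8"), proton_selector(2, "H5"), STRONG)
    assert noe_value(_two_proton_conformation(2.0), rst) == pytest.approx(1 / 64)
    v1 = noe_value(_two_proton_conformation(3.0), rst)
    v2 = noe_value(_two_proton_conformation(6.0), rst)
    assert v1 / v2 == pytest.approx(64.0)


def test_noe_matrix_matches_brute_force_oracle(two_state):
    """Group-summed r^-6 values equal a naive per-proton double loop."""
    ens, _, experiment = two_state
    sub = Ensemble(conformations=ens.conformations[:5])
    matrix = back_calculate_noe(sub, experiment.restraints)
    for t, conf in enumerate(sub.conformations):
        for i, rst in enumerate(experiment.restraints):
            total = 0.0
            ra = conf.residue_by_author(rst.proton_a[0])
            rb = conf.residue_by_author(rst.proton_b[0])
            for na in rst.proton_a[1]:
                for nb in rst.proton_b[1]:
                    d = np.linalg.norm(ra.atom(na).position - rb.atom(nb).position)
                    total += d ** -6
            assert matrix.values[t, i] == pytest.approx(total, rel=1e-12)


def test_noe_monotone_in_distance(rng):
    rst = NOERestraint(proton_selector(1, "H8"), proton_selector(2, "H5"), WEAK)
    ds = np.sort(rng.uniform(1.5, 12.0, 25))
    vals = [noe_value(_two_proton_conformation(d), rst) for d in ds]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_unresolvable_selector_names_proton():
    rst = NOERestraint(proton_selector(1, "H99"), proton_selector(2, "H5"), WEAK)
    with pytest.raises(KeyError, match="H99"):
        noe_value(_two_proton_conformation(2.0), rst)


def test_effective_distance_properties(rng):
    # constant distance is a fixed point
    assert effective_distance([3.0 ** -6] * 4, [0.25] * 4) == pytest.approx(3.0)
    # the worked two-snapshot example
    assert effective_distance([2.0 ** -6, 6.0 ** -6], [0.5, 0.5]) == \
        pytest.approx(2.2444, abs=1e-3)
    # power-mean bounds
    for _ in range(20):
        d = rng.uniform(2, 9, 6)
        w = rng.dirichlet(np.ones(6))
        eff = effective_distance(d ** -6.0, w)
        assert d.min() - 1e-9 <= eff <= d.max() + 1e-9


# ---------------------------------------------------------------------------
# violation reports
# ---------------------------------------------------------------------------

def test_violation_definition_and_zero_case():
    rst = NOERestraint(proton_selector(1, "H8"), proton_selector(2, "H5"), STRONG)
    rep = violation_report(_two_proton_conformation(3.71), [rst])
    assert rep.max_distance_violation == pytest.approx(0.11, abs=1e-9)
    assert rep.unsatisfied == [rst.rid]
    rep0 = violation_report(_two_proton_conformation(3.0), [rst])
    assert rep0.max_distance_violation == 0.0 and rep0.unsatisfied == []


def test_violation_report_invariant_under_reordering(two_state):
    ens, _, experiment = two_state
    sub = Ensemble(conformations=ens.conformations[:4])
    fwd = violation_report(sub, experiment.restraints)
    rev = violation_report(sub, list(reversed(experiment.restraints)))
    assert fwd.distance_violations == rev.distance_violations
    assert fwd.unsatisfied == rev.unsatisfied


def test_planted_experiment_shows_exactly_seven_uniform_violations(two_state):
    """The synthetic NOE experiment reproduces the qualitative MD
    observation: exactly 7 ensemble-averaged NOEs unsatisfied."""
    ens, _, experiment = two_state
    rep = violation_report(ens, experiment.restraints,
                           weights=ens.uniform_weights())
    assert len(rep.unsatisfied) == 7
    assert sorted(rep.unsatisfied) == sorted(experiment.violated_ids)


def test_ideal_structure_satisfies_torsion_windows_away_from_shears(ideal29):
    """The idealized A-form hairpin sits inside every restraint window,
    except for backbone angles spanning the locally sheared wobble and
    U:U junctions (residues 87-91), where the rigid in-plane shear
    distorts the inter-residue backbone as it does in real structures."""
    torsions = build_torsion_restraints(fx.sequence_map("29"),
                                        fx.HELICAL_RESIDUES, fx.LOOP)
    rep = violation_report(ideal29, torsion_restraints=torsions)
    sheared_junctions = {f"{ang}{num}" for ang in ("alpha", "epsilon", "zeta")
                         for num in range(87, 92)}
    assert set(rep.unsatisfied) <= sheared_junctions
    # intra-residue angles (sugar pucker, glycosidic, beta, gamma) are
    # exact everywhere, including the sheared residues
    for rid, v in rep.dihedral_violations.items():
        if not rid.startswith(("alpha", "epsilon", "zeta")):
            assert v == 0.0, rid


def test_noe_table_round_trip(tmp_path, two_state):
    _, _, experiment = two_state
    path = tmp_path / "noe.tsv"
    write_noe_table(experiment.restraints, path)
    back = read_noe_table(path)
    assert [r.rid for r in back] == [r.rid for r in experiment.restraints]
    assert [r.noe_class.label for r in back] == \
        [r.noe_class.label for r in experiment.restraints]
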