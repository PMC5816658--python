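"""Generate the planted two-state ensemble and its NOE experiment.

A 100-snapshot ensemble of the 29-nt hairpin mixes a native loop
conformation (30%) with a loop-opened state (70%, the loop displaced
and the bases spun).  Proton pairs around the loop are dressed with
intensity-class bounds chosen so that exactly 7 restraints are violated
by the uniform-weight ensemble average while 13 are satisfied -- the
situation an unrestrained trajectory presented.  The full multi-model
PDB goes to scratch/ (large); the NOE matrix, bounds and restraint
table go to results/.
"""

from pathlib import Path

import numpy as np

from triloop import fixtures as fx
from triloop.restraints import violation_report, write_noe_table
from triloop.structure import write_pdb_models
from triloop.synth import (EnsembleSpec, NOEDesign, StateSpec,
                           generate_ensemble, plant_noe_experiment)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 11


def build(seed: int = SEED):
    spec = EnsembleSpec(
        structure=fx.secondary_structure("29"), n_snapshots=100, noise=0.1,
        states=[StateSpec("native", 0.3),
                StateSpec("open", 0.7, shift=(4.0, 2.0, 5.0), base_spin=40.0)])
    ens, truth = generate_ensemble(spec, seed=seed)
    experiment = plant_noe_experiment(
        ens, truth, NOEDesign(n_violated=7, n_satisfied=13),
        candidate_residues=range(74, 84))
    return ens, truth, experiment


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    ens, truth, experiment = build()
    print(f"generated {len(ens)} snapshots "
          f"(native {np.sum(truth.labels == 0)}, open {np.sum(truth.labels == 1)})")
    rep = violation_report(ens, experiment.restraints,
                           weights=ens.uniform_weights())
    print(f"planted {len(experiment.restraints)} NOE restraints; "
          f"{len(rep.unsatisfied)} violated at uniform weights")
    print(f"feasibility boundary: native-state weight must reach "
          f"w* = {experiment.w_star:.3f}")
    experiment.noe.to_tsv(RESULTS / "noe_matrix.tsv")
    np.savetxt(RESULTS / "noe_bounds.txt", experiment.noe_exp)
    write_noe_table(experiment.restraints, RESULTS / "noe_restraints.tsv")
    np.savetxt(RESULTS / "state_labels.txt", truth.labels, fmt="%d")
    write_pdb_models(ens, SCRATCH / "two_state_ensemble.pdb")
    print(f"wrote {RESULTS}/noe_matrix.tsv, noe_bounds.txt, "
          f"noe_restraints.tsv; ensemble PDB in scratch/")


if __name__ == "__main__":
    main()
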