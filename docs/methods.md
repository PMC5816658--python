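# Methods

`triloop` analyses conformational ensembles of a small RNA hairpin — a
G/C-rich A-form stem closed by a GUG triloop, with one U:U mismatch and
one G:U wobble in the stem and a dynamic A:U pair next to the loop —
against the observables an NMR/probing study provides: NOE distance
bounds, imino-proton hydrogen bonds, chemical reactivities and
secondary-structure pairings.  This note records the models, the
conventions and the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Coordinate model and base frames

Structures are ordered residue lists carrying author numbering (the
29-nt construct spans residues 64–92 of the parent element; the 38-nt
construct 59–96).  Multi-model PDB I/O goes through biotite; alternate
locations resolve to highest occupancy, HETATM/solvent records are
skipped.

Two base-fixed frames are used:

* **Ring frame** — origin at the six-membered-ring centroid, x toward
  the Watson–Crick edge, z along the base normal, obtained by
  least-squares fit (Kabsch, via `scipy`'s `Rotation.align_vectors`) of
  the observed ring onto an idealized planar template.  Purines are
  fitted on their six-membered ring only, so the fit tolerates missing
  exocyclic atoms.  Used for pairing/stacking annotation and eRMSD.
* **Standard pair frame** — the standard nucleic-acid base reference
  frame, in which an ideal Watson–Crick pair is generated by rotating
  the partner 180° about x.  Used by the helical-parameter code and the
  A-form builder.

The idealized planar base geometries (standard-frame coordinates of
ring + exocyclic atoms and C1′) are encoded in
`geometry.py:_BASE_XY`; their chemistry — ring bond lengths
1.28–1.45 Å, Watson–Crick donor–acceptor separations 2.87–3.02 Å under
the x-flip, C1′–C1′ ≈ 10.7 Å — is asserted in the test suite rather
than trusted.

## Restraints

NOE cross-peaks are modelled as class-bounded distance restraints:
strong (1.8–3.6 Å), medium (2.6–5.0 Å), weak (3.5–6.5 Å).  Because the
NOE is proportional to r⁻⁶, a restraint becomes a lower bound
NOEᵢ,exp = 1/r_hi⁶ on the (possibly ensemble-averaged) NOE value.
Equivalent-proton groups contribute by **summing** r⁻⁶ over all
proton-pair combinations (the pseudo-atom-free convention); a
center-averaging mode is available for comparison
(`noe_value(..., group_convention="center")`).

Torsion restraints encode the refinement rules: δ = 85 ± 30° for every
nucleotide (C3′-endo pucker), χ = −120 ± 90° (anti) for every
nucleotide except the triloop G77–G79, and α, ζ = 0 ± 120°,
β = 180 ± 40°, γ = 60 ± 40°, ε = 235 ± 65° for helical residues only
(the stem minus U75–A81).  Backbone angles that need a neighbouring
phosphate absent at a chain terminus (α at the 5′ end; ε, ζ at the 3′
end) are dropped silently.  On the 29-mer this yields 29 δ, 26 χ and
107 backbone restraints; the builder reports its own breakdown rather
than forcing any published total, since which single terminal angle a
given refinement retained cannot be reconstructed from counts alone.

Hydrogen-bond restraints per pair type: 3 for G:C (N1–N3, N2–O2,
O6–N4), 2 for A:U (N1–N3, N6–O4), 2 for G:U wobble (N1(G)–O2(U),
O6(G)–N3(U)); non-canonical pairs contribute none unless whitelisted.
The 11 imino-supported stem pairs of the 29-mer give 29 restraints.

Violation statistics: the distance violation of restraint i is
max(0, d_eff − r_hi) with d_eff = (Σₜ W(t)·NOEᵢ(t))^(−1/6); dihedral
violations are circular distances from the window, maximized over
models for an ensemble.  The satisfaction tolerance defaults to 0
(strict).

## Maximum-entropy reweighting

Snapshot weights take the exponential form
W(t) = exp(−Σᵢ λᵢ·NOEᵢ(t)) / Z with one multiplier per restraint,
updated by

    λᵢ += K · [⟨NOEᵢ⟩ − (NOEᵢ,exp + λᵢ σ²)],   λᵢ ← min(λᵢ, 0)

from λ = 0, iterated until every ⟨NOEᵢ⟩ meets its bound.  The clamp
keeps the restraints one-sided (only too-long averages are corrected);
among all feasible weight vectors the exponential solution minimizes
the Kullback–Leibler divergence from uniform — verified against
brute-force grid search on ≤3-snapshot instances in the tests.

**Units.** The step constant K = 10⁻⁵ and error scale σ = 0.5 are only
dimensionally sensible for order-1–10⁴ NOE values, i.e. nm⁻⁶; the API
takes Å⁻⁶ matrices and converts internally (`units="nm"`, default).
Both constants are configurable.

**Stability.**  The update is dual gradient ascent with effective step
K·Var(NOE); it overshoots when that product approaches 1.  With the
default K and nm⁻⁶ values this is safe for weak/medium-class
restraints; the oracle tests on strong-class toy instances use
K = 10⁻⁷.  A too-large K does not diverge silently — it terminates at a
feasible but non-optimal point, which is why the optimality tests exist.

**Stopping.**  Two rules are exposed.  `strict` (default) stops when
all ⟨NOEᵢ⟩ ≥ NOEᵢ,exp within an absolute tolerance (default 10⁻¹⁰ in
working units).  With σ > 0 the fixed point of an active restraint sits
at NOEᵢ,exp + λᵢσ² — *below* the strict bound — so the strict test can
be unreachable; a stall detector then reports `converged_with_slack`
with the slack restraints listed, instead of looping to the iteration
cap.  `relaxed` stops at the σ²-relaxed fixed point directly.  Neither
behaviour is hidden: the result carries the status, the multipliers and
the final averages.  Restraints no single snapshot can satisfy are
detected up front and reported per restraint (`infeasible`).

Representative structures are selected greedily from the pool of the
20 highest-weight snapshots: take the top-weight snapshot, then add,
in descending weight, any snapshot that covers a restraint not yet
satisfied (per-snapshot satisfaction: its own distance within r_hi),
stopping when every restraint is covered.

## Ensemble observables

An imino hydrogen bond (G: N1–H1, U: N3–H3) is present in a snapshot
when donor–acceptor distance < 3.5 Å and the H–donor–acceptor angle
< 30° for at least one acceptor atom of the partner's set (A: N1,
C: N3, G: O6, U: jointly {O2, O4} — one table row per donor).  Its
*stability* is the weight-summed occurrence, a number in [0, 1] that is
linear in the weight vector and reduces to the occurrence fraction
under uniform weights.  When a model carries no protons, a proxy mode
places the imino proton on the in-plane bisector at 1.01 Å and says so.

Pair/stacking annotation classifies each residue pair from the two ring
frames: pairing needs near-coplanarity (|z| ≤ 2 Å in both frames), an
in-plane partner position (ρ ≤ 8 Å) and ≥1 polar inter-base contact
(< 3.4 Å); the edge code (W/H/S) comes from the partner's azimuth
sector in each frame, the cis/trans flag from the sign of the normals'
dot product.  Stacking needs 2 Å < |z| < 5 Å in both frames with
in-plane overlap (min ρ < 4.5 Å); the direction follows the signs of
the two z-readings: (+,−) upward, (−,+) downward, (−,−) outward, (+,+)
inward, so swapping arguments flips upward↔downward.  All thresholds
live in one `AnnotationConfig` block.  They were calibrated once on
ideal constructed geometry (an ideal duplex must annotate WW-cis on
every pair and upward on every intra-strand step) — the published
annotation method they emulate prints its own constants, but without
that implementation installed the calibration here is the package's
own, and cross-tool agreement on borderline geometries is not claimed.

Helical parameters: per base pair a mean pair frame (average of the two
standard frames after flipping the second about x, quaternion mean);
per step, rise = projection of the inter-pair origin displacement onto
the mean pair normal and twist = rotation about that normal between
consecutive pair frames.  For the idealized builder geometry these
definitions recover the construction parameters exactly; on real
A-form coordinates they are local step parameters and can differ from
global-helix-axis conventions by the usual x-displacement/inclination
effects.

## eRMSD and motif search

For every ordered residue pair (i, j) the position of j's ring center
in i's ring frame is anisotropically scaled — in-plane by 5 Å, normal
by 3 Å — and mapped to a smooth 4-vector
G = (sin(γr̃)·r̃/r̃, 1 + cos(γr̃)) / γ with γ = π/2.4, zero at and
beyond the cutoff |r̃| ≥ 2.4.  eRMSD is the root-mean-square G
difference over all ordered pairs, √(Σ|ΔG|²/N).  It is a Euclidean
distance on G-space: identity, symmetry, rigid-motion invariance and
the triangle inequality are asserted in the tests.  The scan slides a
window of template length over every model of every library entry
(chain breaks terminate windows), reports the best window per entry,
and returns hits below the threshold (default 1.0) sorted ascending;
`model_mode` chooses best-over-models (default) or model-1-only.

## Probing logic

Reactivity is categorical (reactive / weak / protected / unprobed), as
read off footprinting gels; DMS can probe A and C (N1/N3), CMCT can
probe U and G (N3/N1), and calls at chemically unprobeable positions
are rejected.  Positions reactive in either reagent at or above a
threshold level are emitted as force-single-strand constraints
(`P <n> 0 1` lines).  Consistency scoring counts reactive∧paired as a
hard conflict; protected∧unpaired is a soft warning by default because
protection can arise from tertiary burial or stacking.

## Synthetic data: what it emulates and what it does not

`build_a_form` places paired bases pair-frame-first on a straight
helix axis (twist 32.8°, rise 2.8 Å by default), partners by the 180°
x-flip, 5′/3′ overhangs as continued single strands and loop residues
on a circular arc over the helix end.  A ribose–phosphate backbone is
attached rigidly in each base's standard frame from a frozen template
whose placement torsions were solved once by least squares so that a
helix-symmetric strand shows A-form backbone torsions (α −69°, β −180°,
γ 51°, δ 84°, ε −157°, ζ −63°, χ −154°) and a near-ideal O3′–P linkage
(1.58 Å).  Wobble and U:U pairs are sheared in-plane onto their
characteristic hydrogen bonds; the shear locally distorts the
inter-residue backbone at those junctions, as real non-canonical pairs
do.  Known idealizations: no helical x-displacement or base
inclination (so local step parameters equal the construction
parameters by design), a non-physical loop arc, and no sequence-
dependent geometry.  Passing tests on this geometry demonstrate the
correctness of the *operators* (back-calculation, reweighting,
annotation, eRMSD), not force-field realism.

`generate_ensemble` realizes a mixture of planted states (rigid loop
displacement and/or base spin) at exact largest-remainder counts, with
label order and atomwise Gaussian noise drawn from a single seed; the
generators are pure functions of (spec, seed).  The default study
condition used throughout the analyses is 100 snapshots, 0.1 Å
coordinate noise, and a 30/70 native/loop-opened mixture — small
enough to run in seconds, large enough that per-state NOE averages are
well separated from their bounds.

`plant_noe_experiment` dresses proton pairs around the perturbed
region with intensity classes such that exactly n_violated restraints
(7 by default, the count an unrestrained trajectory produced) are
violated by the uniform-weight average yet satisfiable by upweighting
the discriminating state, plus n_satisfied that hold from the start.
It also returns the feasibility boundary w* — the minimum weight of
the discriminating state compatible with all bounds, computed from
state-mean NOE values.  With zero coordinate noise the within-state
NOE values are constant, w* is exact, and the maximum-entropy solution
must land on it; the recovery test asserts exactly that.

`simulate_reactivity` draws reactive calls at unpaired probeable
positions with probability 1 − FN and at paired positions with
probability FP, checked against the binomial expectation over 200
seeds.

## Published quantities that are out of desk-scale reach

The per-bond stability table and the annotation stabilities of the
original study were computed on a 400-ns trajectory that is not
deposited; they cannot be recomputed here and are covered instead by
the defining properties of stabilities on synthetic ensembles.  The
pairwise-RMSD, stem rise/twist and cross-structure eRMSD checks
require the deposited coordinate bundles (PDB 5LSN and 2N4L); the
corresponding acceptance test states the exact files it needs and
fails — rather than passing vacuously — when they are absent.  Both
region-superposition and global-superposition pairwise-RMSD
conventions are implemented, since published per-region values do not
always state which was used.
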