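# Methods

## Scope and model

`vhhforge` implements the control logic of a two-step generative nanobody
design campaign: composition-biased CDR sampling, an interface-area
objective, contact admissibility constraints, staged score gates, and a
stack-sorted hill-climbing optimizer. The four heavy external stages —
backbone diffusion, inverse folding, structure prediction, and force-field
scoring/relaxation — are not reimplemented; they are pluggable backends
(`vhhforge.backends`) with deterministic in-repo surrogates standing behind
the same contracts so the pipeline is fully exercisable offline.

## Region model and numbering

Kabat numbering is configuration, never computed: the scaffold is built with
known labels, and a `RegionMap` assigns each label to FR1–FR4/CDR1–CDR3.
Insertion-code labels sort as (number, letter) with the bare number first
(`52 < 52a < 53`).

Two documented ambiguities in the conventional VHH segmentation are resolved
as follows:

* CDR2 is "the 52a–57 block, seven positions", but 52a, 53–57 enumerates
  only six labels. The default map completes the block with a second
  insertion: 52a, 52b, 53–57.
* CDR3 starts at Kabat 95 while the immutable framework span is usually
  quoted as ending at 95. The default map assigns 95 to CDR3 (FR3 = 58–94)
  and makes CDR3 length configurable between 6 and 12 positions, extending
  past 99 with insertion codes (99a, 99b, …).

## SASA and the interface objective

The objective is the buried interface area
`SA_interface = SA_designed + SA_target − SA_complex`, all three terms by
Shrake–Rupley point quadrature: each atom's probe-expanded sphere carries a
golden-spiral lattice; a point is buried iff it lies strictly inside another
atom's expanded sphere; accessible area is the exposed fraction times
`4π(r+probe)²`.

Parameters and numerical choices:

* **probe radius 1.4 Å** — the standard water probe;
* **960 lattice points** — the refinement test (960 vs 3840 points) bounds
  the quadrature error of the total below 1% on the bundled fixture;
* **van der Waals radii** — frozen per-element table (C 1.70, N 1.55,
  O 1.52, S 1.80, H 1.20 Å); hydrogens are included when present;
* **canonical frame** — point quadrature with a space-fixed lattice is
  weakly orientation-dependent, so atom centers are first rotated into the
  eigenbasis of their covariance matrix with axis signs fixed by coordinate
  skewness. The frame is a covariant function of the geometry, making areas
  exactly invariant under rigid motion. Perfectly symmetric point sets
  (degenerate covariance eigenvalues, zero skewness) would make the frame
  orientation-sensitive again; molecular structures, including the bundled
  fixture, are never that symmetric.
* `interface_sa` canonicalizes the *complex* once and evaluates all three
  terms in that frame, summing the complex total chain-by-chain; the
  interface of two chains too far apart to share occlusion is therefore
  exactly 0.0, not merely small.
* Neighbor search uses a k-d tree over atom centers with an
  over-approximating candidate radius, then filters to true occluders;
  results are identical to all-pairs checking (tested).

No claim is made that these areas match Rosetta's surface definitions; the
reference interface areas reported for real campaigns (e.g. a reference
complex near 1313 Å²) require the external relax protocol and are context,
not targets.

## Contacts and admissibility

A designed-chain residue contacts the target iff any of its atoms is within
4.0 Å of any target atom. The bound is inclusive: "within 4.0 Å" is read as
a closed bound, and the k-d tree query used is a closed ball. All atoms
participate (backbone, side chains, hydrogens when present).

Admissibility of a pose:

* `fr_contact_count > 5` → FR_EXCESS (5 framework contacts pass; "more
  than five" fails);
* fewer than 2 distinct CDRs in contact → TOO_FEW_CDRS;
* CDR3 not in contact → CDR3_NOT_IN_CONTACT. "CDR3 contact is mandatory"
  is interpreted as *at least one* CDR3 residue in contact; requiring every
  CDR3 residue to touch the target would reject nearly all plausible poses.

## Sampling modes

Tables are aggregate composition only; positions are sampled independently
(no positional profile — the design constraint is stated as bulk content).
In `cdr12-min-3-germ`, the CDR3 remainder after Tyr/Ser/Gly (50%) is shared
equally by the 15 residues other than Tyr, Ser, Gly, Cys, Met:
(1 − 0.50)/15 ≈ 3.333% each — the printed per-residue share (3.3%) does not
sum exactly to 100%, so the table is renormalized. Cys and Met carry
probability zero and are recorded as prohibited. The surrogate sampler
enforces the table exactly (a real inverse-folding backend would apply it as
a soft bias; the contract leaves that to the backend).

## Surrogate backends

The surrogates are pure functions of geometry, chosen for exact testability,
and are documented as non-physical:

* interaction score = `−1.0 × (inter-chain atom pairs ≤ 4.0 Å) + 10.0 ×
  (pairs < 2.5 Å)`; lower is better, REU-like scale;
* PAE surrogate = `clamp(30 − 2.0 × contacting residue pairs, 1, 30)`;
* structure update: each CDR residue's pseudo side-chain sphere radius is
  reassigned from a frozen table — cube roots of standard mean residue
  volumes mapped linearly onto [1.0, 2.4] Å (Gly → 1.0, Trp → 2.4) — with
  backbone coordinates and framework side chains untouched. Framework
  substitutions are an error: FR immutability is a contract, not a
  convention.

The coefficients (−1.0, +10.0, 2.0) are frozen module constants. External
backends are invoked through a JSON request/response exchange (see
`SubprocessScorer`); a recorded/replay scorer verifies that pipeline
semantics are independent of which backend produced the scores.

## Optimizer semantics

Decisions taken where the procedure was genuinely open:

* "16 attempts" are 16 proposals per cycle against the current top-of-stack
  candidate; accepted variants are pushed without evicting the predecessor.
* Acceptance compares against the *immediate predecessor* (the candidate
  whose CDRs were resampled), not the global best, and consults interface
  SA only — the interaction score is never an acceptance criterion, it only
  gates selection.
* All gates are strict inequalities ("below −20 REU", "lower than 10"):
  boundary values are excluded, including −40.0 REU at final selection.
* The 50-cycle budget is per root, not global.
* RNG: a master seed fans out to one stream per (root, cycle, attempt), so
  serial and parallel execution produce identical results, and reruns are
  bit-identical.
* Final selection orders ancestors by their best candidate's score and
  round-robins one candidate per ancestor per pass; ties break on higher
  interface SA, then id.

## The synthetic fixture

`toyworld` builds a deterministic pseudo-complex: the receptor is a planar
9×12 grid of uniform spheres (2.5 Å spacing), and the designed chain is a
120-residue scaffold with one backbone and one side-chain sphere per
residue. CDR side chains hang 2.8 Å above the grid facing a three-residue
epitope; framework segments run high and off to the side so they never
contact the receptor. The fixture is < 400 atoms, so brute-force oracles
(all-pairs contacts, analytic sphere caps, cross-implementation SASA) run in
seconds.

What it emulates: an admissible starting pose (all three CDRs in contact,
zero framework contacts), realistic interface-area magnitudes (~900–1050 Å²),
and a sequence→structure→score feedback in which bulkier CDR residues bury
more interface. What it does not emulate: real loop geometry, side-chain
packing, electrostatics, or any energetics — under the surrogate update the
backbone never moves, so contact counts (and hence the surrogate score and
PAE) are constant along an optimization trajectory and only the interface
area changes. Passing tests therefore demonstrate the correctness of the
pipeline's logic, bookkeeping and invariants, not binding of any real
design.

Scaffold framework sequences are fixed literals of plausible VHH framework
character; they are synthetic, not a germline reference.

## Problem sizes

The bundled test suite and the worked example run the optimizer at reduced
budgets (2 roots, 2–6 cycles, 6–16 attempts per cycle) — the stack semantics
are budget-independent, and the full 50×16 schedule is exercised with a
cheap mock scorer where the test is about counting (stack size
1 + 16×50 = 801). The composition statistics use 200,000 draws, where the
binomial standard error (≤ 0.12 percentage points) sits comfortably inside
the ±0.5-point check.

## Known limitations

* No automatic Kabat/Chothia/IMGT renumbering; the RegionMap is explicit.
* mmCIF, heteroatoms, ligands and multi-model files are out of scope.
* SASA is plain Shrake–Rupley: no analytic derivatives, no coarse-grained
  approximation, no Rosetta-compatible surface definition.
* The surrogate stages are not predictive of real binding; campaign-scale
  score distributions from GPU pipelines cannot be reproduced here.
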