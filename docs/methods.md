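# Methods

This note records the model, the numerical and design choices, and the
limits of what the synthetic tests demonstrate.

## Inputs and their contract

The package analyses one domain movement at a time, given as:

* two PDB-format conformations of the same protein, **already
  superposed on one domain** (the fixed-domain frame produced by
  DynDom-style analysis). The package never verifies superposition;
  contacts are computed per conformation in whatever frame is supplied,
  and the single screw-axis record is interpreted in that common frame;
* a partition of residues into domain A, domain B and bending regions
  (pairwise disjoint; domains non-empty);
* the interdomain screw axis: a point, a unit direction, the rotation
  angle (degrees), the translation along the axis (Å) and the
  percentage closure. These scalars are consumed, not computed — screw
  axis determination is the job of the upstream domain-decomposition
  program.

Parsing keeps heavy atoms only (element not H/D, with an atom-name
fallback when the element column is blank), the first-listed alternate
location per atom name, model 1 of multi-model files, and author
residue numbering with insertion codes. HETATM residues are excluded by
default (a flag includes them); waters are always excluded. These
conventions are deterministic, standard choices; the underlying method
statement is silent on all of them.

## Contact definition

Residues are in contact when the minimum heavy-atom distance is
**≤ 4.0 Å** (inclusive — "within" is read as ≤, and the boundary is
pinned by tests; boundary cases have measure zero in real coordinates).
Before collecting interdomain pairs, two exclusions apply:

* bending-region residues;
* residues with any heavy atom within **5.5 Å** (inclusive) of the
  *infinite* axis line — the screw axis is a line, not a segment.

Both kinds would contribute maintained contacts regardless of
mechanism and would bias the classifier toward shear. The exclusion is
evaluated per conformation against the one supplied axis; because a
rigid rotation about the axis preserves distances to it, the moving
domain's exclusion set is stable across the two conformations.

The production search flattens each domain's atoms into a k-d tree
(`scipy.spatial.cKDTree`) and queries ball neighbourhoods at the
cutoff; the naive all-pairs residue scan is kept in the package as the
reference implementation and the two are asserted equal on randomized
fixtures (up to 200 residues) and on exact-boundary fixtures.

## DCG decomposition

The dynamic contact graph has forward edges (conformation 1 contacts)
and backward edges (conformation 2). The decomposition into
maintained / exchanged-partner / exchanged-pair / new elements follows
a fixed canonical rule, because the element counts are otherwise not
unique:

1. every pair present in both conformations is a **maintained**
   element (forced by the definition) and removed;
2. remaining forward-only and backward-only edges are matched
   one-to-one, maximizing lexicographically first the number of
   **exchanged-partner** elements (edge pairs sharing exactly one
   residue — the most specific signature, whose undercounting would
   bias toward hinge), then **exchanged-pair** elements (edge pairs
   sharing no residue); unmatched edges are **new**.

The exchanged-partner maximum is a maximum-cardinality bipartite
matching (deterministic Kuhn augmenting paths over residue-key-sorted
adjacency). Two consequences make the rest trivial: after a maximum
matching no leftover forward/backward pair can share a residue
(otherwise the matching would extend), and no leftover pair can share
both residues (those were maintained) — so every leftover cross pair is
a valid exchanged-pair and the exchanged-pair count is
min(leftover forward, leftover backward). The counts are therefore
invariant across optimal matchings, satisfy edge conservation
|F| + |B| = 2(N_maint + N_exchpart + N_exchpair) + N_new, and are
checked against an exhaustive enumeration of all pairings
(`decompose_bruteforce`, ≤ 14 edges) on hundreds of seeded random
graphs plus hypothesis-generated graphs. If a supplied real structure
pair ever disagrees with externally published counts, the discrepancy
will surface in these reports rather than being silently absorbed.

## Classifier

The predictor is plain logistic regression on **N** with the shear
label as the positive class. The packaged constant stores the
published-form coefficients exactly; internally logit(y) = w·N + b with
w the negated α-coefficients, and a test asserts the α form is
reproduced verbatim to 1e-12. Class boundaries (0.45 / 0.55) are
applied to the **full-precision** y, never to a rounded value: the
count vector (10, 2, 2, 6) has y ≈ 0.5470, which prints as 0.55 yet
falls in the mixed class — comparing rounded values would misclassify
it. The boundary comparisons are inclusive (y ≤ 0.45 hinge,
y ≥ 0.55 shear). The no-contact class is decided before prediction,
from **N** = 0 alone.

Fitting minimizes the cross-entropy (kept with its ½ factor for
faithful objective values; the optimum is unaffected) by Newton/IRLS:
zero initialization, iteration cap 200, infinity-norm gradient
tolerance 1e-8. The objective is convex, so the fit is deterministic
without seeds; statsmodels' Newton Logit is used as an independent
cross-check in the tests. Complete separation is detected from the
fitted margins (all strictly positive implies a separating hyperplane,
hence a divergent MLE) and reported as a warning with the coefficients
capped at the iteration limit.

ROC curves sweep the distinct prediction values as thresholds
(items with score ≥ threshold predicted positive), AUC is trapezoidal,
and the area under the upper convex hull is reported alongside.
Leave-one-out cross-validation refits per fold and aggregates the
held-out predictions; folds that would leave a single class are
skipped with a warning. Precision of a predicted class is
correct/predicted, with mixed predictions counting toward neither
class and an empty class reported as undefined (NaN), not zero.

## Geometry

* **Axis outside the protein**: no heavy atom within 5.5 Å (inclusive)
  of the axis line, i.e. outside ⇔ minimum distance > 5.5 Å.
* **Mechanical hinge**: a bending region with at least one Cα within
  5.5 Å of the axis — Cα only; a side chain reaching toward the axis
  does not count. Bending regions are formed by grouping bending
  residues consecutive in (chain, residue number); grouping is a
  package convention, as segments are otherwise undefined.
* **Pitch** = |translation| / rotation angle (Å/degree); undefined (an
  error) at zero angle; invariant under axis-direction flip since the
  translation sign flips with the direction.
* **Closure vs twist**: closure iff percentage closure > 50.

## Statistics

The pooled one-sided two-proportion z-test (see README) reproduces the
printed comparison values for the axis-outside, twisting-prevalence
and effective-hinge-axis contrasts from their printed group counts. A
permutation test at n = 400 per group agrees with the normal
approximation within Monte-Carlo error; at small n the approximation
visibly overstates significance, which is why the package exposes the
test for database-scale counts, not toy samples. A Welch-style z for
mean/SD summaries is included as a convenience only; no published
mean-based comparison is claimed to be reproduced, since the exact
test behind those values is not derivable from the printed summaries.

## Synthetic data

`synth` builds poly-alanine-like residues (N, CA, C, O, CB) so the
heavy-atom contact logic runs on realistic atom counts without rotamer
machinery. Domain A and domain B face each other with a 5.9 Å gap
between Cα planes, placing facing Cβ atoms 3.48 Å apart — inside the
4 Å cutoff with a safe margin against the default 0.03 Å jitter.
Conformation 2 applies an exact screw transform (Rodrigues rotation
plus axial translation) to domain B only.

* **hinge**: facing 8-residue chains; a 30° rotation about an axis at
  the interface edge (through the bending residues, which therefore
  form a mechanical hinge) swings domain B away and breaks all eight
  contacts — a pure-new DCG; annotated closure (84%).
* **shear**: facing 5×5 grids; a 5° rotation about the interface
  normal displaces atoms by at most ~1.3 Å, preserving the contacts —
  a maintained-dominated DCG; annotated twist (30%), with the bending
  residues placed far from the axis so no effective hinge axis exists.
* **no_contact**: domains 40 Å apart.

The training-set simulator draws count vectors from independent
Poissons — half with hinge-like means (0.3, 0.2, 4, 14), half with
shear-like means (20, 6, 0.2, 0.3) — and labels each item
Bernoulli(y(**N**)), reading the model output as the posterior
probability of shear. The means emulate clear-cut, intuitively
assignable movements (wholesale contact creation for hinge, a large
preserved interface for shear), so most simulated predictions sit near
0 or 1. That choice matters quantitatively: with Bernoulli labels the
average in-sample prediction error of a refitted model scales like
√(w̄·p/n) with w̄ the mean of y(1−y), p = 5 parameters; at n = 400 a
mid-range regime (w̄ ≈ 0.2) cannot beat ~0.05 mean |Δy| no matter how
the optimizer behaves, while the saturated regime (w̄ ≈ 0.02) recovers
the generating predictions to ~0.01. Null-model calibration (labels
independent of counts) is evaluated on leave-one-out held-out
predictions, since in-sample AUC of a refitted 5-parameter model is
optimistically biased by ~0.05–0.08 at this n.

What the fixtures do **not** emulate: real side-chain packing and
rotamer rearrangement (so exchanged-partner-rich interfaces are
under-represented among the structural fixtures), disorder, missing
residues, crystal contacts, and the correlated count structure of real
interfaces. Passing tests demonstrate the pipeline's correctness and
the classifier's self-consistency, not field performance on PDB data.

## Problem sizes and determinism

Randomized checks use fixed seeds throughout: 500 random DCGs for the
decomposition oracle, ~200-residue fixtures for the contact oracle,
400-item simulated training sets for recovery and null calibration.
These sizes give stable pass/fail behaviour at comfortable margins
while keeping the whole suite around two seconds. Every generator is
deterministic given its seed; the fitting path contains no randomness
at all.

## Known limitations

* The decomposition priority (maximize exchanged-partner, then
  exchanged-pair) is a stated canonical rule; alternative priority
  orders yield different count splits for pathological graphs, though
  maintained and the exchanged total are rule-independent.
* The published coefficients ship as constants; refitting them exactly
  would require the original 77-movement labelled training table,
  which is not distributed here. Database-scale quantities (class
  fractions, training-set AUC) are likewise outside what synthetic
  data can certify.
* Percentage closure, rotation angle and translation are trusted
  inputs; no consistency check against the two structures is made.
* The two-proportion test assumes independent cases; domain movements
  from related families violate this mildly.
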