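# hingeshear

Quantitative assignment of **hinge** versus **shear** mechanisms to
protein domain movements, from interdomain residue contact changes.

Multi-domain proteins move their domains to bind ligands, close over
substrates and transmit signals. A long-standing classification splits
these movements into *hinge* mechanisms (the domains approach or
separate roughly perpendicular to their interface, creating or breaking
contacts — a "pacman" movement) and *shear* mechanisms (the domains
slide along a preserved interface). Historically the assignment was
made by eye; this package implements a reproducible, quantitative
version for anyone analysing conformational pairs from the PDB with a
DynDom-style domain decomposition in hand.

## Method

Given two conformations of a two-domain protein, superposed on one
domain, with the interdomain screw axis known:

1. **Contacts.** Residues i, j are in contact when any heavy atom of i
   is within 4 Å of any heavy atom of j. Residues in bending regions,
   and residues with any heavy atom within 5.5 Å of the screw axis, are
   excluded first (they keep their contacts whatever the mechanism).
2. **Dynamic contact graph (DCG).** Interdomain contacts of
   conformation 1 become forward edges A→B, those of conformation 2
   backward edges B→A. The DCG decomposes into four elemental motifs,
   counted as **N** = (N_maint, N_exchpart, N_exchpair, N_new):
   *maintained* (same pair in both conformations), *exchanged-partner*
   (one residue swaps partners — sliding), *exchanged-pair* (disjoint
   pairs swap — see-saw) and *new* (a contact in only one conformation).
3. **Logistic predictor.** The packaged model computes
   y(**N**) = 1/(1 + e^α) with
   α = −0.2387 N_maint − 0.0356 N_exchpart + 0.4249 N_exchpair
   + 0.2122 N_new + 0.1467,
   read as the posterior probability of shear. Classes: **hinge** for
   0 ≤ y ≤ 0.45, **shear** for 0.55 ≤ y ≤ 1, **mixed** in between, and
   **no-contact** when **N** = 0.
4. **Screw-axis geometry.** Whether the axis lies outside the protein
   body, which bending regions are *mechanical hinges* (a Cα within
   5.5 Å of the axis), the pitch |translation|/angle, and the
   closure (>50%) versus twist (≤50%) annotation.
5. **Statistics.** Pooled one-sided two-proportion z-tests for
   comparing the hinge and shear sets.

Training machinery (cross-entropy fit by Newton/IRLS, ROC/AUC with
convex hull, leave-one-out cross-validation, per-class precision) is
included as a scikit-learn-style estimator, `HingeShearClassifier`.

## Worked example

Generate a synthetic hinge movement (two facing poly-alanine domains,
domain B rotated 30° about an axis at the edge of the interface) and
classify it:

```sh
hingeshear simulate --kind hinge --seed 1 --out fx
hingeshear classify --conf1 fx/conf1.pdb --conf2 fx/conf2.pdb \
    --domains fx/domains.txt --axis fx/axis.txt --out run
```

which logs the pipeline stages and prints:

```text
INFO:hingeshear:conf1: 8 interdomain contacts
INFO:hingeshear:conf2: 0 interdomain contacts
INFO:hingeshear:N = (0, 0, 0, 8)
class: hinge (y = 0.136544)
```

All eight interface contacts of the closed conformation are broken by
the opening — a pure-new DCG, N = (0, 0, 0, 8) — and the prediction
value 0.137 < 0.45 assigns the hinge class. `run/axis_analysis.txt`
reports the geometry: the axis passes through the bending region
(`mechanical_hinges = A:9-10`, an effective hinge axis) and the
movement is a closure.

The same from Python, on a count vector with a large preserved
interface plus some contact turnover:

```pycon
>>> import hingeshear as hs
>>> hs.predict((10, 2, 2, 6))
0.5469859559272142
>>> hs.classify((10, 2, 2, 6)).value
'mixed'
```

y ≈ 0.547 lies in the 0.45–0.55 band: slightly more
interface-preserving than interface-creating, so neither class is
assigned cleanly.

Comparing two sets by proportion (here: 5 of 361 versus 9 of 884 cases
with a screw axis outside the protein):

```sh
$ hingeshear stats 5 361 9 884 --label axis_outside
label	s1	n1	s2	n2	z	p_one_sided_percent
axis_outside	5	361	9	884	0.5571	28.87
```

z ≈ 0.56 with a one-sided p of 29%: no evidence the first set has more
outside axes.

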