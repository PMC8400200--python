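# Methods

`moonpep` implements a classifier-guided workflow for designing
*moonlighting* cell-penetrating peptides (CPPs): single-domain peptides
that carry a second activity — a receptor ligand, or a protease-operated
off-switch — inside the CPP sequence itself rather than as an appended
domain. The workflow has three parts: a 27-descriptor featurization of
peptide sequences, a random-forest CPP/non-CPP classifier, and a
constrained sequence search that adds residues around a fixed functional
motif until the classifier's consensus probability P(CPP) crosses a
design threshold (or, for activatable designs, drops below one).

## The descriptor vector

Each sequence over the 20 canonical residues maps to 27 numbers, in a
fixed order that is part of the I/O contract:

| index | descriptor | notes |
|---|---|---|
| 0–19 | residue counts (A…Y alphabetical) | raw counts; a frequency flag exists but defaults off |
| 20 | mean hydrophobicity | Eisenberg consensus scale |
| 21 | mean charge | Henderson–Hasselbalch net charge at pH 7, divided by length |
| 22 | isoelectric point | bisection root of net charge on pH ∈ [0, 14], tol 1e-4 |
| 23 | sliding-window range of charge | width 11, step 1, max − min |
| 24 | sliding-window range of hydrophobic moment | Eisenberg μH, 100°/residue |
| 25 | water/octanol partition | additive Fauchère–Pliška side-chain sum |
| 26 | helical content | Chou–Fasman helix-former fraction (Pα ≥ 1.00) |

Charge model: basic groups (H, K, R) contribute
`+1/(1+10^(pH−pKa))`, acidic groups (D, E, C, Y) `−1/(1+10^(pKa−pH))`,
with the EMBOSS pKa set. Free termini are **excluded by default**
because the designs this package targets are N-terminally
fluorophore-conjugated; a flag restores them. Hydrophobic moment:
`μH = (1/N)·|Σ_k h_k · e^{i k δ}|` with δ = 100° (α-helical wheel) and
per-residue normalization. All scales live in a `ScaleSet` and every
choice is overridable; under different scales the absolute
probabilities of any trained model shift accordingly.

Numerical details worth knowing:

* **Degenerate pI.** A peptide whose net charge never changes sign on
  [0, 14] (e.g. polyarginine with termini off, or one with no ionizable
  groups) has no root; the bracket endpoint with the smaller |charge|
  is returned with a `degenerate` flag rather than an exception, so
  featurization never fails on a valid sequence.
* **Short sequences.** A sequence not longer than the window width is
  its own single window and both window ranges are 0.
* Indices 0–22, 25, 26 are permutation-invariant; 23–24 intentionally
  are not (they detect local segregation of charge/amphipathicity).

## The forest

The classifier is a bagged ensemble of CART trees implemented in this
package (scikit-learn is used only for the estimator API surface, fold
assignment and as an independent cross-check in the tests):

* per tree, a bootstrap resample of size n (with replacement);
* per tree, a random descriptor subset whose **size is itself uniform
  on 1..27** (`feature_rule="random_size"`, the default); a
  conventional fixed-size rule (`fixed_m`, m = 6 ≈ ⌈√27⌉) is provided
  because the random-size reading is unusual;
* splits by Gini impurity decrease, thresholds at midpoints between
  consecutive distinct values, grown to purity by default
  (`min_leaf=1`, no depth cap);
* ties in impurity decrease break to the lowest feature index, then the
  lowest threshold; leaf-vote ties break to class 0 (non-CPP) —
  conservative, and it makes training bit-reproducible under a seed;
* consensus P(CPP) = the **mean of hard leaf votes**, so with 500 trees
  (the default) probabilities are granular at 0.002; a soft-vote mode
  (mean of leaf class fractions) exists behind a flag;
* out-of-bag error is computed from per-sample majority votes of the
  trees that did not see that sample.

One float subtlety: when two consecutive sorted feature values are
adjacent floating-point numbers, their midpoint rounds onto the upper
value and would produce an empty branch; the threshold then falls back
to the lower value.

## The design search

A design task fixes a motif that must appear intact and exactly once
(additions that accidentally recreate a second copy are discarded), a
mode (`embed_cpp` maximizes P(CPP), target ≥ 0.88 by default;
`embed_noncpp` minimizes it, target ≤ 0.20 by default, bracketing the
published activatable designs), a placement (`both_termini` for
targeted designs, `c_terminal_tail` for activation), a total
added-residue budget (default 12), and an addition alphabet.

The optimizer is a genetic algorithm whose genome is the (N-flank,
C-flank) string pair: point mutation, single-residue insertion and
deletion act on the flanks only, selection is tournament (size 3) on a
length-penalized fitness `raw − λ·n_added` (λ = 0.01 — small enough
never to outweigh a threshold crossing, but it encodes the preference
for short peptides: cost, degradation, antigenicity), with elitism.
The initial population is the empty-flank design plus random flanks
drawn across the **whole** added-residue budget; seeding only short
flanks and waiting on single insertions leaves optima that need ~12
additions effectively unreachable in a default-length run. All distinct
evaluated designs that meet the target are returned, ranked by fewest
additions, then fitness, then sequence (reproducible total order); if
none succeeds, the single best design is returned flagged
`success=False`.

`exhaustive_design` enumerates every flank assignment up to a cap
(guarded at 10⁶ candidates) and is the optimality oracle for the GA in
the tests. A `cleave` helper cuts a design at a protease recognition
site (neprilysin's FFGFLA cuts after the G) to produce the activated
fragment.

## The synthetic corpus

Real CPP training corpora are not redistributable here, so the package
bundles a generator that emulates the two axes such corpora actually
vary on. Positives are sampled from a 50/50 mixture of two archetypes —
polycationic (K/R-dominated, Tat- and oligoarginine-like) and
cationic-amphipathic (K plus an L/I/F/W hydrophobic face,
penetratin-like). Negatives emulate ordinary hydrophilic/acidic
peptides, with K/R kept at background rates: a negative class devoid of
basic residues would let any classifier win by counting lysines, and
would misjudge cationic-core-plus-acidic-tail constructs that real
models must resolve. Lengths are uniform on 10–35.

Two labeling modes: `by_generator` (label = sampling class) and
`by_descriptor_rule`, where labels obey a known ground truth —
*positive iff mean charge > 0.25 and mean hydrophobicity > 0.19* (the
Eisenberg scale median) — enforced by rejection sampling outside an
exclusion margin (default 0.05). The rule mode gives the recovery
experiments a recoverable, interaction-shaped signal.

What the generator does **not** emulate: motif structure, length/
composition correlations, sequence homology and family redundancy, or
any curated-database biases. Passing recovery tests therefore show the
pipeline is self-consistent — the forest can recover a planted
descriptor rule and the search can steer designs across the learned
boundary — not that the classifier matches one trained on curated CPP
data.

## Recovery experiments and the worked example

`recovery_experiment` trains on rule-labeled data and checks held-out
(stratified 5-fold) accuracy; at n = 400, margin 0.05 and 500 trees it
sits at ≈ 1.0, and collapses to ≈ 0.5 when labels are permuted.
`design_recovery_experiment` trains a 200-tree forest on 150+150
rule-labeled peptides, then (i) appends a D/E tail (budget 8) to a
strongly cationic-amphipathic core until the predicted label flips, and
(ii) flanks a short neutral motif (GAGA; brevity keeps the
cationic-amphipathic region arithmetically reachable within 12 added
residues) until P(CPP) ≥ 0.88.

The worked example re-scores the six published moonlighting designs
under a forest trained on the synthetic stand-in corpus (500+500,
500 trees). The coarse structure is robust across seeds: the three
targeted designs and the cleaved activation core score high, the
de-activated construct scores low and classifies as non-CPP, and the
most cationic design (NLS-α-CE) scores highest. The fine ordering
between designs a few hundredths apart, and exact probabilities, depend
on the original training corpus and are not reproduced by the stand-in;
the test suite asserts the published ordering faithfully and documents
the one link that does not hold under these conditions.

All experiment sizes above (corpus sizes, tree counts, GA budgets) are
the package defaults, chosen so the full pipeline runs in well under
five minutes on one CPU.

## Known limitations

* Descriptors are sequence-letter functions: D-amino-acid peptides
  carry only a metadata flag and score identically to their L-isomers
  (the published table reports slightly different values for the
  enantiomer pair, which letter-based descriptors cannot express).
* No solubility, toxicity, receptor-affinity or protease-kinetics
  modeling; the cleavage helper is purely positional.
* Probabilities are consensus vote fractions, not calibrated
  probabilities.
* The exact scales, window width and helix approximation of the
  original descriptor implementation are not published; all are
  configurable here, and absolute P(CPP) values shift under different
  choices.
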