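# moonpep

Design of **moonlighting cell-penetrating peptides** (CPPs): peptides
that embed a second activity — a receptor ligand, or a protease-operated
off-switch — *within* the penetrating sequence itself, keeping designs
short, cheap to synthesize and less antigenic than tandem-domain
fusions.

The package is for peptide and delivery-oriented researchers who want
to:

1. **featurize** peptide sequences with 27 physicochemical descriptors
   (residue counts; mean hydrophobicity and charge; isoelectric point;
   sliding-window ranges of charge and Eisenberg hydrophobic moment
   μH = (1/N)·|Σₖ hₖ·e^{ikδ}|, δ = 100°; additive water/octanol logP;
   helix-former fraction);
2. **classify** CPP vs non-CPP with a bagged random forest of
   hard-voting CART trees (bootstrap per tree, random descriptor subset
   per tree, Gini splits); the consensus P(CPP) is the fraction of
   trees voting CPP;
3. **design** by constrained search: a genetic algorithm adds residues
   at the termini of a fixed motif — never touching it — until P(CPP)
   crosses a target (≥ 0.88 to *create* a CPP around a ligand such as
   the yeast α-pheromone; ≤ 0.20 to *silence* a CPP core such as
   Tat + the neprilysin site FFGFLA until proteolytic activation).

A bundled synthetic-corpus generator (cationic/amphipathic positives vs
hydrophilic/acidic negatives, with an optional known labeling rule)
makes the whole pipeline trainable and testable offline.

## Worked example

Train a forest on a synthetic corpus and re-score the six published
moonlighting designs (three targeted yeast designs embedding the
α-pheromone WHWLQLKPGQPMY, and the Tat-based activation series):

```python
from moonpep import train_forest
from moonpep.synth import SynthParams, generate_synthetic_dataset
from moonpep.sequences import STUDY_PEPTIDES

corpus = generate_synthetic_dataset(SynthParams(n_pos=500, n_neg=500, seed=1))
model = train_forest(corpus.dataset, n_trees=500, random_state=1)
for name, (seq, reported, _) in STUDY_PEPTIDES.items():
    p = float(model.predict_proba([seq])[0, 1])
    print(f"{name:15s} reported={reported:5.3f} predicted={p:.3f}")
```

```
alpha-NLS-C     reported=0.910 predicted=0.890
NLS-alpha-CE    reported=0.970 predicted=0.946
chimera         reported=0.880 predicted=0.902
TatNep          reported=0.990 predicted=0.734
TatNepNoCPP     reported=0.112 predicted=0.222
D-TatNepNoCPP   reported=0.110 predicted=0.222
```

The three targeted designs clear the 0.88 design bound, the cleaved
activation core (TatNep) scores as a CPP, and the de-activated
construct (TatNepNoCPP — the core plus the six-residue acidic tail
DDDDEE) collapses to a non-CPP, mirroring the published pattern.
Absolute values and fine orderings depend on the training corpus; see
`docs/methods.md`.

Design searches run from Python or the CLI:

```sh
moonpep --seed 1 synth --n-pos 500 --n-neg 500 -o corpus.tsv
moonpep --seed 1 train corpus.tsv --trees 500 -o model.json
moonpep --seed 1 design --motif WHWLQLKPGQPMY --mode cpp \
        --max-added 12 --model model.json -o design_report.json
```

`design` prints the best candidate with its P(CPP) and the number of
added residues, and writes a ranked JSON report (fewest additions
first) plus a FASTA of all designs meeting the target.

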