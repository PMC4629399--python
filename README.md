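# guidecraft

Structure- and sequence-aware design of CRISPR/Cas9 single-guide RNAs
(sgRNAs): an RBF-kernel SVM predicts each guide's knockout potency from the
20-nt guide sequence and the folded structure of the assembled sgRNA, hard
pre-filters discard unpromising candidates cheaply, and an exon-restricted
off-target screen enforces specificity. Input is FASTA; output is a ranked
TSV design report.

Intended users: anyone designing knockout guides who wants potency-aware
ranking rather than specificity-only filtering — and anyone with their own
activity screen who wants to train and cross-validate a potency model on it.

## The model

Guides from an activity screen are stratified into *functional* (top 20 %
of the activity ranking) and *non-functional* (bottom 20 %) classes; the
middle is excluded. An SVM with RBF kernel

&nbsp;&nbsp;&nbsp;&nbsp;K(x, x′) = exp(−γ‖x − x′‖²)

is trained on a 176-entry feature vector per guide: GC content; overlapping
mono-/di-/trinucleotide counts; repetitive-run, GGGG and seed-UUU motif
flags; the guide's self-folding minimum free energy ΔG_fold (RNAfold,
37 °C); the RNA/DNA hybrid energy ΔG_duplex (Sugimoto 1995 nearest-neighbor
parameters); binary structural accessibility of sgRNA positions 18–20 and
51–53 in the MFE fold of the full guide+scaffold sgRNA; and a 20×4
position-specific one-hot encoding. (C, γ) come from a log-spaced grid
search with internal cross-validation; scores are Platt-calibrated to
[0, 1].

Before scoring, candidates failing any hard rule are excluded: ΔG_fold
< −8 kcal/mol, ΔG_duplex < −22 kcal/mol, GC > 80 %, UUU in the last six
bases, a repetitive base run, U at position 19, C/U at position 20. A
candidate is also excluded if its 3'-terminal 13-nt seed occurs in any
unintended exon directly 5' of an NGG/NAG PAM, or if any exonic 20-mer
matches it at more than 85 % identity (≤ 3 substitutions, ungapped).
See `docs/methods.md` for assumptions, parameter scales and limitations.

## Worked example

Train a model on a (here synthetic) activity screen, index exons, and
design guides for a target:

```bash
python -c "from guidecraft.screen_io import *; \
           write_screen_table(generate_synthetic_screen(600, seed=42), 'screen.tsv')"
guidecraft train --screen screen.tsv --out model.joblib --seed 1 --no-prefilter
# trained on 120+120 extremes; C=8 gamma=0.000488281; saved model.joblib
guidecraft index --exons exons.fa --out exons.idx
guidecraft design --targets target.fa --model model.joblib --index exons.idx --out report.tsv
# scanned 82 candidates: 78 pre-filtered, 0 off-target-excluded, 4 ranked -> report.tsv
```

`report.tsv` lists every scanned candidate; the ranked head (selected
columns):

```
source_id  start  strand  guide                 pam  svm_score  rank
MYGENE     201    +       AAAGAAAUAAGAAAUAAAAG  AGG  0.999996   1
MYGENE     488    +       GAAUCCUAAAGAAAUUCCAG  CGG  0.988744   2
MYGENE     413    +       CAAUUCAGAUAGUUGGACAG  AGG  0.930773   3
```

`start` is the 1-based protospacer position, `svm_score` the calibrated
potency probability, and `rank` orders only candidates that passed both the
pre-filters and the off-target screen (the other 78 rows carry their
elimination reason in `prefilter_failures` / hit counts instead). Here the
top guide is the A-rich, structure-free candidate the synthetic screen's
planted signal favors, scored near 1.

The same steps are available as library calls (`train_svm`,
`crossvalidate`, `design_guides`, …), and `guidecraft audit-filters
--screen screen.tsv` reports per-class exclusion rates of each pre-filter.

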