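# Methods

## Problem and model

`guidecraft` predicts the knockout potency of CRISPR/Cas9 single-guide RNAs
(sgRNAs) and designs guides against user sequences. The premise is that a
guide's activity is driven jointly by sequence composition and by the
secondary structure of the assembled sgRNA: a guide whose PAM-proximal 3'
end ("seed", positions 18–20) is sequestered in intramolecular structure, or
whose hybrid with the target DNA is excessively stable, recognizes its
target poorly.

The potency model is a binary classifier separating *functional* from
*non-functional* guides, defined as the top and bottom 20 % of an activity
screen's ranking (the middle 60 % is excluded from training to sharpen the
contrast). Classification uses a support vector machine with an RBF kernel
over a 176-entry feature vector per guide:

| block | entries | notes |
|---|---|---|
| GC fraction | 1 | (#G+#C)/20 |
| mono-/di-/tri-nucleotide counts | 4+16+64 | overlapping windows within the 20-mer |
| motif flags | 3 | repetitive run (AAAAA/CCCCC/GGGG/UUUU); GGGG; UUU in positions 15–20 |
| self-folding ΔG | 1 | MFE of the 20-mer alone, kcal/mol |
| duplex ΔG | 1 | RNA/DNA hybrid nearest-neighbor energy, kcal/mol |
| accessibility | 6 | unpaired-state flags at sgRNA positions 18–20 and 51–53 |
| position one-hot | 80 | base identity at each of the 20 positions |

Accessibility is binary, read off the dot-bracket minimum-free-energy (MFE)
structure of the full 100-nt sgRNA (20-nt guide + 80-nt *S. pyogenes*
scaffold). Positions 51–53 of the default assembly are AAG; a guide ending
in pyrimidines can pair with them and extend the first scaffold stem-loop
over the seed, which is why both triplets are features. Ensemble (partition
function) accessibilities are deliberately not used — the binary
paired/unpaired call on the MFE structure is the modeled quantity.

## Folding and thermodynamics

All folding uses ViennaRNA (RNAfold) at its default 37 °C parameter set;
the engine version is recorded in every model manifest. MFE values are
clamped to ≤ 0 (an unfoldable sequence reports 0.0 and an all-dots
structure).

Guide:target hybrid energies use the Sugimoto et al. (1995) RNA/DNA
nearest-neighbor ΔG°37 parameters, shipped as a TSV in `guidecraft/data/` so
that tests and the implementation read one source. The energy of a perfect
20-bp hybrid is the sum of the 19 stacking terms (keyed by the RNA dimer)
plus +3.1 kcal/mol initiation. Mismatched duplexes are rejected rather than
approximated.

**Scale caveat.** On the Sugimoto scale a random 20-mer hybrid averages
about −24.7 kcal/mol (sd ≈ 3.9). Published duplex-stability filters for
sgRNA design are sometimes stated on other nearest-neighbor scales that sit
several kcal/mol higher; with the default exclusion threshold of
−22 kcal/mol the duplex pre-filter is therefore strict, excluding roughly
three quarters of random guides. Orderings and differences between guides
are scale-invariant and are what the tests assert; users who want a more
permissive duplex filter should lower `thresholds.duplex_dg` in the YAML
config.

## Pre-filters

Before SVM scoring, hard rules discard guides with properties strongly
enriched among non-functional guides: self-fold ΔG < −8 kcal/mol, duplex
ΔG < −22 kcal/mol, GC > 80 %, UUU within the last six bases, any repetitive
run, U at position 19, C or U at position 20. Thresholds print as strict
inequalities and are implemented that way: a guide sitting exactly on a
boundary passes. All rules are evaluated (no short-circuit) so audits can
attribute exclusions per rule. By default the SVM trains on the pre-filtered
extremes, matching a pipeline in which the model only ever scores
pre-screened candidates; `prefilter=False` trains on all extremes.

## Training and evaluation

Features are min–max scaled to [0,1] using training-set constants stored
with the model. (C, γ) are chosen by grid search over the libsvm practical
ranges C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ with internal 3-fold stratified CV on
accuracy; the default grid uses log₂ steps of 4 (a coarse-first grid), and
the step is configurable. Probability-style scores in [0,1] come from Platt
sigmoid calibration on seeded CV splits (`CalibratedClassifierCV` with
`ensemble=False` around the RBF SVC). Models serialize with a manifest
(feature order, scaffold, folding-engine version, hash); scoring refuses a
manifest whose hash disagrees with the live feature assembler.

Two cross-validation modes: stratified tenfold, and leave-one-gene-out
(every guide of one gene held out per fold — with nine genes this trains on
eight and tests on the ninth). Each fold re-runs the grid search; pooled
out-of-fold scores give the AUC. ROC-AUC uses the tie-aware rank
definition; the precision–recall curve reports every distinct threshold in
descending order plus the positive-fraction baseline (the precision of
random selection).

## Off-target screening

Restricted to exon space by design. Two rules, both causes for exclusion:

* **seed+PAM**: the guide's 3' 13 nt (as DNA), found anywhere in an
  unintended exon immediately 5' of NGG *or* NAG, on either strand. Exact
  k-mer lookup over a prebuilt index of all 16-nt seed+PAM windows.
* **similarity**: any exonic 20-mer (either strand) within 3 substitutions
  of the guide — ungapped identity ≥ 17/20 = 85 %. Gapped alignment of
  20-mers is ill-defined at this scale, so "over 85 % similarity" is
  operationalized as the ungapped mismatch count; similarity hits are
  PAM-agnostic, which is the stricter reading.

Windows containing N never match. Coordinates are 0-based half-open
internally and in BED exports; the TSV design report prints 1-based starts.
The on-target site is spared either by declared coordinates or, when
unambiguous, by a unique exact protospacer+PAM match.

## Design pipeline

`scan_pam_sites` enumerates every NGG-adjacent 20-mer on both strands
(N-containing candidates dropped). Order of operations: PAM scan → hard
pre-filters → SVM scoring of survivors → off-target screen → ranking by
descending score, ties broken by fewer similarity near-misses, then by
5'-most start. Every scanned candidate appears in the report with either a
dense rank (from 1) or its elimination reason; pre-filtered candidates are
reported unscored.

## Synthetic screens

`generate_synthetic_screen` emulates a flow-cytometry-style knockout screen:
uniform random 20-mers (UUUU-containing guides rejected, as U6-driven
screens preselect), nine genes assigned round-robin, and activity

    activity = effect_size · z(planted) + ε,  ε ~ N(0,1)

where the planted score is `#A − 4·I(GGGG) − |self-fold ΔG| − 2·I(position
20 ∈ {C,U})`, z-scored within the batch. The terms deliberately overlap the
model's feature set so parameter-recovery tests are meaningful; the
coefficients weight the rarer, stronger motifs (GGGG) above the graded terms
and are fixed package constants. Default conditions are n = 2000 and
effect size 2, giving top/bottom-quintile classes that a working pipeline
separates with cross-validated AUC well above 0.85, while effect size 0
yields chance AUC.

What the generator does *not* emulate: gene-specific activity baselines,
position-of-cut effects within a transcript, chromatin context, measurement
error structure beyond i.i.d. Gaussian noise, and any feature outside the
planted rule. Passing recovery tests therefore demonstrates that the
pipeline recovers a signal of the modeled kind when present — not that the
shipped defaults reproduce any particular laboratory screen.

## Numerical choices and degenerate inputs

* Percentile labels use numpy linear-interpolation quantiles with inclusive
  boundary comparisons (a tie at the threshold joins the extreme class); on
  1841 distinct activities this yields 369 guides per class.
* All-identical activities make stratification undefined and raise.
* Welch's t-test (unequal variances) is used where a class-mean comparison
  is needed; binary flags use Pearson's χ² without continuity correction.
  Identical degenerate groups report ratio 1, p = 1.
* Folding results are cached per sequence; with a pinned engine version the
  whole pipeline is deterministic given its seeds.
* Report sorting and rank ties are fully specified (see above), so repeated
  runs are byte-identical.

## Known limitations

* Exon-space off-targeting only; no genome-wide scan, no bulges/gaps, no
  off-target activity scoring.
* Duplex energetics cover perfect hybrids only.
* The default scaffold is one common 80-nt S. pyogenes assembly; other
  scaffolds are accepted but change the accessibility features, so models
  are scaffold-specific (enforced via the manifest).
* Problem sizes in the test and acceptance runs (screens of 300–2000
  guides, exon fixtures of 10–20 kb) were chosen as the smallest sizes at
  which the statistical checks are stable.
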