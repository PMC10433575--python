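# Methods

## Problem and model

`bactipred` treats bacteriocin detection as balanced binary classification
of short proteins (roughly 20–100 residues) over a fixed 643-dimensional
descriptor space. The underlying assumption is that bacteriocins carry a
recognisable physicochemical signature — cationic, often
hydrophobic/amphiphilic, adopting diverse secondary structures — that
survives even when sequence similarity to known families is low. The
pipeline is deliberately classical: interpretable descriptors, statistical
filtering, and kernel/ensemble classifiers whose selected features can be
read off.

## Descriptors

* **AAC / DPC** are plain residue and adjacent-pair frequencies with
  denominators L and L−1.
* **PseAAC (type I)** uses λ=10 correlation tiers and weight w=0.05. The
  tier-j factor θ_j averages Θ(R_i, R_{i+j}) over all i, where Θ is the
  mean of squared differences of three standardized scales
  (hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass; each scale
  z-scored over the 20 residues with population SD). The 30 components are
  jointly normalized to sum to 1, so w→0 recovers AAC padded with zeros.
  λ=10 is forced by the 30-dimensional target; w=0.05 is the conventional
  default.
* **APAAC (type II)** uses the same λ and w with lag-j autocorrelations of
  the two hydropathy scales interleaved (τ_{2j−1} hydrophobicity, τ_{2j}
  hydrophilicity), giving 20 + 2λ = 40 components.
* **CTD** uses the canonical seven-property, three-group residue
  partitions (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary-structure propensity, solvent
  accessibility). Composition is the per-group fraction; transition the
  fraction of adjacent cross-group pairs per unordered pair; distribution
  records 100·position/L of the first residue of each group and of the
  residues at index max(1, ⌊q·n_g⌋) for q ∈ {0.25, 0.5, 0.75, 1.0}, with
  zeros for absent groups. 7 × (3+3+15) = 147.
* **Secondary structure** is predicted in-package by a deterministic
  propensity method: per-residue argmax of Chou–Fasman helix/sheet/turn
  propensities, smoothed by majority vote over a 5-residue window
  (truncated at the termini); ties resolve coil, then helix, then sheet.
  The predictor sits behind a plain state-string interface and can be
  swapped without touching the six summary features, which are per-state
  composition and longest-run fraction. These six are the package's own
  concrete definition of "position/segment" secondary-structure summaries;
  alternatives (mean segment length, first-occurrence index) carry similar
  information.

Column order is frozen (AAC, DPC, PseAAC, APAAC, CTD by property, SS) and
identical across runs and platforms; models refuse matrices whose columns
do not cover their stored feature list.

## Selection cascade

1. **Correlation filter** (cutoff 0.9): constant columns are removed first
   (ρ undefined) and logged. For each violating pair, the member with the
   larger mean absolute correlation against all other features is dropped
   (tie → later column). The pass is idempotent.
2. **Welch t-test** per feature, α = 0.05, no multiple-testing correction —
   a deliberate fidelity choice to the classical recipe this implements;
   the cascade's later CV stage is what guards against false discoveries.
   The unequal-variance form is the safer default where the pooled form
   was not specified. A feature identical in both classes gets p = 1 by
   convention; a zero-variance feature with different class means keeps
   its p of 0 (it is maximally informative).
3. **MDG ranking**: impurity-based mean decrease in Gini from a 500-tree
   random forest. The default retention rule is "score above the mean
   score"; a top-k override exists for reproducing a fixed target
   dimensionality. How the original recipe cut its list is not recoverable,
   so the rule is explicit and logged.
4. **RFE**: features are ranked (RF → impurity importance; SVM →
   univariate |AUC − 0.5|, since an RBF SVM exposes no per-feature weight)
   and a grid of subset sizes is scored by mean repeated stratified k-fold
   CV-AUC (default 10-fold × 5 repeats). The ranking is recomputed inside
   every fold from that fold's training part, as caret's `rfe` resampling
   does; without this the per-size CV-AUC is optimistically biased and a
   label-permutation null lands well above 0.5 (we measured ≈ 0.64 at
   n = 120 with 100 candidate features when ranking once outside the CV).
   Best size is the argmax, ties to the smaller subset. The default size
   grid is {1..N} for N ≤ 60, else a 20-point geometric grid plus N.

## Classifiers

Features are z-scored with training-set constants only. The SVM tunes only
C ∈ {4, 8, 16, 32, 64, 128}; the RBF width is fixed beforehand as
γ = 1/median(pairwise squared distances) on the standardized training
rows, mirroring kernlab-style sigma estimation. Probabilities come from
Platt scaling (sigmoid calibration with internal 5-fold CV). The random
forest tunes ntree ∈ {400, 500} and mtry ∈ {5, 6} (≈ √44 for a ~44-feature
set); its probability is the fraction of trees voting positive. Grid ties
break to the smaller parameter. The assessment forests inside RFE use 100
trees — ranking stability needs far fewer trees than the final model, and
repeated CV multiplies every fit by 50.

## Evaluation

Accuracy, MCC, recall, precision and F1 follow the standard confusion
formulas with fixed degenerate conventions (precision/recall 0 when their
denominator is 0; MCC 0 when any factor under the root is 0). The accuracy
interval is exact Clopper–Pearson, which reproduces published reference
intervals at 107/112 and 106/112 exactly and therefore identifies the
method. Model-vs-model probability comparisons use a two-sided paired
t-test (sidedness was an open choice; two-sided is the conservative one),
with p = 1 for zero-variance zero-mean differences and p = 0 for
zero-variance nonzero-mean ones. The sequence-matching baseline replaces
BLASTP with an in-package local aligner (BLOSUM62, gap open 11 / extend 1,
identity = matches/alignment columns × 100) and reports, per identity
threshold, how many query sequences have a best hit at or above it; it
reproduces the shape of the comparison, not E-values.

## Dataset handling

Redundancy reduction approximates CD-HIT with greedy longest-first
clustering per class: a sequence is kept iff its global-alignment identity
(match +1, mismatch 0, linear gap −1; identity = matches/alignment length)
to every kept sequence is below 0.9. Balancing subsamples the majority
class without replacement; the split is per-class with
test = ⌊0.2·n_class⌋ (283+283 in → 56+56 test out). Whether balancing or
splitting came first in the original recipe is unknowable from the outside;
this package reduces redundancy, balances, then splits, and accepts
pre-made train/test FASTA files as authoritative when provided
(`from_split_fasta`).

## Synthetic data

The generator emulates two classes of short proteins whose residue
compositions differ by a controllable effect size δ: negatives are i.i.d.
draws from a SwissProt-like background composition; positives from a
mixture placing weight δ on a pool enriched in K (0.22), R (0.18),
C (0.15) and G (0.15) — a caricature of cationic, disulfide/glycine-rich
bacteriocins. Defaults: 100 sequences per class, lengths uniform on
30–80, δ = 0.5. What it does **not** emulate: motif/family structure,
positional signal, leaders/cleavage, length–class correlation, or
homology clusters. Passing tests therefore demonstrate that the machinery
recovers compositional signal and is honest under the null — not that real
bacteriocin accuracy will match the synthetic numbers.

## Numerical choices and problem sizes

Determinism: every stochastic step (subsampling, splitting, CV fold
layout, forests) derives from one user-visible seed. Standardization uses
population SD with zero-SD features left centred. Test and acceptance runs
use scaled-down study sizes chosen once: 5-fold × 2-repeat CV instead of
10 × 5, 100-candidate cascade matrices at n = 120, and 100 sequences per
class end-to-end; the full 10 × 5 protocol remains the library default.

## Limitations

* The six secondary-structure summary features and the propensity
  predictor are this package's own concrete definitions of an
  under-specified classical recipe; they are pinned by oracle tests, not
  by an external reference implementation.
* Printed historical stage counts (e.g. 643→590→140, 44, 131 selected)
  depend on the original data, CV seeds and tie-breaking conventions and
  are not treated as reproducible constants; the pipeline reports its own
  counts in the run log.
* Greedy identity clustering is not CD-HIT; at 90% identity on short
  peptides the difference is small but nonzero.
* The t-test filter's raw α = 0.05 threshold admits false positives by
  construction; downstream RFE is the guard.
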