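# Methods

This note documents the models and procedures implemented in `pdzscan`,
the parameters that matter, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## The prediction problem

A PDZ domain is represented by the 16 alignment columns of its binding
site that contact the ligand (a string over the 20 amino acids plus
'-' for alignment gaps). A ligand is the C-terminal 5-mer of a protein,
positions labelled p-4..p0 with p0 the terminal residue. Prediction is
binary: given (domain, peptide), does the pair interact? Training data
come in two shapes: fully labelled interaction tables (protein
microarray style, ±1 labels) and positive-only tables (phage display
style), which require artificial negatives before a discriminative
model can be trained.

## Genomic-likeness filtering

Phage display selects optimal binders from random peptide libraries, so
its positives can be non-genomic. A peptide is *genomic-like* when its
last four residues (p-3..p0) equal the last four residues of at least
one C-terminal tail of the reference proteome. Only the last four
positions are compared because the p-4 residue contributes least to
recognition and tail sets are sparse at five positions. Domains are
categorized by the number of unique genomic-like (g) and
non-genomic-like (n) peptides they bind, with threshold t = 10:
genomic-like (g ≥ t, n < t), non-genomic-like (g < t, n ≥ t), dual
(both ≥ t), non-specific (both < t). Filtering then proceeds in the
order: drop non-genomic-like domains entirely; strip non-genomic-like
interactions from dual domains; drop dual domains left with fewer than
t unique genomic-like peptides; keep genomic-like and non-specific
domains unfiltered provided they have at least t unique peptides in
total. Category assignment uses the unfiltered counts; the filter is a
subset operation and is idempotent. Unique peptides are counted as
fully distinct 5-mers.

## Position weight matrices

A PWM is a 20×5 column-stochastic matrix estimated with additive
smoothing: cell(a, j) = (count(a at j) + c) / (N + 20c) with
pseudocount c = 0.01 by default (c > 0 is needed to score residues
unobserved in small binder sets; results depend on c only through
rankings near ties). A peptide's score is the sum over positions of
log2 cell probabilities — a log-likelihood under the independent-
positions model, not a log-odds against a background; no background
model is assumed, and every use of the score downstream depends only on
ranks. PWM–PWM similarity is the mean over columns of the Pearson
correlation between 20-entry probability vectors, mapped to [0, 100] by
100·(r+1)/2; a zero-variance column contributes 50 (r treated as 0).
This metric is bounded, symmetric, and 100 exactly at identity. Logo
export writes per-residue letter heights, probability × column
information content (log2 20 − entropy, bits).

## Artificial negatives

For a domain with positive set P and a cross-domain pool U of unique
real binders, the PWM-selected method scores U \ P with the domain's
PWM, discards candidates scoring at or above min-score(P) (ties at the
cutoff are excluded: a score-indistinguishable peptide should not be
labelled a non-binder), sorts the rest ascending (score, then
lexicographic for determinism), and greedily accepts candidates sharing
at most `redundancy_max_identity` (default 3 of 5) identical positions
with every already-accepted negative. Selection stops at
⌈ratio·|P|⌉ (default ratio 2.0, the approximate artificial-negative to
phage-positive ratio of the benchmark corpus). If the pool is exhausted
first, the domain is flagged *insufficient* and excluded from training
by the pipeline — this operationalizes "domains that are hard to
generate negatives for". Greedy lowest-score-first acceptance is a
design choice: it maximizes dissimilarity from the binder distribution
subject to the redundancy cap, and it is deterministic. The three
baselines are: `random` (i.i.d. uniform residues), `shuffled`
(per-positive residue permutations), and `randomly_selected` (uniform
draw without replacement from the same below-cutoff candidate pool,
ignoring score order). All stochastic methods use an independent,
reproducible stream per (seed, domain id).

## Feature encodings

The contact-map encoding fixes a list of (domain position, peptide
position) pairs; for pair k with residues (a, b), bit
k·400 + index(a)·20 + index(b) is set (alphabetical one-letter residue
order). The shipped default map has 38 pairs over all 16 domain
positions and all 5 peptide positions, giving 15,200-bit vectors with
at most 38 set bits. The pair list itself is a synthetic reconstruction
(the published analysis reports only the structural constants); the
encoding's behaviour — dimensionality, sparsity, locality of residue
changes — is invariant to which 38-pair map is used. An alignment gap
at a domain position zero-fills its 400-bit block ("no information").
The binary-sequence encoding is 21 one-hot blocks (16 site + 5 peptide
residues, 420 bits); the physicochemical encoding replaces each residue
by the five-factor descriptor of Atchley et al. (2005), min-max scaled
to [0, 1] per factor over the 20 amino acids (105 values). Min-max
scaling for real-valued encodings is fitted on training vectors only;
test values are clipped to [0, 1] and constant dimensions map to 0.
Scaling is applied after encoding. Binary encodings pass through
unscaled.

## The weighted-cost SVM

The decision function is f(x) = sgn(Σᵢ αᵢyᵢK(xᵢ,x) + b), sgn(0) = +1,
with the RBF kernel K(x,z) = exp(−γ‖x−z‖²). The dual maximizes
W(α) = Σαᵢ − ½ΣΣ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ) subject to 0 ≤ αᵢ ≤ C_class(i) and
Σαᵢyᵢ = 0. Class imbalance is handled by per-class costs related by
C⁺ = (n⁺/n⁻)·C⁻ — the positive-class box constraint is scaled by the
exact count ratio (0.48622… at the benchmark corpus counts
n⁺ = 1006, n⁻ = 2069). The dual is solved by libsvm (via
scikit-learn's SVC, tolerance 1e-3 by default, shrinking enabled); the
package computes the Gram matrix explicitly with sparse linear algebra
and trains on the precomputed kernel, which is roughly an order of
magnitude faster for 38-of-15,200-bit vectors than row-wise kernel
evaluation. The returned model stores support vectors, dual
coefficients αᵢyᵢ and bias, and scores new points by explicit kernel
expansion; tests verify the solution against an independent SLSQP
quadratic-program oracle on small problems (decision-score agreement
within 1e-4, box and equality constraints, KKT structure). Grid search
scans log2-spaced grids C ∈ {2⁻⁵..2¹⁵}, γ ∈ {2⁻¹⁵..2³} (the
conventional exhaustive RBF ranges) by stratified k-fold mean ROC AUC,
breaking ties toward smaller C then smaller γ. ROC AUC was chosen as
the internal criterion because it matches how performance is reported;
accuracy would interact badly with the class imbalance the weighted
costs exist to absorb.

The default γ = 0.05 used throughout the examples reflects the
geometry of contact-map vectors: two gap-free encodings differ in at
most 76 bits, so γ = 0.05 maps the maximal squared distance to
K ≈ 0.02 while near-duplicates stay near 1.

## Evaluation

Threshold metrics follow the standard confusion-matrix definitions
(TPR = TP/P, FPR = FP/N, precision = TP/(TP+FP),
F1 = 2·precision·recall/(precision+recall)); 0/0 cases are defined as 0
and logged. ROC curves group tied scores into single operating points;
the trapezoidal area then equals the Mann–Whitney U statistic with ties
counted half (verified exactly in tests). PR areas use the
Davis–Goadrich interpolation: between consecutive achievable points FP
is interpolated linearly in TP and the area accumulated at unit-TP
steps; the curve is anchored at recall 0 with the first achievable
precision.

Cross-validation schemes: stratified 10-fold over interactions;
leave-fraction-out schemes that hold out all interactions touching a
sampled 12% of domains, 8% of peptides, or both (defaults follow the
benchmark's figure captions; its methods text swaps the two numbers, so
both are configuration parameters), repeated 10 times with redraws when
a draw yields a single-class test set; and leave-one-domain/peptide-out.
Per-split AUCs, pooled curves over all held-out scores, and mean AUCs
are all reported, since pooling and averaging answer slightly different
questions. For leave-one-domain-out, each run records the held-out
domain's binding-site similarity (fraction of matching columns; gap vs
residue is a mismatch, gap vs gap a match) to its nearest training
neighbour, enabling similarity-stratified AUC tables. All schemes slice
one precomputed Gram matrix rather than re-encoding per split.

The nearest-neighbour baseline returns, among the training interactions
of the most similar domain, the label of the most similar peptide, with
score = (domain similarity) × (peptide similarity); ties prefer the
positive label, then lexicographic order. The PWM-ensemble baseline
scans tails with the nearest training neighbour's PWM and returns the
top 1% by score. Scan validation reports recall over known positives,
FPR only when known negatives exist (undefined otherwise, never
silently 0), and a one-sided hypergeometric (Fisher's exact) overlap
p-value against the scanned universe.

## Synthetic data generator

The generator emulates the statistical shape of the training corpora:
domains with planted per-position binding preferences, positive-only
peptide sets, and decoy proteome tails. Each domain's specificity is an
independent per-position categorical distribution — exactly the PWM
model, inheriting its documented inability to represent inter-position
dependencies. A column gives probability p = s/(s+19) to a preferred
residue (sharpness s; default 40, p ≈ 0.68; s = ∞ degenerates to the
consensus) and spreads the rest uniformly over 4 tolerated residues
that are a deterministic function of the preferred one — real
specificity columns tolerate a handful of residues, not all 20, and the
deterministic tolerated set keeps the site→specificity map smooth under
mutation. Domains descend from founders along a family tree; each child
mutates a configurable number of binding-site columns and, with
probability ½ per site mutation, redraws one position's preferred
residue. Site similarity therefore predicts specificity similarity,
which is what makes the similarity-stratified analyses testable.
Positives are drawn from the specificity (draws, not unique peptides,
so duplicates occur as in real binder lists); negatives are uniform
decoy tails at 2 per positive; labels flip with probability
`label_noise`. A single seeded generator drives everything, so a fixed
seed reproduces the dataset byte for byte.

What the generator does **not** emulate: inter-position dependencies in
specificities, compositional bias of real proteomes (decoy tails are
uniform), fluorescence-intensity noise of microarrays, and panning-round
artefacts of phage display. Passing tests on synthetic data therefore
demonstrate the pipeline's correctness and its qualitative behaviour
(scheme ordering, similarity dependence), not performance on real
experimental corpora, whose headline AUCs depend on data this package
does not ship.

## Problem sizes and reproducibility

The recovery analyses use 50 domains × 50 peptides (≈7,500 training
vectors) for the pipeline/CV comparison and a 36-domain family (6
founders, planted divergence between 1 and 12 site mutations) for the
leave-one-domain-out similarity analysis, with similarity bins
[0, 0.5), [0.5, 0.8), [0.8, 1.0] chosen to give low/mid/high groups.
These sizes make every analysis reproducible in well under a minute
each on a single CPU while keeping per-bin counts large enough for
stable medians. Every stochastic component takes an explicit seed; the
pipeline derives independent per-stage streams from one root seed and
records seeds and input checksums in its manifest.

## Known limitations

- The shipped contact map is a structurally plausible stand-in, not the
  original pair list; models trained with different maps are not
  interchangeable.
- PWM scoring uses raw log-probabilities; a background-corrected score
  would change negative selection only through rank changes near the
  cutoff.
- The PWM similarity metric is this package's own definition (bounded
  Pearson); published similarity percentages computed with other
  metrics are not directly comparable.
- `leave_one_peptide_out` over thousands of unique peptides is
  quadratic in practice; prefer the fraction-based scheme at scale.
- Proteome scans treat each domain independently; multi-PDZ proteins'
  interactions cannot be attributed to a specific domain.
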