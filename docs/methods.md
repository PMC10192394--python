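# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not establish.

## Windows and benchmark construction

A propionylation site peptide PSP(m, n) is a lysine-centered window
with m upstream and n downstream residues; m = n = 30 by default, so
windows are 61-mers. Positions beyond the protein termini are padded
with `*`, which is also a scored symbol of the 24-letter matrix
alphabet (20 residues plus B, Z, X, `*`), so every scoring formula is
total over padded windows. Coordinates are 1-based protein positions
throughout.

The negative pool is every non-positive lysine in proteins that carry
at least one positive site; unrelated proteins would contribute
trivially easy negatives. Redundancy clearance is exact-duplicate
removal only (one item per distinct 61-mer, positives winning label
conflicts — a peptide observed modified anywhere is not a safe
negative). No sequence-identity clustering is applied; homology
filtering beyond exact duplicates is out of scope.

## Pair-similarity embedding

The average similarity between a window P and the N reference
positives is

    S = (1/N) Σ_{j} ( Σ_{i} M[P_j, K_ij] ) · W_j,

with the substitution matrix M initialized to BLOSUM62 (taken from
Biopython's matrix collection; its own `*` column scores pad symbols)
and position weights W_j initialized to 1. The embedded vector has one
entry per unordered character pair,

    S_ab = (1/N) Σ_j C_j(a, b) · M[a, b] · W_j,

where C_j(a, b) counts reference windows whose character at j pairs
with P_j as {a, b}. Pairs partition all (P_j, K_ij) co-occurrences, so
Σ S_ab = S to machine precision — this identity is asserted in the
tests. The canonical feature order is the 20 standard residues
alphabetically, then B, Z, X, `*` (so features run S_AA, S_AC, ...,
S_**), giving 24·25/2 = 300 features.

When a window being embedded is itself a member of the reference set,
its own contribution is removed (leave-self-out over the remaining
N − 1 references); otherwise a positive would partly match itself and
inflate its features relative to negatives.

### Weight and matrix optimization

The tuning of W and M is greedy coordinate ascent: position sweeps
perturb one W_j at a time by ±0.1 (floored at 0), matrix sweeps perturb
one symmetric entry M[a,b] by ±1.0; a step is kept on first improvement
of the seeded, stratified cross-validated AUC of an L2 logistic
regression on the embedded vectors, with ΔAUC < 1e−6 counted as no
improvement. After each full round the inverse regularization strength
C rises by 0.1 (start 1.0); the loop stops when a round accepts no step,
with a hard cap of 50 rounds. Fold assignment is fixed by the seed for
the whole run so every AUC comparison is paired, and the accepted-state
AUC trace is non-decreasing by construction. Sweep ranges can be
restricted in the configuration, which keeps exhaustive sweeps out of
routine test runs. The sweep order (positions by index, then pairs
alphabetically) and the step sizes are this package's own choices; only
the alternate-and-raise-C schedule and the keep-if-AUC-improves rule
are inherited from the method family.

### A transductive caveat

Because the embedding is defined *relative to the positive set*, fixing
one reference set across cross-validation folds leaks information:
held-out positives share the sampling fluctuations of the reference
they belong to, and on a motif-free dataset a classifier reaches CV AUC
≈ 0.77 instead of 0.5. Leave-self-out removes only the first-order
self-match, not this population-level effect.
`embedding.fold_aware_cv_auc` therefore rebuilds the reference from the
training-fold positives only and embeds both partitions against it;
this is the estimator to use when an unbiased performance number is
needed, and it returns ≈ 0.5 on null data. The headline pipeline keeps
the fixed-reference design of the method family (on strongly
motif-bearing data the genuine signal dominates), but reported CV AUCs
from that path should be read as partly transductive.

## The classifier

Four layers, 300 → 64 → 16 → 1. Hidden activations are the identity
("linear unit"), the output neuron is a sigmoid, so the pre-sigmoid
output is affine in the features and the network is a factored,
dropout-regularized logistic regression — the tests assert its CV AUC
matches a directly fit ridge logistic regression within 0.02. Training:
binary cross-entropy, Adam at learning rate 1e−3, mini-batches of 256,
dropout 0.2 on hidden activations (training only; prediction is
deterministic), at most 300 epochs with early stopping on a seeded 10%
stratified validation split (patience 10, best weights restored).
Features are standardized with statistics frozen into the model. Hidden
sizes, dropout and optimizer settings are package defaults, overridable
in `TrainConfig`; all randomness flows from one integer seed.

Score cutoffs High/Medium/Low are anchored at specificities 95/90/85%
on a sample of negative scores: the cutoff is the smallest candidate
score with at least the target fraction of negatives strictly below it
(candidates are the observed scores plus a value just above the
maximum), so the achieved specificity is never below the target. Ties
at a cutoff count as predicted positive. Cross-validated performance is
reported both as the pooled AUC over concatenated held-out scores
(headline) and the mean of per-fold AUCs.

## Functional fine-tuning

The functional model starts from the pre-trained weights and runs
first-order MAML. Per meta-iteration: sample 5 negatives per functional
positive from the secondary pool (known sites not annotated
functional), split into 5 stratified fold-tasks, adapt a copy of the
weights on the training folds (10 full-batch gradient steps at rate
0.05), evaluate AUC and take the gradient on the held-out fold at the
adapted weights, and apply the fold-averaged held-out gradient through
an Adam meta-update (rate 0.01). The mean held-out AUC is tracked;
iteration stops after 15 iterations without improvement beyond 1e−4, or
at 150 iterations. The best-AUC meta-weights are then adapted once on a
full support task (all positives plus one 5:1 negative sample) — the
meta-learned weights are an initialization and are not meant to be used
unadapted; without this deployment step the returned model
under-performs its own recorded task-adapted CV AUC. A configuration
with zero meta-iterations returns the base weights unchanged.

The inner/outer rates and iteration budget are this package's choices,
set so that a linear model can actually traverse the distance from the
general-site solution to the functional-site solution on ~78-sample
tasks; the 5:1 sampling ratio and the 5-fold task structure are part of
the method definition. Whether each resample or each fold is "a task"
was open; fold-tasks within each resample were chosen so every
meta-update sees five held-out gradients.

## Evaluation statistics

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total, and the Matthews
correlation; a zero MCC denominator is reported as 0 with an explicit
flag. ROC/AUC uses the trapezoid over all distinct cutoffs and equals
the tie-corrected Mann-Whitney statistic; the tests pin this against a
brute-force pairwise oracle.

Hypergeometric enrichment: E-ratio = (m/M)/(n/N) over entities
annotated by at least one term (unannotated entities never enter N or
M); the p-value is the upper-tail sum from m when E-ratio ≥ 1 and the
lower-tail sum to m otherwise, evaluated through scipy's hypergeometric
distribution (the tests verify it against exact rational enumeration
for N ≤ 60). No ontology-graph propagation is applied, and no
multiple-testing correction is applied by default; a clearly labeled
Benjamini-Hochberg column is available as an extension.

## Propionylome post-processing

Modified peptides are located by exact substring search (no Ile/Leu
folding — upstream search engines already resolved the sequences); all
matches are returned and flagged ambiguous when more than one exists,
and unmatched peptides go to a report rather than being dropped. The
daily fold change of a site is max/min intensity over the wild-type
time points; any zero or missing intensity makes it undefined (not
infinite) and the site is excluded from cycling counts. Cycling sites
exceed FC 1.5 strictly; the clock-mutant effect is the larger of the
WT/mutant and mutant/WT ratios, maximized over matched time points,
with a strict 1.2 threshold. The diagnostic-ion mass is
K residue (128.09496 Da) + modification delta − immonium offset
(26.98708) − NH3 (17.02655), giving 140.1075 for propionyl
(Δ 56.02621) and 126.0919 for acetyl (Δ 42.01057) at 4 decimals; the
constants are Unimod monoisotopic values and omit the electron mass,
matching how these ions are conventionally quoted.

## The synthetic-data generator

The generator emulates the *structure* of a propionylation benchmark,
not fly biology: by default 890 uniform-random proteins (lengths
150–450) carrying 1707 positive lysines spread over all proteins (one
per protein first, the remainder at random), with a general motif
planted around positives — G at +2 and K at +7/+8, each with
probability 0.85 — and a disjoint upstream motif (F/W/Y at −5..−3,
probability 0.9) on a 13-site functional subset. The plant
probabilities are deliberately strong: they encode a pronounced
over-representation on a uniform background so that recovery is a
property of the method, not of a marginal signal; plant probability 0
gives an exactly null dataset. Intensity tables oscillate as
fc^(cos/2) around a log-normal baseline so the peak/trough ratio is
exactly the configured fold change at zero noise, the clock-mutant
series divides the matched CT6 intensity by the configured effect, and
multiplicative log-normal noise is applied per measurement. Everything
derives from one seed through a single generator in a documented draw
order, so equal configurations are byte-identical.

What passing tests on this generator show: the embedding + classifier
recover a planted positional preference of realistic shape, the
fine-tuning recovers a small-sample signal the pre-trained model
ignores, and the filters recover known fold changes. What they do not
show: performance on real propionylomes, whose motif strength,
compositional bias, homology structure and intensity noise are not
modeled — real sites share no generative process with this simulation,
and uniform background frequencies understate the redundancy of real
proteomes.

## Problem sizes and numerical notes

The default study (≈15,800 windows after negative enumeration) embeds
in under a second and completes 10-fold cross-validation in well under
a minute on one CPU; the acceptance script's full run is about one
minute. Degenerate inputs are handled explicitly: single-class training
data, windows not centered on lysine, non-alphabet characters (named
with their position), fold changes with missing intensities, and MCC
with empty margins all raise or flag rather than returning silent
numbers. Score ties at cutoffs resolve positive; AUC ties get half
credit; threshold calibration needs at least 20 negatives to resolve
the 95% anchor.

## Known limitations

Exact-duplicate redundancy clearance only; the transductive caveat
above for fixed-reference CV numbers; greedy first-improvement tuning
explores a narrow neighborhood of BLOSUM62 and is quadratic in sweep
size; first-order MAML ignores second-derivative terms; the serialized
models are study artifacts, not distributable predictors trained on
real propionylation data.
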