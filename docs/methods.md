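# Methods

## Target-specific gene signatures

Each target (a gene whose perturbation — knockdown, knockout,
over-expression or a selective compound — has been profiled) is represented
by a consensus differential-expression profile over the gene universe shared
by its replicates (intersection rule; genes missing in any replicate are
dropped and counted in the log).  The consensus is a weighted average with
weights from the pairwise Spearman correlation matrix of the replicates:
weight_i ∝ Σ_{j≠i} max(ρ_ij, 0.01), normalized to sum to one.  The clip
floor (0.01) keeps anticorrelated or uncorrelated replicates from receiving
negative or zero weight while still down-weighting them; a single replicate
gets weight 1, and two replicates always split evenly because the 2×2
correlation matrix is symmetric.  Over-expression replicates are aggregated
as given; a per-type sign flip is exposed as an option but not applied by
default, since the appropriate convention depends on how the upstream
differential statistics were computed.

The target's signature is the pair (t_up, t_down) of the n largest and n
smallest consensus values (stable sort; ties break by input gene order).
At full library scale n = 350 is the conventional default.  When chosen
from data, n is selected by the decrease rate (DR): over a size grid
(default 100..1000 step 50) the mean absolute connectivity score m(n) of
all profiles-as-queries against all signatures is computed, DR(n_i) =
|m(n_{i+1}) − m(n_i)| / m(n_i), and the smallest size with DR ≤ 0.01 is
taken (falling back, with a warning, to the largest size on the grid).  The
absolute value is used so that a shrinking score sequence yields a positive
rate.

## Connectivity scoring

A query is a gene list ranked descending by any differential metric
(signal-to-noise, fold change, ...).  For a gene set S the enrichment score
ES is the signed extremum of largest magnitude of a running sum that gains
1/|S∩L| at each member of S and loses 1/(G−|S∩L|) elsewhere (G = query
length).  This is the unweighted, rank-only dialect: it depends only on the
ranking, not the metric values, which makes the permutation null exact and
metric-scale-free.  A metric-weighted variant (exponent 1) is available
behind a flag.  Exact magnitude ties between the positive and negative
extremum resolve to the positive one, with a 1e-12 tolerance absorbing
float rounding in symmetric hit patterns.

The effect target score is ETS = (ES_up − ES_down)/2, zeroed when both
sides enrich with the same sign: a coherent match requires the up set near
one end of the list and the down set near the other, and a same-sign pair
carries no direction.  Signature genes absent from the query are dropped
per side (coverage below 50% is logged; a side with no overlap contributes
ES = 0 and is flagged low-coverage).

### Permutation null, p, NETS

The null permutes the query's gene labels — equivalently, the matched
signature genes are placed at uniformly random distinct ranks — 1000 times
by default.  One generator seeded per query is advanced across targets, so
a single seed reproduces a whole result table.  The nominal p compares the
actual score with the *strictly* same-sign portion of its null: the zero
rule gives the null an atom at 0, and zero scores carry no direction, so
they belong to neither portion.  Among targets with a nonzero score this
makes p exactly uniform under a random query (verified by the calibration
suite); a zero actual score gets the conventional p = 1.  The floor
p ≥ 1/(same-sign count) prevents p = 0 from finite permutations.

NETS divides ETS by the absolute mean of the same-sign null portion,
preserving the sign (positive: the query moves the target's program the
same way the perturbation does; negative: opposite).  Normalization makes
scores comparable across signature sizes and queries.

### Pooled FDR

For each NETS the raw estimate is A/B: A the tail frequency of the value in
the pooled null NETS (all signatures × all permutations, each target's null
normalized by its own sign-portion means), B its tail frequency among the
actual NETS, both within the matching sign.  The reported FDR is the
minimum of A/B over all same-sign thresholds of magnitude up to the score's
own (every such threshold calls the score), a q-value-style monotonization
that makes FDR non-increasing in |NETS| while agreeing with the raw ratio
at each threshold.  Values are clipped to [0, 1]; NETS = 0 gets FDR 1 by
convention.  The null is pooled across all targets, not per target: this
borrows strength across the library and is what makes the A/B ratio an FDR
rather than a per-target p-value.

## Binding prediction

The classifier reads each compound–protein pair as two character strings.
Character-level tokenizers over a fixed SMILES vocabulary and the 20
amino acids + X (pad and unknown indices; inputs truncated at 100 / 1000
characters) define the normalized strings; each branch is then featurized
by character n-gram counts (n = 2, 3), concatenated, and fed to a
multilayer perceptron (two hidden layers, 128/64) trained with binary
cross-entropy (Adam, learning rate 0.0008, batch size 256 — the full-scale
reference settings; the desk-scale default is 30 epochs, with 100 available
via configuration).  N-gram counting with an MLP decoder was chosen over a
convolutional encoder because it captures the same local-substructure
signal at a fraction of the training cost on CPU, and it cleanly learns
conjunctive rules ("fragment X in the compound AND motif Y in the
protein") of the kind the synthetic benchmark plants.  Training holds out
10% validation + 10% test by pair (seeded); the model records its per-epoch
loss curve and held-out AUROC/AUPR.  Interaction databases list positives
only, so negatives are sampled uniformly from unobserved pairs at 1:1 with
positives (seeded) when the caller supplies none.

Pairs with score ≥ 0.90 are called binding targets; a multi-component
preparation's binding-target set is the union over its components.

## Target algebra

Effect targets: FDR ≤ 0.05 (inclusive).  Reversal (therapeutic) targets:
significant in both the drug and the disease run with strictly opposite
NETS signs — a zero NETS on either side excludes the target, and
significance is required on both sides.  Direct = effect ∩ binding;
indirect = effect \ binding; the two partition the effect set.  The
compound–direct-target network is the bipartite graph of binding calls
restricted to direct targets; compounds rank by degree (ties broken
lexicographically), and "strong" targets are those with |NETS| ≥ 4.

## Over-representation analysis

Each gene set is tested with the hypergeometric upper tail P(X ≥ k) for
overlap k between the query (size m) and the set (size K) in a universe of
N genes; Benjamini–Hochberg adjustment runs across all tested sets.  The
universe is the collection's declared universe (intersected with a
user-supplied universe file when given); query genes outside it are dropped
and logged before m is fixed, so genes absent from both query and sets do
not dilute the test.  Sets with fewer than 5 or more than 2000 effective
members are skipped (configurable).  Significant pathways are annotated
with which overlapping members are direct versus indirect targets; the
annotation never alters the test statistics.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
any particular platform.  Defaults (the benchmark's study conditions):
2000 genes, 50 targets, 5 replicates per target, signature size 20, effect
size 3 in noise-SD units, unit Gaussian noise, 1000 permutations.  Each
target owns disjoint up/down blocks of n genes (an overlapping mode exists
for stressing the pooled FDR and for libraries too large for disjointness,
e.g. the 500-target calibration library); replicates put ±effect on block
genes plus noise everywhere.  Queries sum signed block effects over their
active targets plus noise; the negation of a query is its exact reversal
partner.  Binding data use a small SMILES fragment grammar and random
amino-acid sequences with a planted conjunctive motif rule (label noise
1%, class balance near 0.5).  Gene sets either draw a controlled fraction
of members from one target's blocks or are fully random; a separate
generator produces sets over the *target* identifiers for pathway-mapping
runs, since in real data the scored targets are themselves genes but the
simulation keeps target labels distinct from its gene universe.  All
randomness flows from one master seed through named substreams, so each
piece regenerates independently.

What passing the synthetic benchmark does **not** show: real perturbation
profiles have correlated noise, off-target effects, heavy-tailed metrics
and shared biology between targets; real SMILES have chemistry the fragment
grammar ignores; and the binding rule in nature is not a two-motif
conjunction.  The benchmark validates the statistics and the plumbing, not
biological accuracy.

## Numerical and design notes

- Problem sizes in the test suite (500-target calibration library, 10,000
  stress pairs, 2000 binding pairs) were chosen to give stable statistics
  at interactive runtimes; the calibration check pools six independent
  noise queries so the empirical KS distance is measured to ±0.03.
- p-values, NETS and FDR are deterministic given the query, library and
  seed; pipeline reruns with the same manifest are byte-identical.
- Degenerate inputs: empty signature lists, single-class training labels,
  constant NETS vectors, queries disjoint from the library or the universe
  all raise immediately with a named cause rather than propagating NaNs.
- Known limitations: no gene-identifier mapping (callers align name
  spaces); no SMILES canonicalization beyond whitespace/case cleanup; the
  binding model is a desk-scale classifier, not a replacement for a
  docking- or deep-learning-scale predictor; FDR pooling assumes the
  library's signatures are exchangeable under the null, which breaks if a
  few signatures dominate the pooled tail.
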