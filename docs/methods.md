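# Methods

## Anchor-gene scoring

The consistency index of a gene is a pairwise rank statistic: over all
C(N, 2) unordered patient pairs, the fraction whose expression difference
has the same sign as their response-grade difference. Pairs tied in either
expression or grade contribute to the denominator but never to the
numerator; C_g therefore penalises ties and satisfies
C_g(x) + C_g(−x) ≤ 1 with equality exactly when no pair is tied. Because
only signs of differences enter, C_g is invariant under strictly
increasing transforms of either input on untied pairs — in particular the
choice between TPM and log2(TPM + 1) only matters through tie frequency,
and the readers let the caller state the scale explicitly.

Anchors are genes with C_g **strictly** above the threshold (default 0.6,
the conventional acceptability bar for prognostic concordance, applied
here to keep the anchor criterion aligned with the downstream evaluation
metric). Anti-consistent genes (C_g near 0) are not selected by default;
`two_sided=True` adds genes with C_g < 1 − threshold for sensitivity
analyses. An empty anchor set is a warning, not an error: downstream
stages refuse empty seed sets themselves.

## Interaction graph

Edges come from a STRING-layout scored edge list; combined_score ≥ 700 is
read inclusively (STRING's "high confidence" convention). The two
orientations of an undirected edge are collapsed keeping the larger score.
Adjacency is binarised: the paper-of-record algorithms for both ranking
strategies are defined on unweighted graphs, and edge-confidence weighting
is exposed nowhere (rankings proved insensitive in exploratory runs, and a
single convention keeps the oracle tests exact). All connected components
are retained; diffusion acts independently within each component, so
dropping small components would only silently remove genes.

The virtual phenotype node exists only in the augmented graph used by the
embedding strategy; heat diffusion runs on the plain gene–gene graph. Node
identity is the gene symbol throughout — mapping STRING protein IDs to
symbols is deliberately left to the caller.

## Heat diffusion

d = exp(−Lt)·h with L = D − A and h the anchor indicator. The matrix
exponential is applied as an action on h
(`scipy.sparse.linalg.expm_multiply`), never materialised, so graphs with
tens of thousands of nodes are fine. t defaults to 0.1, the common default
of network-propagation tools; smaller t keeps heat near the anchors,
larger t spreads it toward the component-wise mean (the t → ∞ limit).
Heat is conserved (Σd = Σh, tested to 1e−9 at n = 500) and non-negative
for non-negative queries. `query_mode="normalized"` divides h by the
anchor count; since the kernel is linear this changes reported magnitudes
but never the ranking, and the default is the plain indicator ("unit").
Accuracy is contract-tested against an independent 30-term Taylor series
to 1e−10 and against the closed form on the two-node graph to 1e−12.

## Node embedding

Walk generation follows DeepWalk: per node, 100 uniform random walks of 6
nodes each (start node included), start nodes in sorted order so the
corpus is deterministic given the seed. The skip-gram negative-sampling
trainer is implemented in-package as a compact numba kernel (the classic
per-pair sequential SGD): window 4 with all offsets used symmetrically,
10 negatives per positive drawn from the unigram^0.75 distribution,
vectors of 256 dimensions, learning rate decaying linearly from 0.03 to
0.0007 across 50 epochs. Training is single-threaded and bit-reproducible
given the seed — a deliberate slower-but-reproducible default. Genes are
ranked by cosine similarity of their input vector to the virtual node's
(cosine is the convention for skip-gram vectors); zero-norm vectors score
−1 with a warning. On a planted two-clique graph the anchored clique's
mean similarity exceeds the other clique's in 10/10 seeds.

All ranked lists share one contract: descending score, ties broken
lexicographically by gene symbol, ranks consecutive from 1.

## Greedy signature selection

The candidate pool is the top k = 150 of the ranked list (k is a plain
configurable count) intersected with the training matrix, rank order
preserved. Each iteration sweeps the pool in rank order while growing a
working set from scratch: a candidate is *helpful* and kept when adding it
strictly raises the 10-fold cross-validated C-index of the working set
(ΔC = 0 is hindering, which encourages parsimony; a Cox failure on a
candidate marks it hindering with a warning). The empty working set scores
the 0.5 coin-flip baseline. Survivors become the next iteration's pool;
the procedure stops when the pool size is unchanged, provably within
|pool| iterations since the pool never grows.

CV folds are event-stratified (stabilises Cox fits in small folds) and are
**redrawn each iteration** from a seed derived deterministically from the
run seed and the iteration index. This is the one genuinely open design
point, and the redraw is load-bearing: with folds frozen for the whole
run, the second sweep replays the first sweep's evaluations verbatim
(identical folds, identical growing prefixes restricted to the kept
genes), so every survivor is re-labelled helpful and the fixed point is
always reached after two iterations with no further reduction. Fresh folds
make a gene's label a replication test, which is what progressively prunes
candidates that only helped by chance. Runs remain bit-reproducible given
the seed.

An empty fixed point raises a dedicated error advising a larger pool or a
lower anchor threshold. Note a statistical limitation: candidates whose
expression is correlated with outcome *in the dataset at hand* — including
chance correlations among pure-noise genes (the most extreme of ~20 noise
genes at n = 300 reaches a concordance of ~0.55) — survive any
within-dataset cross-validation protocol, so a handful of such genes can
persist in the fixed point; only an independent cohort can remove them.

## Survival evaluation

The Cox partial likelihood is maximised by a small in-package
Newton–Raphson solver with step-halving and the Efron tie approximation; a
fully vectorised fast path covers distinct event times. The solver exists
because greedy selection evaluates thousands of small models per run; it
is cross-checked against lifelines to 1e−4 on coefficients and standard
errors (distinct and tied times). Zero-variance genes are dropped before
fitting with a warning. Risk scores are the linear predictor Σ β_g x_g.

The concordance index follows Harrell's valid-pair rules: a pair is
comparable when the times differ and the shorter time's sample had the
event; tied scores count in M but not in K, consistent with the
strict-sign convention of the consistency index. An O(n log n) Fenwick
tree path handles large cohorts and is equality-tested against the O(n²)
path. Stratification splits at the cohort median with strict > (exact
median samples fall to low risk); the hazard ratio is exp(β) from a
univariate Cox fit on the group indicator with a Wald 95% CI, the
log-rank test is the unweighted two-group statistic, and Kaplan–Meier
curves come from lifelines. A group with zero events makes the HR
non-estimable while KM and log-rank are still reported. k-fold CV is
event-stratified, deterministic by seed, and partitions every sample into
exactly one test fold; folds without comparable pairs are skipped with a
warning.

## Synthetic data

The generators define the study conditions for all tests:

- **PPI graph** — Barabási–Albert preferential attachment (m = 2, n = 300
  by default) with integer edge scores drawn uniformly in [700, 999]; a
  planted module of 10 genes is wired as a clique, and anchors plus
  signature genes live inside it so ranking recovery has a known positive
  set.
- **Immunotherapy cohort** — grades uniform over {1..4} (n = 200),
  planted anchors express `effect·grade + N(0, noise_sd)` with
  effect = 1.0 and noise_sd = 0.1, all other genes N(0, 1); the matrix is
  shifted non-negative and tagged log2-scale.
- **Survival cohort** — expression standard normal; event times
  Exponential with rate λ₀·exp(βᵀx), λ₀ = 0.1 (the simplest baseline
  hazard consistent with proportional hazards), censoring by an
  independent Exponential clock with rate 0.05 (≈ one third censored at
  the default signal strength, a realistic fraction for cohort studies);
  fewer than 10% events is rejected as a parameterisation error. The
  end-to-end benchmark uses a three-gene signature with β = 1 each and
  n = 400 train / 400 test.

What these generators do **not** emulate: RNA-seq count noise (negative
binomial dispersion), batch structure, correlated co-expression outside
the planted module, molecular subtypes, and non-proportional hazards.
Passing tests therefore demonstrate algorithmic correctness and
recoverability of planted signal under clean conditions, not performance
on real cohorts.

## Problem sizes and numerical choices

Test and benchmark sizes (200–1000 samples, 150–300 genes, 10 seeds per
stochastic claim, a 10⁵-sample draw for the asymptotic concordance
reference) were chosen so the full suite settles the stated tolerances
comfortably on a single CPU. Newton iterations stop at a 1e−8 step norm;
the information matrix carries a 1e−9 ridge jitter purely for numerical
safety; diffusion accuracy is bounded by `expm_multiply`, tested at
1e−10. Tie-breaks everywhere are lexicographic by gene symbol, which
makes every ranking and clustering deterministic.

## ssGSEA co-occurrence

Per sample, genes are ranked by descending expression (stable sort; the
rank statistic is G for the top gene down to 1) and the enrichment score
is the summed running difference between the weighted in-set ECDF
(weights = rank^α, α = 0.25, normalised over the set) and the uniform
out-of-set ECDF — the integrated form of the single-sample enrichment
statistic. Scores are not normalised across samples by default: Pearson
correlation, which defines co-occurrence, is location/scale invariant, so
the common normalisation variants change nothing downstream. Signature
co-occurrence is the Pearson correlation of score profiles; clustering is
average-linkage agglomeration on the distance 1 − r (not 1 − |r|:
anti-correlated signatures are functionally distinct), cut to k clusters
(default 3). The implementation agrees with gseapy's ssGSEA ES to 1e−6 on
shared conventions and with a hand-stepped recurrence exactly.

## Known limitations

- The greedy fixed point is defined relative to the training cohort;
  dataset-level chance associations can contribute a few extra genes (see
  above) and shrink only with independent validation data.
- The embedding trainer targets walk corpora over graphs up to a few
  thousand nodes; genome-scale graphs are better served by the heat
  diffusion strategy, which is linear-algebraic and scales with sparsity.
- Batch correction across cohorts and protein-ID mapping are out of
  scope by design; inputs are assumed harmonized and symbol-keyed.
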