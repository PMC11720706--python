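# nbt — network-based transfer of immunotherapy response into prognostic gene signatures

Tumor-intrinsic programs that drive response to immune checkpoint inhibition
are shared across cancers, and the ordinal response grade (mRECIST:
CR > PR > SD > PD) carries prognostic information that a single-cancer
survival cohort cannot provide on its own. `nbt` implements a
network-based transfer pipeline that converts pan-cancer immunotherapy
response labels into a prognostic gene signature for a survival cohort:

1. **Anchor genes.** Each gene g is scored against the digital response
   scale (CR = 4, PR = 3, SD = 2, PD = 1) by a pairwise consistency index

   C_g = #{ pairs (i, j) : (g_i − g_j)(r_i − r_j) > 0 } / C(N, 2),

   the fraction of patient pairs in which the expression difference and the
   response-grade difference share a sign (tied pairs count in the
   denominator only). Genes with C_g > 0.6 are *anchor genes*.
2. **Network ranking.** Anchors are mapped onto a high-confidence STRING
   protein–protein interaction graph (combined_score ≥ 700) and the rest of
   the genome is ranked by phenotype relevance with either strategy:
   *heat diffusion* d = exp(−Lt)·h over the graph Laplacian L = D − A
   (t = 0.1), seeded with the anchor indicator h; or *node embedding*,
   where a virtual phenotype node wired to all anchors joins DeepWalk-style
   random walks (100 walks × 6 nodes per node) feeding a skip-gram
   negative-sampling trainer (256 dims, window 4, 10 negatives, learning
   rate 0.03 → 0.0007 over 50 epochs), and genes are ranked by cosine
   similarity to the virtual node.
3. **Greedy signature selection.** The top-150 ranked candidates are swept
   in rank order; a gene is *helpful* (kept) if adding it raises the
   10-fold cross-validated Harrell C-index of a Cox model over the working
   set, *hindering* otherwise. Survivors form the next sweep's pool; the
   fixed point is the signature (netHD from heat diffusion, netNE from
   embedding).
4. **Evaluation.** Multivariable Cox risk model, C-index = K/M over
   censoring-valid pairs, median-split risk groups with hazard ratio,
   Kaplan–Meier curves and the log-rank test, and event-stratified k-fold
   cross-validation.

A first-class synthetic module generates all three inputs with planted
ground truth — a scale-free PPI graph with a planted module, an
immunotherapy cohort whose anchors vary monotonically with the grade, and
survival cohorts with an exponential proportional-hazards law — so the
whole pipeline is testable end-to-end without any external download.

The package is for computational biologists building transfer-based
prognostic models and for methodologists who need the individual pieces
(consistency index, network propagation, greedy survival feature
selection) with exact, brute-force-verified semantics.

## Worked example

```bash
nbt simulate --out-dir demo --seed 0 --n-genes 300
nbt anchors --expr demo/immuno_expr.tsv --clinical demo/immuno_clinical.tsv \
    --out demo/anchors.tsv
nbt rank --method heat --ppi demo/ppi.tsv --anchors demo/anchors.tsv \
    --out demo/ranked.tsv
nbt select --ranked demo/ranked.tsv --expr demo/train_expr.tsv \
    --clinical demo/train_clinical.tsv --seed 0 --out demo/netHD.gmt
nbt evaluate --signature demo/netHD.gmt \
    --train-expr demo/train_expr.tsv --train-clinical demo/train_clinical.tsv \
    --test-expr demo/test_expr.tsv --test-clinical demo/test_clinical.tsv \
    --out demo/report.json
```

The same pipeline through the library API (seed 1) prints:

```
anchor_recall          1.0      # all 5 planted anchors found at C_g > 0.6
netHD_signature_size   5        # 150 candidates reduced to 5 genes
netHD_train_cv_c_index 0.810    # 10-fold CV concordance on the training cohort
netHD_heldout_c_index  0.828    # concordance on the untouched test cohort
netHD_hazard_ratio     7.03     # high- vs low-risk group (median split)
netHD_logrank_p        2.0e-46  # the two risk groups separate decisively
netNE_heldout_c_index  0.831    # embedding strategy performs on par
```

A held-out C-index of ~0.83 against a planted three-gene hazard (β = 1
each) means the selection recovered the planted signal; anything above the
usual 0.6 acceptability bar for prognostic models indicates useful risk
discrimination.

## Scope notes

Cross-cohort batch correction (e.g. ComBat) is deliberately out of scope:
the pipeline assumes one harmonized cohort per invocation. Mapping STRING
protein identifiers to gene symbols is the caller's responsibility.
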