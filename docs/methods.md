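# Methods

This note documents the models implemented by mccrewire, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish about real data.

## Marker-anchored signature

Given a cohort expression matrix (log2 scale) and a marker panel, every
gene is scored by the arithmetic mean of its Pearson correlations with the
panel genes across all samples. Defaults: the 8-gene neuroendocrine panel
(ENO2, NEFM, NEFH, NMB, HES6, SOX2, ATOH1, CHGA) and 500 genes per tail.

Choices made here:

- **Samples pooled.** Correlations use tumor and normal samples together;
  pooling maximizes the dynamic range the marker panel spans. A `samples`
  argument restricts to tumor-only when wanted.
- **Markers excluded from the ranking.** A marker trivially correlates with
  itself; including the panel would burn 8 of the top slots on tautologies.
- **Ties.** Ranking sorts on (score descending, gene ascending); the down
  tail is the tail of the same ordering. This makes the signature a pure
  function of the score table, independent of input order.
- Zero-variance genes receive a missing score and never enter a tail.

## Reversal screening

Per drug, the log2FC vector is z-scored across genes (sample sd), the 1000
genes of largest |z| are selected, and split by the raw log2FC sign. The
reversal-concordant count `a` adds |drug-down ∩ signature-up| and
|drug-up ∩ signature-down|; the 2×2 table is completed from the selected
and signature set sizes against the universe, tested with the one-sided
(enrichment) Fisher exact test, BH-adjusted across the screened drugs, and
ranked by adjusted p (ties: descending odds ratio, then name).

- The direction-aware count is the default because "reversal" is a signed
  hypothesis; `direction_aware=False` gives the overlap-only variant for
  sensitivity analysis, and `alternative="two-sided"` the two-sided test.
- The universe defaults, per drug, to the intersection of the signature's
  score table with the drug's profile: genes absent from either cannot be
  selected and would only inflate the null.
- Odds ratios use the Haldane–Anscombe 0.5 correction only when a cell is
  zero, so ordinary tables are reported uncorrected.
- "Top 1000" counts both directions together (the selection is on |z|);
  per-direction counting would be a trivial variant via two calls with the
  appropriate k.

## Signed coexpression core

Adjacency `a_ij = ((1 + r_ij)/2)^β` (β = 16 by default, scanned by
`soft_threshold_scan` over a grid that includes 16 with a log-log
histogram regression of the connectivity distribution), topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with unit diagonal, and average-linkage hierarchical clustering on
1 − TOM.

- **Initial cut.** The dendrogram is cut statically at the height that
  maximizes the number of clusters of at least `min_size` (30) genes; among
  tying heights the largest is used so each surviving cluster is fully
  agglomerated before two clusters of acceptable size would fuse. A fixed
  `cut_height` can be supplied instead. This replaces the dynamic tree-cut
  heuristic: only the minimum size and the merge height are structural
  parameters here, and planted-block recovery is preserved.
- Clusters below 30 genes stay unassigned (label 0). Module eigengenes are
  the first principal component of the module's genes standardized across
  samples (unit norm, sign-oriented to correlate nonnegatively with the
  module mean profile). Modules whose eigengene dissimilarity 1 − r falls
  below the merge height 0.25 are merged iteratively, closest pair first;
  merging is idempotent.
- Hub score = summed TOM edge weight (row sum minus the diagonal); 40 hubs
  per module. Among edges between retained hubs, exactly the
  ⌈(1 − 0.8)·E⌉ heaviest are kept (ties at the threshold are all included).
- Zero-variance genes are dropped before network construction with a
  logged list; Pearson is undefined for them.

## Regulatory-network arm

**Inference.** The TF × gene weight matrix W starts from the z-scored motif
prior and is refined by damped message passing,
`W ← (1−α)W + α·(T(P, W) + T(W, C))/2` with α = 0.1, where P is the TF–TF
cooperativity (from the interaction matrix), C the gene–gene coexpression,
and T the continuous Tanimoto similarity
`T(X,Y)_ij = (XY)_ij / sqrt(Σ_k X_ik² + Σ_k Y_kj² − |(XY)_ij|)`. P and C
are pulled toward the co-targeting/co-regulation similarity of W with the
same damping and re-z-scored each step. The re-normalization is the fixed
point of the design: the similarity update inflates through its diagonal
(a TF's self-similarity grows with ‖W‖), and holding P and C on the
z-scored scale is the single normalization that keeps the iteration
contractive while preserving the relative message structure. Iteration
stops when max |ΔW| < 1e−3 (or at `max_iter`, with a logged warning and a
`converged: False` tag).

**Single-sample extraction.** For sample q,
`e_q = N·e(all) − (N−1)·e(all∖q)` edgewise. By default the constant matrix
`e(all) − mean_q e_q` is then added to every e_q (`recenter=True`): for any
inference that is linear in the sample set this is exactly zero, and for
nonlinear inference it removes the jackknife bias term so the
decomposition's defining property — single-sample networks average exactly
to the aggregate — holds by construction. `recenter=False` gives the raw
formula.

**Transform and periods.** Edges are made nonnegative with softplus
`w' = ln(1 + e^w)` (monotone, ℝ→ℝ₊) before averaging; `register_transform`
installs alternative published forms. Samples map to five periods
(t1={0,4}h, t2={8,12}, t3={16,20}, t4={24,32}, t5={40,48}) and member
networks are averaged edgewise per (condition, period).

**Differential communities.** The base network is partitioned by greedy
maximization of the bipartite modularity
`Q = (1/m) Σ_ij (A_ij − k_i d_j/m) δ(c_i, c_j)`; the differential
modularity scores the perturbed edges A′ (normalizer m′ = ΣA′) against the
*base* strength-product null. Greedy label moves (fixed node order: TFs
then genes; a node may join any label or open a fresh one; only strict
improvements accepted) run from both the base-partition seed and an
all-singleton seed, and the better optimum is kept (ties keep the
base-seeded one). Base seeding alone cannot carve a newly rewired block out
of the interior of an existing community, while with identical base and
perturbed networks both seeds coincide with the base partition, so nothing
is spuriously "rewired". Per-node contributions are half the node's
in-community summand share (they sum to Q_diff). Communities with more
than 30 nodes — TFs and genes counted together; `count="genes"` restricts —
are retained. No Louvain aggregation phase is used; at the package's
problem sizes the label-move optimum already recovers planted blocks
exactly, and the procedure stays deterministic.

## Shared statistics

- Differential expression is a two-sided Welch t test on log2 expression
  (log2FC = difference of group means), BH-adjusted, thresholded at
  adjusted p ≤ 0.05 and |log2FC| ≥ 1 (the coexpression input variant sets
  the fold-change threshold to 0). The count-level models of DE tools are
  deliberately out of scope: on log-normal synthetic data the Welch test is
  calibrated (type-I error checked at 0.05 ± 0.02 on 2,000 null genes), and
  only the thresholding conventions are structural.
- Enrichment: hypergeometric upper tail, BH across terms, odds ratios with
  the zero-cell-only 0.5 correction. BH is the adjustment behind every
  "adjusted p" in the package.
- Inter-set correlation: all pairwise Pearson r between two disjoint gene
  sets within each sample group (e.g. condition × period), reported as the
  signed matrix and the mean |r|.

## Synthetic data: what it emulates, and what it does not

Generators draw from named seed-derived streams (`default_rng` on
`SeedSequence([seed, stream_id])`), so a single integer seed reproduces
every fixture independently of execution order.

**Time course** (`gen_timecourse`): two conditions (viral induction `ER`
vs `CTRL`), the study grid {0,4,8,12,16,20,24,32,40,48} h, three
replicates — 60 samples. Gene g in block b is
`baseline + λ_g (slope_b(cond)·τ + σ_z z_b(sample)) + ε`, with τ = t/48,
λ ~ U(0.8, 1.2), σ_z = 0.6, ε ~ N(0, 0.3²). Default blocks: `canonical`
(60 genes, slope +2 under ER only), `noncanonical` (60, −2 under ER),
`ne` (50, flat), plus 130 independent noise genes. Expression is emitted
directly on the log2 scale; no count layer, overdispersion, library-size
or batch structure is simulated.

Two realized-draw normalizations make the planted structure exact rather
than merely expected, because six-sample period groups are far too small
for raw Gaussian draws to concentrate:

1. within each (condition, period) group every block factor is standardized
   and made exactly orthogonal to the within-period time contrast;
2. the `ne` factor is rebuilt per period as
   `w·ẑ_canonical + sqrt(1−w²)·ẑ_⊥` with ẑ_⊥ Gram–Schmidt-orthogonalized,
   so the within-period factor correlation equals the planted coupling w
   exactly. Under ER, w ramps as `0.9·sqrt(t̄/48)` — a fast-onset,
   saturating coupling, the shape expected when rewiring begins promptly
   after induction — and stays 0 in the control.

Consequently a passing dynamics test shows the pipeline *detects* a planted
monotone coupling at the study's design size; it does not show such
couplings are detectable at single-period resolution in noisier real data.

**Cohort** (`gen_cohort`): a latent neuroendocrine factor
`h ~ N(2·1[tumor], 1)` drives the 8 markers (loading 1.0, noise sd 0.3)
and 12% positively / 12% negatively loaded genes (loading ±0.8, noise sd
1.0) out of 5000 — an L1000-scale universe, sized so both 500-gene tails
fit inside the loaded sets and the screening 2×2 tables have a proper
null margin. 60 tumor / 40 normal samples by default.

**Perturbagens** (`gen_perturbations`): six profiles named after the
commercially available Wnt perturbagens screened in this disease context;
one (pyrvinium pamoate by default) is the planted reverser, opposing the
signature direction on a configurable fraction (default 0.6) of signature
genes with effect sizes |N(2, 0.5²)| over N(0, 0.2²) background; decoys
perturb 800 genes drawn uniformly with random signs. Real L1000 profiles
have correlated effects, batch structure and dose/time dimensions that are
not modeled.

**Priors, annotation, network pairs**: Bernoulli motif prior (density 0.2),
symmetric U(0,1) interaction matrix with unit diagonal, uniformly drawn
annotation terms with one term planted over a query set, and — for
differential-community truth — a complete-bipartite base with constant
weight (every edge exactly equals its null expectation, so the base carries
no community structure) plus dense added blocks in the perturbed copy.

## Numerical conventions

- Tolerances: TOM and modularity against brute force at 1e−12; the
  single-sample averaging identity at 1e−10; message-passing convergence at
  max |ΔW| < 1e−3 within 300 iterations.
- Tie-breaks are lexicographic by identifier throughout (signature tails,
  top-perturbed selection, hub ranking, screen ranking) and by fixed node
  order in the greedy community moves, making every stage deterministic
  given (config, seed).
- Problem sizes in the test and acceptance runs (hundreds of genes, tens of
  TFs, 60 samples) are the package's desk-scale defaults; all stages are
  dense-matrix implementations chosen for clarity and exactness at these
  sizes, not block-wise scalability beyond ~20k genes.

## Known limitations

- The message-passing inference is a deliberately simplified reimplementation
  (single damping constant, one fixed normalization); it is validated at the
  pipeline level (averaging identity, permutation equivariance, planted
  community recovery), not for numeric parity with any reference
  implementation.
- The static dendrogram cut is a declared substitute for dynamic tree-cut;
  on real data with nested module structure the two can differ.
- The Welch-t DE stand-in ignores count noise; with few replicates on real
  RNA-seq counts a negative-binomial model is preferable.
- GO structure (DAG, term redundancy, evidence codes) is not modeled; the
  enrichment is plain over-representation on flat gene sets.
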