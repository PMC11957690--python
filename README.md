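# mccrewire

Tools for studying how a tumor-defining expression program can be read out,
reversed, and traced back to regulatory-network rewiring — exercised
end-to-end on synthetic transcriptomes with planted ground truth.

The motivating biology is Merkel cell carcinoma (MCC), an aggressive
neuroendocrine skin cancer frequently driven by Merkel cell polyomavirus
(MCPyV). The package implements, as a tested and reusable pipeline, the
in-silico analyses such a study needs:

1. **Marker-anchored disease signature.** Every gene *g* in a tumor/normal
   cohort is scored by the average Pearson correlation with an 8-gene
   neuroendocrine marker panel *M* (ENO2, NEFM, NEFH, NMB, HES6, SOX2,
   ATOH1, CHGA):
   `s(g) = (1/|M|) Σ_{m∈M} r(x_g, x_m)`.
   The 500 highest- and 500 lowest-scoring genes form the two-tail
   signature.
2. **Perturbagen reversal screen.** For each drug profile (per-gene log2
   fold change), the top 1000 genes by |z-scored log2FC| are split into
   drug-up/drug-down sets; the direction-opposed overlap with the signature
   (`a = |drug-down ∩ sig-up| + |drug-up ∩ sig-down|`) is tested with a
   one-sided Fisher exact test, Benjamini–Hochberg adjusted across drugs,
   and ranked.
3. **Signed coexpression modules.** A signed weighted network
   `a_ij = ((1 + r_ij)/2)^β` with β = 16, topological overlap
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
   average-linkage module detection (minimum size 30, eigengene merge
   height 0.25), module-eigengene/trait correlation, 40 hubs per module by
   summed TOM edge weight, and a top-quintile leading-edge filter.
4. **Time-resolved regulatory networks.** Message-passing integration of
   expression, a TF-motif prior, and TF–TF interactions into a bipartite
   TF × gene network; leave-one-out single-sample extraction
   (`e_q = N·e(all) − (N−1)·e(all∖q)`); a softplus edge transform; averaging
   into five time periods (t1=[0,4]h … t5=[40,48]h); and differential
   community detection that maximizes the bipartite modularity of the
   perturbed network against the base network's strength-product null,
   keeping communities of more than 30 nodes.
5. **Shared statistics.** Welch-t differential expression with the study's
   thresholds (adjusted p ≤ 0.05, |log2FC| ≥ 1), hypergeometric set
   enrichment with Haldane–Anscombe-corrected odds ratios, inter-set
   correlation dynamics, and paired log2FC trajectories.

A first-class synthetic-data module generates every input shape with known
planted structure — a two-condition 10-time-point triplicate course, a
marker-anchored cohort, L1000-like drug profiles with one planted reverser,
network priors, annotations, and base/perturbed network pairs — so every
stage has a ground-truth recovery test.

## Worked example

```sh
mccrewire run --workdir demo --seed 7
```

runs both analysis arms on freshly simulated data and prints:

```
simulate: ok (10 outputs, 0.88s)
signature: ok (2 outputs, 0.12s)
  n_per_tail = 500
reversal: ok (3 outputs, 0.12s)
  planted_reverser = pyrvinium-pamoate
  planted_reverser_rank = 1
coexpr: ok (5 outputs, 0.12s)
  n_modules = 3
regnet: ok (26 outputs, 3.08s)
enrich: ok (4 outputs, 0.06s)
```

The screen table (`demo/reversal_screen.tsv`) shows the planted reverser
dominating the five decoys — 615 of its top-1000 perturbed genes oppose the
signature direction versus ~110 expected by chance:

```
perturbagen        a    b    c    d     odds_ratio  p              p_adj          rank
pyrvinium-pamoate  615  385  385  3615  14.999      5.37e-249      3.22e-248      1
mesalazine         110  890  890  3110  0.432       1              1              2
```

`demo/interset_dynamics.tsv` reports the planted coupling dynamic: the mean
absolute correlation between the canonical-Wnt block and the NE block rises
monotonically across the five periods under the viral condition
(0.23 → 0.33 → 0.50 → 0.53 → 0.73) and stays flat (~0.21) in the control —
the coregulation signature of virus-induced rewiring.

The same operations are available as a library:

```python
from mccrewire import synthetic
from mccrewire.signature import marker_correlation_scores, build_signature
from mccrewire.reversal import reversal_screen

cohort, truth = synthetic.gen_cohort(seed=7)
scores = marker_correlation_scores(cohort, list(synthetic.DEFAULT_MARKERS))
signature = build_signature(scores)              # 500 genes per tail
profiles, ptruth = synthetic.gen_perturbations(signature, seed=7)
results = reversal_screen(signature, profiles)   # top 1000 genes per drug
print(results[0].perturbagen, results[0].rank)   # pyrvinium-pamoate 1
```

## Layout

- `src/mccrewire/synthetic.py` — generators with planted ground truth
- `src/mccrewire/signature.py` — marker scoring and two-tail signatures
- `src/mccrewire/reversal.py` — drug reversal screening
- `src/mccrewire/coexpr.py` — signed network / TOM / modules / hubs
- `src/mccrewire/regnet.py` — inference, single-sample networks, communities
- `src/mccrewire/enrichstats.py` — DE, enrichment, dynamics
- `src/mccrewire/config.py`, `pipeline.py`, `cli.py`, `io.py` — orchestration
- `docs/methods.md` — the model and design choices in detail
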