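# phosphodyn

Analysis toolkit for insulin-regulated phosphoproteome screens in
adipocytes — the kind of experiment in which SILAC-labeled cells are
stimulated with insulin over a dense time course (0, 15 s, 30 s, 1, 2, 5,
10, 20, 60 min) and, in parallel, treated with pathway inhibitors (the
Akt inhibitor MK2206 and the PI3K/mTOR inhibitor LY294002), and tens of
thousands of phosphosites are quantified as log₂(condition/basal) ratios.

The package is aimed at computational proteomics practitioners who want
the downstream analysis of such screens as reusable, tested components
rather than spreadsheet folklore:

- **Regulation calling.** A site is insulin-regulated when its median
  log₂ ratio exceeds a global threshold of 2.5 raw median absolute
  deviations (MADs) of the log₂-transformed data:
  `|median(log₂ R)| > 2.5 · MAD`. On typical data (MAD ≈ 0.4 log₂ units)
  this corresponds to roughly a 2-fold change.
- **Inhibitor dependence.** With reversal fraction
  `ρ = 1 − log₂R_inhibitor / log₂R_insulin`, a site is PI3K/mTOR-dependent
  when `ρ_LY > 0.40` and Akt-dependent when additionally `ρ_MK > 0.40`,
  evaluated on class I sites (localization probability > 0.75) quantified
  in every screen arm with a consistent response direction.
- **Temporal clustering.** Profiles are min–max scaled to [0, 1] and
  clustered by fuzzy *c*-means (Bezdek updates,
  `u_ik = 1 / Σ_j (d_ik/d_jk)^{2/(m−1)}`, default *c* = 18, *m* = 2);
  centroids are labeled sustained-increase / transient / decreased by
  shape rules. AUC (trapezoidal, on real time normalized to [0, 1]) and
  an order-2 polynomial fit summarize each profile's kinetics.
- **Motif statistics.** Position-specific scoring matrices (13-residue
  windows, log₂ odds with pseudocounts) and iceLogo-style
  percent-difference enrichment `100·(p_fg − p_bg)` with a two-proportion
  z-test at α = 0.01.
- **Kinase-substrate prediction.** Per-kinase ensembles of RBF-kernel
  SVMs (all curated positives vs independently subsampled 5:1 negatives),
  trained on scaled time courses + kinetic summaries + inhibitor responses
  + PSSM scores. Normalized scores, delta scores
  `Δ_K = s_K − max_{K'≠K} s_{K'}`, and Pareto non-dominated sorting over
  (score, Δ) rank candidate substrates for Akt, mTORC1 and PKA.
- **Abundance & enrichment statistics.** iBAQ-style ranking (summed
  intensity / theoretical tryptic peptides) with quartiles, Fisher's exact
  term enrichment with Benjamini–Hochberg control, and a Wilcoxon
  rank-sum test for abundance shifts.

Because raw screens of this scale are rarely at hand, the
`synthetic_data` module generates full two-screen cohorts with planted
ground truth (regulation fractions, kinase-specific temporal archetypes,
motif-bearing windows, replicate noise, missingness), so every stage of
the pipeline can be exercised and validated end to end.

## Worked example

Run the whole pipeline on a simulated 20,000-site cohort:

```bash
phosphodyn run-all --simulate --seed 7 --out results/
```

```
[simulate] generated 20000 sites
[regulate] 3017 regulated of 19983 quantified (threshold 0.511)
[cluster] clustered 3017 regulated profiles
[motif] 10 significant cells
[predict] scored 19947 sites ({'no_timecourse': 0, 'sparse_timecourse': 0, 'no_inhibitor': 53} excluded)
[run-all] wrote 8 outputs to results/
```

The regulation summary (`results/regulation_summary.json`) reports 1,993
up- and 1,024 down-regulated sites — 15.1% of the quantified cohort,
recovering the planted 15% — with 54.2% of regulated sites blocked by the
PI3K/mTOR inhibitor and 66.2% of those additionally blocked by the Akt
inhibitor. The prediction stage recovers the planted substrates: all 50
top-ranked Akt candidates are true planted Akt sites (Fisher p ≈ 5×10⁻⁸⁸
in `results/prediction_enrichment.tsv`), and the head of
`results/predictions.tsv` shows the (score, delta, Pareto front, rank)
layout:

```
site_id  kinase  score     delta     pareto_front  rank  known_positive
S019551  Akt     1.000000  0.580251  1             1     True
S012378  Akt     0.989386  0.702499  1             2     True
S011664  Akt     0.918747  0.737164  1             3     True
```

Individual stages are also available as subcommands (`simulate`,
`regulate`, `cluster`, `motif`, `predict`, `enrich`), each reading and
writing plain TSV; see `phosphodyn <cmd> --help`.

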