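# Methods

This note documents the models implemented in `phosphodyn`, the
parameter choices that matter, what the synthetic screens do and do not
emulate, and the numerical conventions used at the edges.

## Screens and data model

The package models two SILAC screen designs in insulin-stimulated
adipocytes. The *inhibitor screen* quantifies each phosphosite as
replicate log₂(condition/basal) ratios under three arms: insulin alone,
insulin after Akt inhibition (MK2206), and insulin after PI3K/mTOR
inhibition (LY294002). The *time-course screen* quantifies
log₂(insulin/basal) at 0, 15 s, 30 s, 1, 2, 5, 10, 20 and 60 min. A
site record carries its protein, 1-based position, residue (S/T/Y),
localization probability, peptide multiplicity, and a 13-residue
sequence window centered on the phosphosite ('_'-padded at termini,
MaxQuant convention). Ratios are stored in log₂ throughout; missing
quantification is an absent value, never 0, since 0 is a meaningful
log₂ ratio.

## Regulation calling

One global threshold, 2.5 × raw MAD, is computed from the full insulin
log₂ distribution (regulated and unregulated sites together) and
applied strictly (`>`) to per-site replicate medians. Two conventions
deserve explanation:

- **Raw MAD.** No normal-consistency constant (1.4826) is applied; the
  convention in this literature quotes "k median absolute deviations"
  of the data as-is. The constant is exposed as
  `RegulationConfig.mad_consistency` for users who want the
  normal-consistent estimator.
- **Spread of the measurements, not of the medians**
  (`RegulationConfig.threshold_on = "replicates"`). The threshold is the
  spread of the log₂-transformed data, i.e. the pooled replicate-level
  measurements. Computing it on per-site medians instead (available as
  `threshold_on = "medians"`) produces a systematically tighter
  threshold — the median of n replicates is less dispersed than the
  replicates — and a correspondingly inflated regulated fraction; on
  replicate-level data the null exceedance of the 2.5-MAD rule is small
  and the called fraction tracks the true regulated fraction closely.

Dependence classification uses the reversal fraction
ρ = 1 − log₂R_inh / log₂R_ins (sign-symmetric for down-regulated
sites; undefined when the insulin response is 0, in which case the site
is excluded). PI3K/mTOR dependence requires ρ_LY > 0.40; Akt dependence
additionally requires ρ_MK > 0.40 (Akt sits downstream of PI3K, so
Akt-dependent is defined as a refinement of PI3K-dependent). Reversal is
computed on median replicate log₂ values for robustness; a linear-scale
variant (`reversal_scale = "linear"`) is provided because the choice of
scale is a genuine convention. Classification is restricted to class I
sites (localization probability > 0.75) quantified in at least one
replicate of every screen arm. The record format carries a single shared
insulin arm for both inhibitor screens, so the "same direction in both
screens" filter reduces to requiring a definite direction; the config
flag is retained for data with per-screen insulin arms.

## Temporal analysis

Missing timepoints are linearly interpolated on the real time axis
(clamped at the edges); sites missing more than 3 of 9 points are
excluded from clustering and feature assembly rather than imputed.
Profiles are min–max scaled to [0, 1]; a constant profile carries no
kinetic information and maps to all-0.5 with a degenerate flag. AUC is
the trapezoid over time divided by 60 min, so AUC ∈ [0, 1]; the real
(strongly non-uniform) time axis is used rather than index spacing
because the kinetic claims of interest are about real time. The
quadratic fit is ordinary least squares on time normalized to [0, 1],
coefficients highest-degree first.

Fuzzy c-means is the standard Bezdek alternating scheme under squared
Euclidean distance, defaults c = 18 and m = 2.0 (both configurable; the
fuzzifier and metric are conventions, not derived quantities),
tolerance 10⁻⁶ on the maximum centroid shift, 300 iterations max.
Initial centroids are drawn uniformly inside the per-dimension bounding
box of the data, which makes results deterministic for a fixed seed and
exactly invariant to input row order (random initial memberships would
tie the result to the row ordering). A point coincident with a centroid
receives full membership in it (the standard singularity rule). The
fuzzy objective Σ u^m d² is recorded per iteration and is non-increasing.

Centroid shape rules (on the scaled axis): *sustained increase* — final
value ≥ 60% of the maximum and the post-1-min maximum at least 0.3
above the initial value; *decreased* — final value more than 0.3 below
the initial value; *transient* — peak after t = 0 but before 5 min with
the final value ≤ 40% of the peak; otherwise *other*. Decreased is
tested before transient because a monotone decay also "peaks before
5 min" (at t = 0); requiring an interior peak disambiguates the two.

## Motif statistics

PSSMs are per-position frequencies over the 20 amino acids with an
additive pseudocount of 0.5 per letter (PSSM regularization is a
package choice), log₂ odds against a background — uniform by default,
the residue composition of the full site table in the pipeline.
Window scoring sums the 12 flank cells; the center is excluded (it is
conditioned on being S/T/Y) and pads contribute 0. Enrichment between
two window sets is scored per (position, residue) cell as the percent
difference 100·(p_fg − p_bg), with significance from a two-sided pooled
two-proportion z-test at α = 0.01; zero-variance cells (pooled
proportion 0 or 1) return p = 1. The z-test is a declared approximation
of the iceLogo machinery it mirrors.

## Kinase-substrate prediction

Feature layout (17 + K values per site): 9 scaled timepoints, AUC, 3
polynomial coefficients, mean interpolated log₂ ratio across
timepoints, the 3 inhibitor-screen medians, and one PSSM score per
trained kinase. Sites missing a time course or an entire inhibitor arm
are excluded and counted.

Each kinase's classifier is an ensemble of E = 25 SVMs (RBF kernel,
C = 1, γ = 1/n_features): every member trains on all positives against
a fresh negative subsample at 5:1 negative:positive, drawn without
replacement from sites that are in no kinase's positive set and not
within 13 residues of a positive on the same protein (window-overlap
leakage guard). The ensemble size, ratio, and kernel are configuration,
not inferred from data. The score is the mean decision value, min–max
normalized to [0, 1] over the scored cohort (a degenerate cohort maps
to 0.5 with a warning). Delta scores and per-kinase Pareto
non-dominated sorting over (score, delta) produce the final ranking —
within a front, ties break by descending score then site id. Known
positives are flagged in the output but kept in the ranking.
Cross-validated sensitivity/specificity use the 0.5 normalized-score
operating point with normalization inside each held-out fold.

Pareto sorting is implemented as a sorted sweep (descending score, then
delta, then id) with per-front dominance state, and is validated in the
tests against an O(n²) brute-force oracle.

## Synthetic screens

The generator's defaults are the study conditions the package is
benchmarked under: 20,000 sites; 15% insulin-regulated with a 2:1
up:down split; 55% of the regulated response PI3K-dependent and 67% of
that Akt-dependent; residue frequencies 87.8/11.4/0.8% S/T/Y; 63%
class I; effect sizes |log₂| from a normal(1.5, 0.5) truncated at 1.0;
3 replicates with N(0, 0.25²) log₂ noise; 10% missingness, completely
at random per replicate per condition. The noise magnitude is a
calibration choice (exposed in config): it gives replicate medians a
realistic dispersion relative to the ≥1 log₂-unit planted effects.

Temporal archetypes are noiseless template curves scaled by the signed
effect: fast-sustained 1−e^(−t/0.25 min) (≥95% of plateau by 1 min,
Akt-like), slow-ramp 1−e^(−t/7 min) (plateau between 10 and 60 min,
mTORC1-like), transient e^(−t/8) − e^(−t/0.3) peak-normalized (peaks at
1–2 min, ≤25% of peak by 60 min), decreased = negative fast-sustained,
flat = 0. Up-regulated sites draw archetypes at 0.5/0.3/0.2
fast/transient/slow. Inhibitor arms carry the planted effect times
(1 − reversal), with reversal ~ U(0.6, 1.0) in the arms a site depends
on and U(−0.1, 0.2) otherwise; the insulin arm carries the full effect
regardless of archetype, since the inhibitor screen is a separate
fixed-duration stimulation experiment. Kinase labels are assigned where
dependence and archetype are compatible (Akt: Akt-dependent ∧
fast-sustained; mTORC1: PI3K-only ∧ slow-ramp; PKA: PI3K-independent ∧
fast-sustained), keeping the marginal archetype mix intact;
kinase-labeled sites draw sequence windows from that kinase's motif
model (Akt: R at −5/−3; PKA: R at −3/−2; mTORC1: P at +1), all others
from a uniform-flank background.

What the generator does **not** emulate: peptide-level intensities and
spectra, abundance–regulation correlation, non-Gaussian or
intensity-dependent noise, informative missingness, correlated sites on
one protein, compositional biases of real sequence space, and partial
inhibitor dose-response (reversal is a draw, not a dose curve). Passing
tests therefore demonstrate that the pipeline recovers what was
planted under idealized noise — parameter recovery and internal
consistency — not that it is robust to every pathology of real MS data.

## Problem sizes and determinism

The test suite works on cohorts of 1,200–2,000 sites (5,000–20,000 for
the composition-recovery tests), chosen so the full suite runs in well
under a minute of compute per heavy test while keeping sampling error
comfortably inside the asserted tolerances; `scripts/acceptance.py`
uses 20,000-site cohorts (5,000 for clustering) to match the default
study conditions. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the end-to-end pipeline is bit-for-bit
reproducible for a fixed seed, and the run manifest records the seed,
the effective config and SHA-256 checksums of all inputs and outputs.

## Known limitations

- Multiplicities are kept as separate records (site ids include the
  multiplicity); no collapsing rule is applied.
- The same-direction cross-screen filter is vacuous on single-insulin-arm
  data (see above).
- Fisher/BH, rank-sum and SVM machinery delegate to scipy, statsmodels
  and scikit-learn; fuzzy c-means, PSSM/enrichment scoring, MAD/reversal
  rules, Pareto sorting and the generator are implemented here.
- The shape-label thresholds (0.6/0.3/0.4) are heuristics tuned to the
  scaled [0, 1] axis; centroids of very noisy or low-amplitude clusters
  may fall into *other*.
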