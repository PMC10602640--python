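# Methods

## Scope and data model

The package analyzes genus-level microbial read-count profiles derived
from bulk tumor RNA-seq (taxonomic classification itself — Kraken2 /
Bracken — is upstream and out of scope; their per-sample report files
are the input). A cohort is a samples × genera integer count matrix with
per-genus lineage (kingdom, taxonomy id) joined to per-sample metadata
carrying the binary therapy-response label (pCR / non-pCR) and clinical
covariates (sex, age, grade, cT, cN). Genus identity is keyed by name
(with taxonomy id retained); duplicate names within one report are
summed with a warning.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, plus ground truth for recovery tests.

* **Baseline composition**: genus proportions drawn log-normal
  (σ = 1.5) and normalized — a few dominant genera and a long rare
  tail, the shape typical of tumor-microbiome profiles.
* **Group effect**: the non-responder arm's expected proportions
  multiply the baseline by 2^log2FC for each differential genus, then
  renormalize. Positive log2FC therefore enriches non-responders. The
  realized mean-abundance ratio is 2^lfc shrunk by the renormalization
  factor (for one genus at proportion *p*, ratio = 2^lfc/(1 + (2^lfc−1)p)).
* **Counts**: Dirichlet-multinomial — per sample a composition is drawn
  from Dirichlet(c·p) and counts multinomial at the sample's library
  size; the total mass *c* (default 200) controls overdispersion.
  Library sizes are log-normal (default log-mean 10 ≈ 22k microbial
  reads, log-sd 0.5), the modest depths typical of microbial reads
  recovered from host RNA-seq.
* **Differential genus placement**: drawn from the moderately-abundant
  tier (abundance ranks ~10–150 of 400). Marker-style genera in this
  setting are established commensals with appreciable abundance;
  placing effects in the rare tail would make them statistically
  invisible at any realistic depth, and in the dominant handful would
  distort the whole composition through renormalization.
* **Contaminants**: a set of genera whose absolute counts are Poisson
  with a depth-independent mean (default mean fraction 0.005 of the
  typical library). Their relative abundance is therefore inversely
  proportional to depth — the signature used by the contaminant filter
  — and independent of response group.
* **Non-bacterial genera** (default 2, kingdom Fungi) exercise the
  kingdom filter.
* **Covariates** are independent of the response arm by default, with
  frequencies matching a typical locally-advanced-rectal-cancer cohort
  (≈69% male, median age ~65, predominantly grade 2, cT3); an optional
  `confound_covariate` knob ties sex or age to the arm for
  logistic-regression testing.

Defaults are the study design this package targets: 105 samples, 26/105
(24.8%) responders, 400 genera, 12 differential at log2FC 1.5.

What the generator does **not** emulate: phylogenetic correlation among
genera, per-genus dispersion heterogeneity, batch effects, and the
zero-inflation structure of very shallow samples. Consequently, passing
recovery tests demonstrate the pipeline's correctness and power under a
clean compositional model, not expected performance on real cohorts —
in real data the injected-signal-to-noise ratio is typically lower, and
single-marker AUCs nearer 0.65 than the ~0.85 seen on synthetic
cohorts.

## Preprocessing

* **Bacteria-only retention** drops genera whose kingdom is annotated
  and not Bacteria; unannotated genera are kept.
* **Contaminant filter**: control-based decontamination is impossible
  here (no negative controls or DNA concentrations exist for
  RNA-seq-derived profiles), so a deliberately simplified, documented
  rule is used: (i) prevalence floor — genera present in <5% of samples
  are removed; (ii) depth-correlation score — Spearman ρ between a
  genus's relative abundance and sample depth; ρ ≤ −0.6 with p < 0.05
  flags a contaminant (constant-count contamination shows exactly this
  depth-inverse pattern). Removed genera are reported with scores and
  reasons. The filter is idempotent.
* **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to a common depth — default the minimum
  post-filter sample depth; shallower samples are dropped with a
  warning. Deterministic under a fixed seed.
* **Relative abundance** divides each row by its sum; presence (for
  Jaccard and group genus sets) means count > 0 after rarefaction.

## Diversity

* **Shannon index** H = −Σ p ln p in nats. Group comparison defaults to
  the two-sided Wilcoxon rank-sum (exact null enumeration when tie-free
  and both groups ≤ 25; asymptotic with tie correction otherwise);
  Welch's t is available by flag.
* **Jaccard distance** on presence sets; two empty samples get d = 0.
* **PCoA** is classical metric scaling: eigendecomposition of the
  double-centered −½D² matrix. Negative eigenvalues (non-Euclidean
  input) are reported, not zeroed; a Lingoes correction is optional.
  Proportions explained are relative to the positive eigenvalue sum.
* **PERMANOVA** computes the pseudo-F from among/within sums of squared
  distances and a permutation p-value p = (1 + #{F* ≥ F}) / (1 + n_perm)
  (999 permutations by default, seeded). Perfectly tight clusters give
  F = ∞ and the minimal attainable p.
* **PLS-DA** is a NIPALS implementation against a ±1 class vector on
  column-centered abundances, with a deterministic sign convention
  (largest-magnitude weight positive). It matches reference PLS scores
  up to sign.

## Differential abundance

* **Welch + BH**: per-genus two-sided Welch's t-test on untransformed
  relative abundances, BH step-up FDR across all tested genera,
  significance at q < 0.05. Zero-variance genera get p = 1. Genera
  observed in <5% of samples are excluded up front from both
  procedures.
* **LEfSe-style effect size**: per-sample scaling to 1e6; Kruskal–Wallis
  screen at α = 0.05; then 30 bootstrap rounds on class-balanced 2/3
  subsamples, each fitting a Fisher discriminant (direction
  pinv(S_w)·(m₁−m₀), robust to singular within-class scatter). The
  per-genus effect is the round-average of
  ½(|u_j · Δ_proj| + |Δ_raw,j|), where u is the unit discriminant
  direction, Δ_proj the projected class-mean difference and Δ_raw the
  raw per-genus class-mean difference, reported as log10(1 + |effect|)
  and thresholded at 3.0. For a single retained feature this reduces to
  log10(1 + |class-mean difference|), the closed form used in tests;
  the score is monotone in the injected separation. A `prescaled` flag
  skips the per-sample renormalization for inputs already on the
  per-million scale (needed when single features are analyzed in
  isolation, where renormalization is degenerate).
* The Welch and LEfSe-style significant lists are reported side by
  side and never merged silently (their disagreement is informative).

## Co-occurrence networks

Pairwise Spearman correlations (average ranks for ties, t-approximation
p-values) thresholded at |ρ| > 0.3 and raw p < 0.05 — the figure
convention in this literature; an optional BH flag adjusts edge
p-values but is off by default. Networks can be restricted to the k
most abundant genera (default 150) and cross-correlated against a
samples × cell-type fraction matrix (e.g. CAF clusters or immune cells
from deconvolution, which is out of scope and consumed as input).
Degrees, sign counts and components come from the thresholded graph.

## Risk classifier

* **AUC** is the Mann–Whitney statistic (ties ½) with a two-sided
  tie-corrected normal-approximation p for AUC ≠ 0.5. The positive
  class is non-pCR throughout (the score predicts non-response); a flag
  flips orientation.
* **Youden cutoff**: candidate thresholds are midpoints between
  consecutive sorted unique values plus sentinels below/above the
  range; the maximal-J threshold wins, ties broken toward the smallest
  threshold (maximizing sensitivity for non-pCR detection). The
  high-level stratum is abundance ≥ cutoff (≥ chosen over > and
  documented, as conventions differ).
* **Screen**: candidates pass stage 1 at continuous AUC p < 0.05;
  stage 2 recomputes the AUC on the dichotomized 0/1 strata (for a
  binary marker this equals (sensitivity + specificity)/2).
* **Score**: per-sample sum of high-level indicators, an integer in
  [0, n_markers]; with seven markers, [0, 7].
* **Logistic regression**: maximum likelihood via statsmodels with Wald
  odds ratios exp(β ± 1.96·SE). The score enters as a continuous
  integer; sex is binary, age dichotomized at the cohort median, and
  grade/cT/cN ordinal (single-OR-per-factor codings; the exact clinical
  codings are conventions and documented as such). Perfect or
  quasi-separation (non-convergence, |β| > 20, or singular Hessian) is
  flagged, point estimates fall back to a ridge-stabilized Newton
  solve, and CIs are suppressed rather than reported unstably.
* No internal cross-validation is applied by default: cutoffs and AUC
  are apparent (in-sample) performance, matching how such classifiers
  are typically first reported; honest external evaluation requires an
  independent cohort.

## Pipeline

Stages run in dependency order (processing → diversity → differential →
networks → classifier) and communicate only through on-disk TSV/JSON
artifacts. Every run writes a manifest with the full configuration,
SHA-256 of each artifact, and each defaulted parameter actually used
(e.g. auto-selected rarefaction depth). Reruns with identical
configuration are byte-identical. Sub-stage seeds derive from the
single pipeline seed by fixed offsets.

## Numerical and testing choices

Oracles are independent of the paths they check: exhaustive
concordant-pair counting for AUC, exhaustive threshold search for
Youden, a brute-force step-up loop for BH, multivariate-hypergeometric
moments and exact marginals for rarefaction, set arithmetic for
Jaccard, scikit-bio for PCoA/PERMANOVA and scikit-learn for PLS.
Calibration tests run at reduced replicate counts chosen for a
single-CPU run: 200 PERMANOVA null replicates at 199 permutations, 100
null cohorts for Welch+BH, 250 logistic fits for Wald-p uniformity, 20
replicate cohorts for recovery at the 105-sample design point, with
acceptance bands from exact binomial intervals at the nominal level.

Known limitations: the contaminant rule is a heuristic stand-in for
control-based decontamination and will miss contaminants whose input
mass scales with sample biomass; the LEfSe-style effect size is a
documented approximation of the original tool (no subclass stage, a
simplified per-feature effect combination); rarefaction discards reads
and its single-draw variance is not propagated; apparent (in-sample)
classifier performance is optimistic by construction.
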