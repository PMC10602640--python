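"""Build and evaluate the composite microbial risk score.

Marker genera pass a continuous-abundance AUC screen, are dichotomized
at their maximum-Youden-index cutoff (1 = high level), and the 0/1
indicators are summed into an integer risk score predicting
non-response. The score is evaluated by rank AUC and by multivariable
logistic regression against clinical covariates.
"""

import numpy as np

from micromarker import (
    CohortConfig,
    build_risk_score,
    clinical_design,
    evaluate_score,
    generate_cohort,
    logistic_fit,
    preprocess,
    score_samples,
    screen_markers,
    welch_bh,
)
from micromarker.containers import RESPONSE_NON_PCR, response_vector

matrix, meta, truth = generate_cohort(CohortConfig(seed=1))
matrix = preprocess.retain_bacteria(matrix)
matrix, _ = preprocess.prevalence_contaminant_filter(matrix)
matrix = preprocess.rarefy(matrix, seed=1)
rel = preprocess.to_relative(matrix)
labels = response_vector(meta, matrix.sample_ids)

# candidates: the differential genera found by Welch+BH (mirroring a
# screen of discovered, not oracle, markers)
rec = welch_bh(rel, labels)
candidates = rec.loc[rec["sig_welch"], "genus"].tolist()
markers = screen_markers(rel, labels, candidates)
markers = sorted(markers, key=lambda m: m.auc_continuous, reverse=True)[:7]

model = build_risk_score(markers)
print("markers (genus, cutoff, continuous AUC):")
for m in model.markers:
    print(f"  {m.genus}: cutoff={m.cutoff:.2e}, AUC={m.auc_continuous:.3f}")

scores = score_samples(model, rel)
roc = evaluate_score(scores, labels)
print(f"\nrisk score range {scores.min()}-{scores.max()}, "
      f"combined AUC = {roc.auc:.3f} (p = {roc.p_value:.2e}) for predicting non-pCR")

design = clinical_design(meta[meta['sample_id'].isin(scores.index)], scores)
outcome = (labels == RESPONSE_NON_PCR).astype(int)
fit = logistic_fit(design, outcome)
row = fit.table.loc["risk_score"]
if fit.separation:
    print(f"adjusted odds ratio per score point: {row['odds_ratio']:.2f} "
          "(quasi-separation: the score nearly perfectly predicts outcome, "
          "so Wald CIs are suppressed)")
else:
    print(f"adjusted odds ratio per score point: {row['odds_ratio']:.2f} "
          f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}, p = {row['p']:.1e})")
# An OR above 1 means each additional high-level marker multiplies the
# odds of non-response, independent of sex, age, grade and cT/cN stage.
# On this synthetic cohort the injected markers are strong enough that
# the integer score separates the groups almost perfectly.
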