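"""Composite microbial risk score for predicting non-response.

The classifier construction:

1. Screen candidate genera by the AUC of their continuous relative
   abundance for the positive class (non-pCR by default), keeping those
   with AUC p < alpha.
2. Dichotomize each retained genus at the cutoff maximizing the Youden
   index J = sensitivity + specificity - 1, assigning 1 (high-level) when
   abundance >= cutoff, else 0.
3. Sum the indicators into an integer risk score in [0, n_markers];
   evaluate the score by rank AUC and by multivariable logistic
   regression against clinical covariates (odds ratio per one-score
   increase).

AUC is the Mann-Whitney statistic (ties count 1/2) with a tie-corrected
normal-approximation p-value for AUC != 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import RESPONSE_NON_PCR

logger = logging.getLogger(__name__)

POSITIVE_CLASS = RESPONSE_NON_PCR


@dataclass
class RocResult:
    auc: float
    p_value: float
    positive_class: str
    n_positive: int
    n_negative: int
    higher_predicts_positive: bool = True


def auc_rank(values, labels, positive_class: str = POSITIVE_CLASS) -> RocResult:
    """Rank (Mann-Whitney) AUC of ``values`` for ``positive_class``.

    AUC = U / (n+ * n-) with ties counted one half; two-sided p for
    AUC != 0.5 from the tie-corrected normal approximation of U. All-tied
    values give AUC 0.5 and p 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"both classes required; positive class {positive_class!r}")
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    auc = u / (n1 * n0)

    n = n1 + n0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_u = n1 * n0 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n1 * n0 / 2) / np.sqrt(var_u)
        p = float(2 * stats.norm.sf(abs(z)))
    return RocResult(
        auc=float(auc),
        p_value=min(p, 1.0),
        positive_class=str(positive_class),
        n_positive=n1,
        n_negative=n0,
    )


@dataclass
class MarkerCutoff:
    genus: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc_continuous: float
    p_continuous: float
    auc_dichotomized: float = float("nan")
    p_dichotomized: float = float("nan")


def youden_cutoff(values, labels, positive_class: str = POSITIVE_CLASS, genus: str = "") -> MarkerCutoff:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive sorted unique
    values plus one below the minimum and one above the maximum;
    classification rule is ``value >= cutoff -> high-level (positive)``.
    Ties in J break toward the smallest threshold, which maximizes
    sensitivity for detecting the positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    uniq = np.unique(values)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        high = values >= c
        sens = (high & pos).sum() / n1
        spec = (~high & ~pos).sum() / n0
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    roc = auc_rank(values, labels, positive_class)
    return MarkerCutoff(
        genus=genus,
        cutoff=float(c),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
        auc_continuous=roc.auc,
        p_continuous=roc.p_value,
    )


def screen_markers(
    relabund: pd.DataFrame,
    labels,
    candidates: list[str],
    alpha: float = 0.05,
    positive_class: str = POSITIVE_CLASS,
) -> list[MarkerCutoff]:
    """Two-stage marker screen: continuous AUC p < alpha, then Youden
    dichotomization with the post-dichotomization AUC recomputed on the
    0/1 strata.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    missing = [g for g in candidates if g not in relabund.columns]
    if missing:
        raise ValueError(f"candidate genera absent from matrix: {missing}")
    labels = np.asarray(labels)
    markers: list[MarkerCutoff] = []
    for genus in candidates:
        vals = relabund[genus].to_numpy()
        roc = auc_rank(vals, labels, positive_class)
        if roc.p_value >= alpha:
            continue
        mc = youden_cutoff(vals, labels, positive_class, genus=genus)
        strata = (vals >= mc.cutoff).astype(int)
        dich = auc_rank(strata, labels, positive_class)
        mc.auc_dichotomized = dich.auc
        mc.p_dichotomized = dich.p_value
        markers.append(mc)
    logger.info("marker screen retained %d of %d candidates", len(markers), len(candidates))
    return markers


@dataclass
class RiskScoreModel:
    """Sum of per-marker high-level indicators; range [0, n_markers]."""

    markers: list[MarkerCutoff]
    positive_class: str = POSITIVE_CLASS

    @property
    def marker_genera(self) -> list[str]:
        return [m.genus for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genus": m.genus,
                    "cutoff": m.cutoff,
                    "youden_j": m.youden_j,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "auc_continuous": m.auc_continuous,
                    "p_continuous": m.p_continuous,
                    "auc_dichotomized": m.auc_dichotomized,
                    "p_dichotomized": m.p_dichotomized,
                }
                for m in self.markers
            ]
        )

    def save(self, tsv_path: str | Path) -> None:
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        sidecar = tsv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"positive_class": self.positive_class, "rule": "value >= cutoff -> 1"},
                indent=2,
            )
        )

    @classmethod
    def load(cls, tsv_path: str | Path) -> "RiskScoreModel":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t")
        meta = {}
        sidecar = tsv_path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        markers = [
            MarkerCutoff(
                genus=row["genus"],
                cutoff=row["cutoff"],
                sensitivity=row.get("sensitivity", float("nan")),
                specificity=row.get("specificity", float("nan")),
                youden_j=row.get("youden_j", float("nan")),
                auc_continuous=row.get("auc_continuous", float("nan")),
                p_continuous=row.get("p_continuous", float("nan")),
                auc_dichotomized=row.get("auc_dichotomized", float("nan")),
                p_dichotomized=row.get("p_dichotomized", float("nan")),
            )
            for _, row in df.iterrows()
        ]
        return cls(markers=markers, positive_class=meta.get("positive_class", POSITIVE_CLASS))


def build_risk_score(markers: list[MarkerCutoff]) -> RiskScoreModel:
    if not markers:
        raise ValueError("at least one marker required")
    return RiskScoreModel(markers=list(markers))


def score_samples(model: RiskScoreModel, relabund: pd.DataFrame) -> pd.Series:
    """Integer risk score per sample: count of markers at/above cutoff."""
    missing = [g for g in model.marker_genera if g not in relabund.columns]
    if missing:
        raise ValueError(f"marker genera absent from matrix: {missing}")
    score = np.zeros(len(relabund), dtype=int)
    for m in model.markers:
        score += (relabund[m.genus].to_numpy() >= m.cutoff).astype(int)
    return pd.Series(score, index=relabund.index, name="risk_score")


def evaluate_score(scores, labels, positive_class: str = POSITIVE_CLASS) -> RocResult:
    """AUC of the integer risk score (heavy ties handled by rank AUC)."""
    return auc_rank(np.asarray(scores, dtype=float), labels, positive_class)


@dataclass
class LogisticFit:
    """Wald summary of a maximum-likelihood logistic regression."""

    table: pd.DataFrame  # coef, odds_ratio, ci_low, ci_high, p per covariate
    converged: bool
    separation: bool
    n: int
    log_likelihood: float = float("nan")
    params: pd.Series = field(default=None)  # type: ignore[assignment]


def logistic_fit(design: pd.DataFrame, outcome, add_intercept: bool = True) -> LogisticFit:
    """Fit outcome ~ design by maximum likelihood (IRLS), Wald inference.

    Outcome is 0/1 (1 = non-pCR by convention here). Reports per-covariate
    odds ratios exp(beta) with 95% Wald CIs exp(beta +/- 1.96 SE).
    Perfect or quasi-separation is detected (non-convergence or exploding
    coefficients) and flagged; CIs are suppressed for separated fits.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("n must exceed the number of covariates")

    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, PerfectSeparationError):
        converged = False
        separation = True
        res = None

    if res is not None:
        params = res.params
        try:
            bse = res.bse
        except np.linalg.LinAlgError:  # singular Hessian
            bse = pd.Series(np.nan, index=params.index)
        if (np.abs(params) > 20).any() or not np.isfinite(np.asarray(bse)).all():
            separation = True
    if res is None:
        # ridge-stabilized Newton fallback: point estimates only
        Xv = X.to_numpy()
        beta = np.zeros(Xv.shape[1])
        for _ in range(100):
            eta = np.clip(Xv @ beta, -30, 30)
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
            h = Xv.T @ (Xv * w[:, None]) + 1e-6 * np.eye(Xv.shape[1])
            step = np.linalg.solve(h, Xv.T @ (y - mu) - 1e-6 * beta)
            beta += step
            if np.abs(step).max() < 1e-8:
                break
        params = pd.Series(beta, index=X.columns)
        bse = pd.Series(np.nan, index=params.index)

    or_ = np.exp(params)
    if separation:
        ci_low = pd.Series(np.nan, index=params.index)
        ci_high = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
        logger.warning("separation detected; Wald CIs suppressed")
    else:
        ci_low = np.exp(params - 1.96 * bse)
        ci_high = np.exp(params + 1.96 * bse)
        pvals = pd.Series(res.pvalues, index=params.index)

    table = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": or_,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p": pvals,
        }
    )
    return LogisticFit(
        table=table,
        converged=converged,
        separation=separation,
        n=len(y),
        log_likelihood=float(res.llf) if hasattr(res, "llf") else float("nan"),
        params=pd.Series(params, index=table.index),
    )


def clinical_design(meta: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Default covariate coding for the multivariable model.

    sex -> 1 for male; age dichotomized at the cohort median; grading,
    cT, cN entered as given (ordinal); score as a continuous integer.
    """
    m = meta.set_index("sample_id").loc[scores.index]
    design = pd.DataFrame(index=scores.index)
    design["sex_male"] = (m["sex"].astype(str).str.lower() == "male").astype(int)
    design["age_high"] = (m["age"] >= m["age"].median()).astype(int)
    for col in ("grading", "cT", "cN"):
        design[col] = pd.to_numeric(m[col])
    design["risk_score"] = scores.astype(int)
    return design
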