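"""Differential genus abundance between response groups.

Two complementary procedures:

* ``welch_bh`` — per-genus two-sided Welch's t-test on relative
  abundances with Benjamini–Hochberg FDR control across genera (the
  STAMP-style analysis).
* ``lefse_like`` — an LDA-effect-size procedure: per-sample scaling to
  1e6, a Kruskal–Wallis screen, then bootstrapped one-component linear
  discriminant analysis whose per-genus effect size (log10 scale) ranks
  the survivors; genera pass at effect > 3.0 with KW p < 0.05 by default.

Both report into a single per-genus record table; genera observed in
fewer than 5% of samples are excluded up front to stabilize the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LEFSE_SCALE = 1e6
MIN_PREVALENCE = 0.05

RECORD_COLUMNS = [
    "genus",
    "mean_pCR",
    "mean_nonpCR",
    "welch_p",
    "bh_q",
    "kw_p",
    "lda_log10",
    "enriched_group",
    "sig_welch",
    "sig_lefse",
]


def _two_groups(labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    return labels, groups, np.where(labels == groups[1], 1, 0)


def _prevalence_mask(relabund: pd.DataFrame, floor: float = MIN_PREVALENCE) -> pd.Index:
    prev = (relabund > 0).mean(axis=0)
    kept = relabund.columns[prev >= floor]
    if len(kept) < relabund.shape[1]:
        logger.info(
            "excluding %d genera observed in <%.0f%% of samples",
            relabund.shape[1] - len(kept),
            100 * floor,
        )
    return kept


def welch_bh(
    relabund: pd.DataFrame, labels, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-genus Welch's t-test with BH FDR on relative abundances.

    Genera with zero variance in both groups (e.g. identical values) get
    p = 1. Returns one row per tested genus with means per group, p, BH q
    and the significance flag at ``q < q_threshold``.
    """
    labels, groups, _ = _two_groups(labels)
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("each group needs n >= 2")
    kept = _prevalence_mask(relabund)
    sub = relabund[kept]
    a = sub.loc[labels == groups[0]].to_numpy()
    b = sub.loc[labels == groups[1]].to_numpy()

    pvals = np.ones(sub.shape[1])
    varless = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    test_idx = np.flatnonzero(~varless)
    if len(test_idx):
        res = stats.ttest_ind(a[:, test_idx], b[:, test_idx], equal_var=False)
        pvals[test_idx] = np.nan_to_num(res.pvalue, nan=1.0)
    qvals = bh_adjust(pvals)

    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    records = pd.DataFrame(
        {
            "genus": kept,
            f"mean_{groups[0]}": mean_a,
            f"mean_{groups[1]}": mean_b,
            "welch_p": pvals,
            "bh_q": qvals,
            "enriched_group": np.where(mean_a >= mean_b, groups[0], groups[1]),
            "sig_welch": qvals < q_threshold,
        }
    )
    return records.reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def _lda_direction(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction pinv(S_w) @ (m1 - m0), unit norm."""
    m0 = X[y01 == 0].mean(axis=0)
    m1 = X[y01 == 1].mean(axis=0)
    sw = np.cov(X[y01 == 0], rowvar=False, bias=True) * (y01 == 0).sum()
    sw = sw + np.cov(X[y01 == 1], rowvar=False, bias=True) * (y01 == 1).sum()
    sw = np.atleast_2d(sw)
    w = np.linalg.pinv(sw) @ (m1 - m0)
    norm = np.linalg.norm(w)
    if norm < 1e-30:
        w = m1 - m0
        norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse_like(
    relabund: pd.DataFrame,
    labels,
    kw_alpha: float = 0.05,
    lda_threshold: float = 3.0,
    n_boot: int = 30,
    boot_fraction: float = 2 / 3,
    seed: int = 0,
    prescaled: bool = False,
) -> pd.DataFrame:
    """Kruskal–Wallis screen followed by bootstrapped LDA effect sizes.

    Abundances are scaled per sample to sum to 1e6 (so effect sizes live
    on the familiar per-million scale). Stage 1 keeps genera with KW
    p < ``kw_alpha``; stage 2 averages, over ``n_boot`` class-balanced
    2/3 subsamples, a per-genus effect combining the discriminant-weighted
    and raw class-mean differences, reported as log10(1 + |effect|).

    ``prescaled=True`` skips the per-sample renormalization for input
    already on the per-million scale (useful when single features are
    analyzed in isolation, where renormalization would be degenerate).
    """
    labels, groups, y01 = _two_groups(labels)
    if prescaled:
        scaled = relabund.astype(float)
    else:
        scaled = relabund.div(relabund.sum(axis=1), axis=0) * LEFSE_SCALE
    kept = _prevalence_mask(scaled)
    scaled = scaled[kept]

    kw_p = np.ones(scaled.shape[1])
    for j, genus in enumerate(scaled.columns):
        col = scaled[genus].to_numpy()
        a, b = col[y01 == 0], col[y01 == 1]
        if np.all(col == col[0]):
            continue
        kw_p[j] = stats.kruskal(a, b).pvalue
    retained = np.flatnonzero(kw_p < kw_alpha)

    effects = pd.Series(0.0, index=scaled.columns)
    if len(retained):
        X = scaled.iloc[:, retained].to_numpy()
        rng = np.random.default_rng(seed)
        n0, n1 = (y01 == 0).sum(), (y01 == 1).sum()
        k0, k1 = int(round(n0 * boot_fraction)), int(round(n1 * boot_fraction))
        if min(k0, k1) < 3:
            raise ValueError("fewer than 3 samples per class after subsampling")
        idx0, idx1 = np.flatnonzero(y01 == 0), np.flatnonzero(y01 == 1)
        acc = np.zeros(len(retained))
        for _ in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(idx0, size=k0, replace=False),
                    rng.choice(idx1, size=k1, replace=False),
                ]
            )
            Xb, yb = X[take], y01[take]
            m0 = Xb[yb == 0].mean(axis=0)
            m1 = Xb[yb == 1].mean(axis=0)
            w = _lda_direction(Xb, yb)
            proj_diff = w @ (m1 - m0)
            acc += 0.5 * (np.abs(w * proj_diff) + np.abs(m1 - m0))
        effects.iloc[retained] = acc / n_boot

    lda_log10 = np.log10(1.0 + np.abs(effects.to_numpy()))
    mean_a = scaled.loc[y01 == 0].mean(axis=0).to_numpy()
    mean_b = scaled.loc[y01 == 1].mean(axis=0).to_numpy()
    records = pd.DataFrame(
        {
            "genus": scaled.columns,
            f"mean_{groups[0]}": mean_a / LEFSE_SCALE,
            f"mean_{groups[1]}": mean_b / LEFSE_SCALE,
            "kw_p": kw_p,
            "lda_log10": lda_log10,
            "enriched_group": np.where(mean_a >= mean_b, groups[0], groups[1]),
            "sig_lefse": (kw_p < kw_alpha) & (lda_log10 > lda_threshold),
        }
    )
    return records.reset_index(drop=True)


@dataclass
class DifferentialSummary:
    table: pd.DataFrame  # significant records, sorted by effect size
    submatrix: pd.DataFrame  # relabund restricted to significant genera
    group_annotation: pd.Series


def summarize_differential(
    records: pd.DataFrame,
    relabund: pd.DataFrame,
    labels,
    flag_column: str = "sig_welch",
) -> DifferentialSummary:
    """Rank significant genera and export their abundance submatrix.

    ``records`` may come from either procedure; rows flagged by
    ``flag_column`` are kept, sorted by effect size (LDA score if present,
    else -log10 of the raw p).
    """
    if len(records) == 0:
        raise ValueError("at least one record is required")
    sig = records[records[flag_column].astype(bool)].copy()
    if "lda_log10" in sig.columns:
        sig = sig.sort_values("lda_log10", ascending=False)
    else:
        sig = sig.sort_values("welch_p")
    genera = [g for g in sig["genus"] if g in relabund.columns]
    return DifferentialSummary(
        table=sig.reset_index(drop=True),
        submatrix=relabund[genera].copy(),
        group_annotation=pd.Series(np.asarray(labels), index=relabund.index),
    )


def merge_records(welch: pd.DataFrame, lefse: pd.DataFrame) -> pd.DataFrame:
    """Outer-join the two procedures' records into one table.

    The two significant lists are kept side by side (no silent
    reconciliation); missing flags are False.
    """
    merged = welch.merge(
        lefse[["genus", "kw_p", "lda_log10", "sig_lefse"]], on="genus", how="outer"
    )
    for flag in ("sig_welch", "sig_lefse"):
        merged[flag] = merged[flag].fillna(False).astype(bool)
    return merged
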