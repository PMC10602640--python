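"""Alpha and beta diversity of genus-level profiles.

Alpha diversity is the Shannon index in natural-log units, compared
between response groups by a two-sided Wilcoxon rank-sum test (Welch's t
optional). Beta diversity uses the Jaccard distance on genus presence
sets, embedded by classical principal-coordinates analysis and tested by
PERMANOVA (pseudo-F under label permutation). A seeded NIPALS PLS-DA
provides the supervised ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p ln p over nonzero proportions (nats)."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(matrix) -> pd.Series:
    """Shannon index for every row of a count or abundance matrix."""
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    return counts.apply(shannon_index, axis=1).rename("shannon")


def compare_alpha(values, labels, method: str = "ranksum") -> dict:
    """Two-group alpha-diversity comparison.

    ``method``: "ranksum" (Wilcoxon rank-sum / Mann-Whitney, default) or
    "welch". Returns the statistic, two-sided p, and per-group medians.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    if method == "ranksum":
        # exact null-permutation p when tie-free and small enough to enumerate
        no_ties = len(np.unique(values[np.isin(labels, groups)])) == len(a) + len(b)
        how = "exact" if (no_ties and max(len(a), len(b)) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=how)
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "statistic": float(res.statistic),
        "p_value": float(min(res.pvalue, 1.0)),
        "groups": (groups[0], groups[1]),
        "medians": (float(np.median(a)), float(np.median(b))),
        "method": method,
    }


def jaccard_distance(matrix) -> pd.DataFrame:
    """Pairwise Jaccard distance on genus presence (count > 0) sets.

    d(a, b) = 1 - |A & B| / |A | B|; two samples with empty presence sets
    get distance 0.
    """
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    presence = (counts.to_numpy() > 0).astype(bool)
    n = presence.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    dist = np.zeros((n, n))
    if presence.shape[1] > 0 and n > 1:
        nonempty = presence.any(axis=1)
        condensed = pdist(presence, metric="jaccard")
        dist = squareform(condensed)
        # scipy defines d=0 for two all-empty rows already; enforce anyway
        for i in np.flatnonzero(~nonempty):
            for j in np.flatnonzero(~nonempty):
                dist[i, j] = 0.0
    return pd.DataFrame(dist, index=counts.index, columns=counts.index)


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # per retained axis, of positive sum


def pcoa(dist: pd.DataFrame, k: int = 2, lingoes: bool = False) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -0.5 * D**2 and eigendecomposes; coordinates come from
    the top-k positive eigenvalues. Negative eigenvalues (non-Euclidean
    distances) are reported as-is unless ``lingoes=True``, which adds the
    Lingoes constant to off-diagonal squared distances first.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    d2 = d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if lingoes and eigvals[-1] < -1e-12:
        c = -eigvals[-1]
        d2c = d2 + 2 * c * (1 - np.eye(n))
        b = -0.5 * centering @ d2c @ centering
        eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues", k, n_pos)
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    pos_sum = eigvals[eigvals > tol].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=np.asarray(prop),
    )


@dataclass
class PermutationTestResult:
    statistic: float  # pseudo-F
    p_value: float
    n_permutations: int


def permanova(
    dist: pd.DataFrame, labels, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """PERMANOVA: pseudo-F on a distance matrix with permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm); deterministic
    under a fixed seed.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    groups, inv = np.unique(labels, return_inverse=True)
    if len(groups) < 2 or min(np.bincount(inv)) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 samples each")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d.shape[0]
    d2 = d**2

    def pseudo_f(inv_labels: np.ndarray) -> float:
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in range(len(groups)):
            idx = np.flatnonzero(inv_labels == g)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        df_a = len(groups) - 1
        df_w = n - len(groups)
        if ssw <= 0:  # e.g. perfectly tight clusters
            return np.inf if ssa > 0 else 0.0
        return (ssa / df_a) / (ssw / df_w)

    observed = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count = 0
    perm = inv.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if pseudo_f(perm) >= observed:
            count += 1
    return PermutationTestResult(
        statistic=float(observed),
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
    )


@dataclass
class PlsdaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genera x components (x-weights, unit norm)
    explained_covariance: np.ndarray  # |cov(score, y)| per component


def plsda(relabund: pd.DataFrame, labels, n_components: int = 2) -> PlsdaResult:
    """Two-class PLS discriminant analysis via NIPALS deflation.

    The class vector is coded +/-1 and column-centered abundances are
    regressed component-by-component; each component's weight vector
    maximizes covariance with the class vector. Sign convention: the
    largest-magnitude weight entry of each component is positive.
    """
    X = np.asarray(relabund, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two classes required, got {list(groups)}")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components must lie in [1, min(n-1, p)]")
    y = np.where(labels == groups[1], 1.0, -1.0)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()

    scores = np.zeros((n, n_components))
    weights = np.zeros((p, n_components))
    expl = np.zeros(n_components)
    Xd = Xc.copy()
    yd = yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            logger.warning("PLS component %d has ~zero covariance; stopping", a + 1)
            break
        w /= norm
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q = yd @ t / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q * t
        scores[:, a] = t
        weights[:, a] = w
        expl[a] = abs(np.cov(t, yc, bias=True)[0, 1])

    cols = [f"comp{i + 1}" for i in range(n_components)]
    return PlsdaResult(
        scores=pd.DataFrame(scores, index=relabund.index, columns=cols),
        loadings=pd.DataFrame(weights, index=relabund.columns, columns=cols),
        explained_covariance=expl,
    )
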