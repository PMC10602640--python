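"""Count-matrix preprocessing: kingdom filtering, decontamination,
rarefaction, relative-abundance transform, and group presence summaries.

Decontamination here is a deliberately simplified, fully data-driven
stand-in for control-sample-based methods (no negative controls or DNA
concentrations exist for RNA-seq-derived tumor microbiomes): a genus is
flagged as a contaminant when its relative abundance correlates strongly
and negatively with sample sequencing depth — the pattern left by a
roughly constant number of spurious reads per sample — and genera below a
prevalence floor are dropped outright.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, normalize_response

logger = logging.getLogger(__name__)

PREVALENCE_FLOOR = 0.05
CONTAM_RHO_MAX = -0.6
CONTAM_ALPHA = 0.05


def retain_bacteria(matrix: CountMatrix) -> CountMatrix:
    """Keep only genera whose lineage kingdom is Bacteria.

    Genera with no kingdom annotation (unannotated assemblies) are kept,
    so the filter is a no-op on lineage-free matrices.
    """
    keep = [
        g
        for g in matrix.genus_ids
        if str(matrix.lineage.loc[g, "kingdom"]) in ("Bacteria", "")
        or pd.isna(matrix.lineage.loc[g, "kingdom"])
    ]
    dropped = len(matrix.genus_ids) - len(keep)
    if dropped:
        logger.info("removed %d non-bacterial genera", dropped)
    if not keep:
        logger.warning("no bacterial genera remain after kingdom filter")
    return matrix.select_genera(keep)


def prevalence_contaminant_filter(
    matrix: CountMatrix,
    prevalence_floor: float = PREVALENCE_FLOOR,
    score_threshold: float = CONTAM_RHO_MAX,
    alpha: float = CONTAM_ALPHA,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-prevalence genera and depth-inverse contaminants.

    A genus scores as a contaminant when the Spearman correlation between
    its relative abundance and sample depth is at most ``score_threshold``
    (default -0.6) with p < ``alpha``. Returns the filtered matrix and a
    report of removed genera (columns: genus, score, reason).
    """
    if matrix.counts.shape[0] < 2:
        raise ValueError("contaminant filtering requires at least 2 samples")
    if not 0 <= prevalence_floor <= 1:
        raise ValueError(f"prevalence_floor must lie in [0, 1], got {prevalence_floor}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")

    depths = matrix.depths().to_numpy().astype(float)
    rel = matrix.counts.to_numpy() / depths[:, None]
    prevalence = (matrix.counts.to_numpy() > 0).mean(axis=0)

    removed = []
    keep = []
    for j, genus in enumerate(matrix.genus_ids):
        if prevalence[j] < prevalence_floor:
            removed.append((genus, float(prevalence[j]), "low_prevalence"))
            continue
        col = rel[:, j]
        if np.all(col == col[0]) or np.all(depths == depths[0]):
            keep.append(genus)
            continue
        rho, p = stats.spearmanr(col, depths)
        if rho <= score_threshold and p < alpha:
            removed.append((genus, float(rho), "depth_inverse"))
        else:
            keep.append(genus)
    report = pd.DataFrame(removed, columns=["genus", "score", "reason"])
    if len(removed):
        logger.info(
            "contaminant filter removed %d genera (%d low-prevalence, %d depth-inverse)",
            len(removed),
            int((report["reason"] == "low_prevalence").sum()),
            int((report["reason"] == "depth_inverse").sum()),
        )
    return matrix.select_genera(keep), report


def rarefy(matrix: CountMatrix, depth: int | None = None, seed: int = 0) -> CountMatrix:
    """Subsample each sample's reads without replacement to a common depth.

    ``depth`` defaults to the minimum sample depth. Samples with fewer
    total reads than ``depth`` are dropped with a warning; the subsample is
    multivariate-hypergeometric, deterministic under a fixed seed.
    """
    totals = matrix.depths()
    if depth is None:
        depth = int(totals.min())
        logger.info("rarefaction depth defaulted to minimum sample depth %d", depth)
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    if (totals < depth).all():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    kept = totals.index[totals >= depth]
    dropped = totals.index.difference(kept)
    if len(dropped):
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped),
            depth,
            list(dropped),
        )
    rng = np.random.default_rng(seed)
    out = np.empty((len(kept), matrix.counts.shape[1]), dtype=np.int64)
    for i, sample in enumerate(kept):
        row = matrix.counts.loc[sample].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountMatrix(
        pd.DataFrame(out, index=list(kept), columns=matrix.genus_ids),
        matrix.lineage.copy(),
    )


def to_relative(matrix: CountMatrix) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    totals = matrix.depths()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return matrix.counts.div(totals, axis=0)


def group_genus_sets(matrix: CountMatrix, labels: pd.Series | np.ndarray) -> dict:
    """Partition observed genera into shared and group-specific sets.

    A genus is present in a group if any sample of that group has count
    > 0. Genera absent everywhere are excluded. Returns counts and member
    lists keyed by the two (normalized) group labels.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=matrix.sample_ids).map(
        normalize_response
    )
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    present = {
        g: set(matrix.counts.columns[(matrix.counts.loc[labels == g] > 0).any(axis=0)])
        for g in groups
    }
    a, b = groups
    shared = present[a] & present[b]
    only_a = present[a] - present[b]
    only_b = present[b] - present[a]
    return {
        "groups": (a, b),
        "shared_count": len(shared),
        f"{a}_only_count": len(only_a),
        f"{b}_only_count": len(only_b),
        "shared": sorted(shared),
        f"{a}_only": sorted(only_a),
        f"{b}_only": sorted(only_b),
    }
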