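"""Synthetic intratumoral-microbiome cohort generator.

Emulates the statistical structure of an RNA-seq-derived tumor microbiome
cohort: a ~105-sample two-arm design (pCR responders vs non-pCR
non-responders, ~25% responders), compositional genus-level read counts
with heavy-tailed baseline abundances and log-normal library sizes, a
minority of genera truly enriched in the non-responder arm, and spurious
reagent-style contaminant genera whose absolute counts are independent of
sequencing depth (so their relative abundance is depth-inverse — the
signature the contaminant filter keys on).

The count model is Dirichlet-multinomial: per-arm expected genus
proportions perturb a shared log-normal baseline by ``2**log2fc`` in the
non-responder arm, and each sample draws its composition from a Dirichlet
with a shared concentration mass (lower mass = more overdispersion) before
multinomial sampling at its drawn library size.

Every draw flows from a single integer seed; identical configuration and
seed give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import META_COLUMNS, RESPONSE_NON_PCR, RESPONSE_PCR, CountMatrix

BRACKEN_COLUMNS = [
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
]


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the study design this package targets: 105 biopsy
    samples, 24.8% responders, a few hundred observed genera of which 12
    are truly enriched in non-responders.
    """

    n_samples: int = 105
    responder_fraction: float = 26 / 105
    n_genera: int = 400
    n_differential: int = 12
    log2_fold_changes: tuple[float, ...] | float = 1.5
    base_concentration: float = 200.0
    library_size_log_mean: float = 10.0  # exp(10) ~ 22,000 microbial reads
    library_size_log_sd: float = 0.5
    n_contaminants: int = 10
    contaminant_mean_fraction: float = 0.005
    n_nonbacterial: int = 2
    confound_covariate: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.log2_fold_changes):
            self.log2_fold_changes = tuple(
                [float(self.log2_fold_changes)] * self.n_differential
            )
        else:
            self.log2_fold_changes = tuple(float(x) for x in self.log2_fold_changes)
        self.validate()

    def validate(self) -> None:
        def _positive(name: str, value, strict=True) -> None:
            if not math.isfinite(value) or (value <= 0 if strict else value < 0):
                raise ValueError(f"{name} must be a finite positive number, got {value}")

        _positive("n_samples", self.n_samples)
        _positive("n_genera", self.n_genera)
        _positive("base_concentration", self.base_concentration)
        _positive("library_size_log_sd", self.library_size_log_sd)
        if not math.isfinite(self.library_size_log_mean):
            raise ValueError("library_size_log_mean must be finite")
        if not 0 < self.responder_fraction < 1:
            raise ValueError(
                f"responder_fraction must lie strictly in (0, 1), got {self.responder_fraction}"
            )
        if not 0 <= self.contaminant_mean_fraction < 1:
            raise ValueError(
                f"contaminant_mean_fraction must lie in [0, 1), got {self.contaminant_mean_fraction}"
            )
        if self.n_differential < 0 or self.n_differential > self.n_genera:
            raise ValueError("n_differential must lie in [0, n_genera]")
        if len(self.log2_fold_changes) != self.n_differential:
            raise ValueError("log2_fold_changes length must equal n_differential")
        if any(not math.isfinite(x) for x in self.log2_fold_changes):
            raise ValueError("log2_fold_changes must be finite")
        for name in ("n_contaminants", "n_nonbacterial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    differential_genera: dict[str, float]  # genus -> true log2 fold change
    contaminant_genera: set[str] = field(default_factory=set)
    nonbacterial_genera: set[str] = field(default_factory=set)
    labels: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if set(self.differential_genera) & self.contaminant_genera:
            raise ValueError("differential and contaminant genus sets must be disjoint")


# baseline heavy tail: a few dominant genera, long rare tail
BASELINE_LOG_SIGMA = 1.5


def _covariates(rng: np.random.Generator, labels: np.ndarray, confound: str | None):
    """Clinical covariates, independent of arm unless one is confounded."""
    n = len(labels)
    non_resp = labels == RESPONSE_NON_PCR
    sex = rng.choice(["male", "female"], size=n, p=[0.688, 0.312])
    age = np.clip(np.round(rng.normal(64, 11, size=n)), 34, 86).astype(int)
    grading = rng.choice([0, 2, 3], size=n, p=[0.019, 0.923, 0.058])
    cT = rng.choice([2, 3, 4], size=n, p=[0.10, 0.70, 0.20])
    cN = rng.choice([0, 1, 2], size=n, p=[0.25, 0.50, 0.25])
    if confound == "sex":
        sex = np.where(
            rng.random(n) < np.where(non_resp, 0.8, 0.5), "male", "female"
        )
    elif confound == "age":
        age = age + np.where(non_resp, 6, 0)
    elif confound is not None:
        raise ValueError(f"unsupported confound_covariate: {confound!r}")
    return sex, age, grading, cT, cN


def generate_cohort(config: CohortConfig) -> tuple[CountMatrix, pd.DataFrame, CohortTruth]:
    """Draw one cohort: counts, metadata, and ground truth.

    Non-responder (non-pCR) expected proportions multiply the shared
    baseline by ``2**log2fc`` for each differential genus, then
    renormalize; positive fold changes therefore enrich non-responders.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_samples)
    n_resp = int(round(n * config.responder_fraction))
    n_resp = min(max(n_resp, 1), n - 1)

    width = max(4, len(str(config.n_genera)))
    genera = [f"Genus_{i + 1:0{width}d}" for i in range(config.n_genera)]
    contam = [f"Contam_{i + 1:02d}" for i in range(config.n_contaminants)]
    nonbact = [f"NonBact_{i + 1:02d}" for i in range(config.n_nonbacterial)]

    baseline = rng.lognormal(mean=0.0, sigma=BASELINE_LOG_SIGMA, size=config.n_genera)
    baseline /= baseline.sum()

    # differential genera come from the moderately-abundant tier: marker
    # genera are established commensals, not the dominant handful (whose
    # perturbation would distort the renormalized composition) and not the
    # rare tail (where counts carry no signal)
    order = np.argsort(baseline)[::-1]
    skip = min(10, config.n_genera // 10)
    span = max(config.n_differential, int(0.35 * config.n_genera))
    eligible = order[skip : skip + span]
    if len(eligible) < config.n_differential:
        eligible = order
    diff_idx = rng.choice(eligible, size=config.n_differential, replace=False)
    lfc = np.zeros(config.n_genera)
    lfc[diff_idx] = config.log2_fold_changes

    p_resp = baseline / baseline.sum()
    p_non = baseline * np.exp2(lfc)
    p_non /= p_non.sum()

    labels = np.array(
        [RESPONSE_PCR] * n_resp + [RESPONSE_NON_PCR] * (n - n_resp), dtype=object
    )
    rng.shuffle(labels)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    depths = np.maximum(
        1,
        np.round(
            rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=n)
        ).astype(int),
    )

    contam_mean = config.contaminant_mean_fraction * math.exp(config.library_size_log_mean)
    counts = np.zeros((n, config.n_genera + len(contam) + len(nonbact)), dtype=np.int64)
    for i in range(n):
        c = rng.poisson(contam_mean, size=len(contam))
        nb = rng.poisson(0.002 * depths[i], size=len(nonbact))
        bio_total = max(int(depths[i] - c.sum() - nb.sum()), 0)
        p = p_non if labels[i] == RESPONSE_NON_PCR else p_resp
        theta = rng.dirichlet(config.base_concentration * p)
        counts[i, : config.n_genera] = rng.multinomial(bio_total, theta)
        counts[i, config.n_genera : config.n_genera + len(contam)] = c
        counts[i, config.n_genera + len(contam) :] = nb

    all_genera = genera + contam + nonbact
    lineage = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * (config.n_genera + len(contam))
            + ["Fungi"] * len(nonbact),
            "taxid": np.arange(1, len(all_genera) + 1) + 10_000,
        },
        index=all_genera,
    )
    matrix = CountMatrix(
        pd.DataFrame(counts, index=sample_ids, columns=all_genera), lineage
    )

    sex, age, grading, cT, cN = _covariates(rng, labels, config.confound_covariate)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "response": labels,
            "sex": sex,
            "age": age,
            "grading": grading,
            "cT": cT,
            "cN": cN,
        }
    )

    truth = CohortTruth(
        differential_genera={genera[j]: float(lfc[j]) for j in sorted(diff_idx)},
        contaminant_genera=set(contam),
        nonbacterial_genera=set(nonbact),
        labels=pd.Series(labels, index=sample_ids, name="response"),
    )
    return matrix, meta, truth


def write_cohort_fixture(
    matrix: CountMatrix, meta: pd.DataFrame, dir_path: str | Path
) -> list[Path]:
    """Write one Bracken-style genus report per sample plus metadata.

    Also emits ``lineage.tsv`` (genus, taxid, kingdom) because the Bracken
    report dialect itself carries no kingdom column; the reader picks it up
    when present. Zero-count genera keep their rows so a re-read reproduces
    the matrix exactly.
    """
    if matrix.counts.shape[0] == 0 or matrix.counts.shape[1] == 0:
        raise ValueError("cannot write an empty cohort fixture")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    depths = matrix.depths()
    for sample in matrix.sample_ids:
        row = matrix.counts.loc[sample]
        total = depths.loc[sample]
        report = pd.DataFrame(
            {
                "name": matrix.genus_ids,
                "taxonomy_id": matrix.lineage["taxid"].to_numpy(),
                "taxonomy_lvl": "G",
                "kraken_assigned_reads": row.to_numpy(),
                "added_reads": 0,
                "new_est_reads": row.to_numpy(),
                "fraction_total_reads": (
                    row.to_numpy() / total if total > 0 else 0.0
                ),
            },
            columns=BRACKEN_COLUMNS,
        )
        path = dir_path / f"{sample}.bracken.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)

    meta_path = dir_path / "metadata.tsv"
    meta[META_COLUMNS].to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)

    lineage_path = dir_path / "lineage.tsv"
    matrix.lineage.rename_axis("name").reset_index().to_csv(
        lineage_path, sep="\t", index=False
    )
    written.append(lineage_path)
    return written
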