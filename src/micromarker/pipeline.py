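"""End-to-end orchestration: processing -> diversity -> differential
abundance -> networks -> risk classifier.

Stages communicate through on-disk TSV artifacts in the output directory
and every run writes ``manifest.json`` recording the full configuration,
every artifact with its SHA-256 content hash, and each defaulted
parameter actually used — so a rerun with the same configuration can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diff_abundance, diversity, network, preprocess, profiles, risk
from .containers import RESPONSE_NON_PCR, check_meta_alignment, response_vector
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "micromarker_out"
    input_dir: str | None = None  # None -> synthetic mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    rarefaction_depth: int | None = None  # None -> min post-filter depth
    prevalence_floor: float = preprocess.PREVALENCE_FLOOR
    contaminant_score_threshold: float = preprocess.CONTAM_RHO_MAX
    n_permutations: int = 999
    q_threshold: float = 0.05
    kw_alpha: float = 0.05
    lda_threshold: float = 3.0
    network_k: int = 150
    r_min: float = network.R_MIN
    edge_alpha: float = network.ALPHA
    candidate_genera: list[str] | None = None  # None -> Welch-significant genera
    marker_alpha: float = 0.05
    cell_fractions: str | None = None  # optional samples x cell-type TSV
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["log2_fold_changes"] = list(d["cohort"]["log2_fold_changes"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages in dependency order; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: dict[str, object] = {}

    # --- input -----------------------------------------------------------
    if config.input_dir is not None:
        matrix, meta = profiles.read_cohort_dir(config.input_dir)
        notes["input"] = str(config.input_dir)
    else:
        matrix, meta, truth = generate_cohort(config.cohort)
        truth_payload = {
            "differential_genera": truth.differential_genera,
            "contaminant_genera": sorted(truth.contaminant_genera),
            "nonbacterial_genera": sorted(truth.nonbacterial_genera),
        }
        _write_json(truth_payload, out / "cohort_truth.json")
        notes["input"] = "synthetic"
    meta = check_meta_alignment(matrix, meta)
    profiles.write_matrix_tsv(matrix, out / "counts_raw.tsv")
    profiles.write_metadata(meta, out / "metadata.tsv")
    _write_json(profiles.summarize_cohort(meta), out / "cohort_summary.json")

    # --- preprocessing ---------------------------------------------------
    matrix = preprocess.retain_bacteria(matrix)
    matrix, removed = preprocess.prevalence_contaminant_filter(
        matrix,
        prevalence_floor=config.prevalence_floor,
        score_threshold=config.contaminant_score_threshold,
    )
    removed.to_csv(out / "removed_genera.tsv", sep="\t", index=False)
    depth = config.rarefaction_depth
    if depth is None:
        depth = int(matrix.depths().min())
        notes["rarefaction_depth_defaulted_to_min"] = depth
        logger.info("rarefaction depth auto-set to minimum post-filter depth %d", depth)
    matrix = preprocess.rarefy(matrix, depth=depth, seed=config.seed + 1)
    meta = meta[meta["sample_id"].isin(matrix.sample_ids)].reset_index(drop=True)
    profiles.write_matrix_tsv(matrix, out / "counts_rarefied.tsv")
    relabund = preprocess.to_relative(matrix)
    relabund.rename_axis("sample_id").to_csv(out / "relative_abundance.tsv", sep="\t")
    labels = response_vector(meta, matrix.sample_ids)
    sets = preprocess.group_genus_sets(matrix, labels)
    _write_json(
        {k: v for k, v in sets.items() if k.endswith("count") or k == "groups"},
        out / "group_genus_sets.json",
    )

    # --- diversity -------------------------------------------------------
    shannon = diversity.shannon_per_sample(matrix)
    shannon.rename_axis("sample_id").to_csv(out / "shannon.tsv", sep="\t")
    alpha_test = diversity.compare_alpha(shannon.to_numpy(), labels)
    dist = diversity.jaccard_distance(matrix)
    dist.rename_axis("sample_id").to_csv(out / "jaccard_distance.tsv", sep="\t")
    ord_res = diversity.pcoa(dist, k=2)
    ord_res.coordinates.rename_axis("sample_id").to_csv(out / "pcoa.tsv", sep="\t")
    perm = diversity.permanova(dist, labels, n_perm=config.n_permutations, seed=config.seed + 2)
    pls = diversity.plsda(relabund, labels, n_components=2)
    pls.scores.rename_axis("sample_id").to_csv(out / "plsda_scores.tsv", sep="\t")
    _write_json(
        {
            "alpha": alpha_test,
            "permanova": dataclasses.asdict(perm),
            "pcoa_proportion_explained": ord_res.proportion_explained.tolist(),
            "plsda_explained_covariance": pls.explained_covariance.tolist(),
        },
        out / "diversity_tests.json",
    )

    # --- differential abundance -----------------------------------------
    welch = diff_abundance.welch_bh(relabund, labels, q_threshold=config.q_threshold)
    lefse = diff_abundance.lefse_like(
        relabund,
        labels,
        kw_alpha=config.kw_alpha,
        lda_threshold=config.lda_threshold,
        seed=config.seed + 3,
    )
    records = diff_abundance.merge_records(welch, lefse)
    records.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)

    # --- co-occurrence network ------------------------------------------
    k = min(config.network_k, relabund.shape[1])
    edges, top = network.top_abundance_subnetwork(
        relabund, k=k, r_min=config.r_min, alpha=config.edge_alpha
    )
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    summary = network.degrees(edges, nodes=top)
    summary.degrees.rename_axis("genus").rename("degree").to_csv(
        out / "network_degrees.tsv", sep="\t"
    )
    if config.cell_fractions is not None:
        cells = pd.read_csv(config.cell_fractions, sep="\t", index_col=0)
        cells = cells.loc[relabund.index]
        diff_genera = records.loc[records["sig_welch"], "genus"].tolist()
        cross = network.spearman_edges(
            relabund[diff_genera], cells, r_min=config.r_min, alpha=config.edge_alpha
        )
        cross.to_csv(out / "microbe_cell_edges.tsv", sep="\t", index=False)

    # --- risk classifier -------------------------------------------------
    candidates = config.candidate_genera
    if candidates is None:
        candidates = records.loc[records["sig_welch"], "genus"].tolist()
        notes["risk_candidates_defaulted_to_welch_significant"] = len(candidates)
    risk_payload: dict[str, object] = {"n_candidates": len(candidates)}
    if candidates:
        markers = risk.screen_markers(relabund, labels, candidates, alpha=config.marker_alpha)
        if markers:
            model = risk.build_risk_score(markers)
            model.save(out / "risk_model.tsv")
            scores = risk.score_samples(model, relabund)
            scores.rename_axis("sample_id").to_csv(out / "risk_scores.tsv", sep="\t")
            roc = risk.evaluate_score(scores, labels)
            risk_payload.update(
                {
                    "n_markers": len(markers),
                    "score_auc": roc.auc,
                    "score_auc_p": roc.p_value,
                    "positive_class": roc.positive_class,
                }
            )
            design = risk.clinical_design(meta, scores)
            outcome = (labels == RESPONSE_NON_PCR).astype(int)
            fit = risk.logistic_fit(design, outcome)
            fit.table.rename_axis("covariate").to_csv(out / "logistic_fit.tsv", sep="\t")
            risk_payload["logistic_converged"] = fit.converged
            risk_payload["logistic_separation"] = fit.separation
        else:
            risk_payload["n_markers"] = 0
            logger.warning("no markers survived screening; risk score skipped")
    _write_json(risk_payload, out / "risk_evaluation.json")

    # --- manifest --------------------------------------------------------
    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "notes": notes,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    _write_json(manifest, out / "manifest.json")
    return out
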