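"""Readers and writers for taxonomic profiles and sample metadata.

Supported dialects:

* Bracken genus report — tab-separated with columns ``name, taxonomy_id,
  taxonomy_lvl, kraken_assigned_reads, added_reads, new_est_reads,
  fraction_total_reads``; counts are taken from ``new_est_reads``.
* Kraken2 standard report (``kraken2=True``) — six unnamed columns
  (percent, clade reads, direct reads, rank code, taxid, name); genus rows
  carry rank code ``G`` and counts come from clade reads.
* Cohort count-matrix TSV — first column ``sample_id``, remaining columns
  genus names.
* Metadata TSV — ``sample_id, response, sex, age, grading, cT, cN`` with
  response in {pCR, non-pCR} (case-insensitive, normalized on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    META_COLUMNS,
    RESPONSE_NON_PCR,
    RESPONSE_PCR,
    CountMatrix,
    normalize_response,
)

logger = logging.getLogger(__name__)

_BRACKEN_REQUIRED = {"name", "taxonomy_lvl", "new_est_reads"}


def _round_counts(values: pd.Series, path) -> pd.Series:
    """Counts as integers; fractional estimates rounded half-to-even."""
    arr = pd.to_numeric(values, errors="raise")
    if not np.allclose(arr, np.round(arr)):
        logger.warning("fractional read counts in %s rounded half-to-even", path)
    return pd.Series(np.rint(arr).astype(np.int64), index=values.index)


def read_genus_report(path: str | Path, kraken2: bool = False) -> pd.DataFrame:
    """Read one per-sample taxonomic report, keeping genus-level rows only.

    Returns a DataFrame with columns ``genus, taxid, count``. Duplicate
    genus names within one file are summed with a warning (Bracken can
    repeat a name across lineages; identity is keyed by name + taxid when
    the ids differ).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty report file: {path}")
    if kraken2:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["percent", "clade_reads", "direct_reads", "rank", "taxid", "name"],
        )
        df["name"] = df["name"].astype(str).str.strip()
        genus = df[df["rank"].astype(str).str.strip() == "G"]
        out = pd.DataFrame(
            {
                "genus": genus["name"].to_numpy(),
                "taxid": genus["taxid"].astype(int).to_numpy(),
                "count": _round_counts(genus["clade_reads"], path).to_numpy(),
            }
        )
    else:
        df = pd.read_csv(path, sep="\t")
        missing = _BRACKEN_REQUIRED - set(df.columns)
        if missing:
            raise ValueError(
                f"malformed Bracken report {path}: missing column(s) {sorted(missing)}"
            )
        genus = df[df["taxonomy_lvl"].astype(str).str.strip() == "G"]
        taxid = (
            genus["taxonomy_id"].astype(int)
            if "taxonomy_id" in genus.columns
            else pd.Series(-1, index=genus.index)
        )
        out = pd.DataFrame(
            {
                "genus": genus["name"].astype(str).str.strip().to_numpy(),
                "taxid": taxid.to_numpy(),
                "count": _round_counts(genus["new_est_reads"], path).to_numpy(),
            }
        )
    if out["genus"].duplicated().any():
        # same (name, taxid) repeated, or same name across taxids: sum reads
        logger.warning(
            "duplicate genus names in %s summed: %s",
            path,
            sorted(out.loc[out["genus"].duplicated(), "genus"].unique()),
        )
        out = (
            out.groupby("genus", sort=False)
            .agg(taxid=("taxid", "first"), count=("count", "sum"))
            .reset_index()
        )
    return out


def read_lineage(path: str | Path) -> pd.DataFrame:
    """Read a genus lineage sidecar TSV (name, taxid, kingdom)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("name")[["kingdom", "taxid"]]


def assemble_matrix(
    reports: dict[str, pd.DataFrame], lineage: pd.DataFrame | None = None
) -> CountMatrix:
    """Assemble per-sample genus reports into one cohort count matrix.

    Genera are the union across samples (lexicographically ordered); a
    genus absent from a sample's report gets count zero.
    """
    if not reports:
        raise ValueError("at least one report is required")
    sample_ids = list(reports)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    genera = sorted(set().union(*(set(r["genus"]) for r in reports.values())))
    counts = pd.DataFrame(0, index=sample_ids, columns=genera, dtype=np.int64)
    taxids = {}
    for sample, rep in reports.items():
        counts.loc[sample, rep["genus"].to_numpy()] = rep["count"].to_numpy()
        taxids.update(dict(zip(rep["genus"], rep["taxid"])))
    if lineage is None:
        lineage = pd.DataFrame(
            {"kingdom": "", "taxid": [taxids.get(g, -1) for g in genera]}, index=genera
        )
    return CountMatrix(counts, lineage)


def read_cohort_dir(dir_path: str | Path, kraken2: bool = False) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a fixture directory of per-sample reports + metadata.tsv.

    Picks up ``lineage.tsv`` for kingdom annotation when present.
    """
    dir_path = Path(dir_path)
    reports = {
        p.name.removesuffix(".bracken.tsv"): read_genus_report(p, kraken2=kraken2)
        for p in sorted(dir_path.glob("*.bracken.tsv"))
    }
    lineage_path = dir_path / "lineage.tsv"
    lineage = read_lineage(lineage_path) if lineage_path.exists() else None
    matrix = assemble_matrix(reports, lineage=lineage)
    meta = read_metadata(dir_path / "metadata.tsv")
    return matrix, meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV, normalizing response labels."""
    meta = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "response"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing column(s): {sorted(missing)}")
    try:
        meta["response"] = meta["response"].map(normalize_response)
    except ValueError:
        bad = meta.loc[
            ~meta["response"]
            .astype(str)
            .str.strip()
            .str.lower()
            .isin({"pcr", "non-pcr", "nonpcr", "non_pcr"}),
            "sample_id",
        ].tolist()
        raise ValueError(f"unknown response label for sample(s): {bad}") from None
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta


def write_matrix_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, lineage: pd.DataFrame | None = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="sample_id")
    counts.index = counts.index.astype(str)
    return CountMatrix(counts.astype(np.int64), lineage)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def summarize_cohort(meta: pd.DataFrame) -> dict:
    """Cohort descriptives from metadata: response counts and percentages.

    Percentages are reported to one decimal, the convention of clinical
    baseline tables.
    """
    n = len(meta)
    if n == 0:
        raise ValueError("empty metadata")
    resp = meta["response"].map(normalize_response)
    n_pcr = int((resp == RESPONSE_PCR).sum())
    n_non = int((resp == RESPONSE_NON_PCR).sum())
    out = {
        "n_samples": n,
        "n_pcr": n_pcr,
        "n_non_pcr": n_non,
        "pct_pcr": round(100.0 * n_pcr / n, 1),
        "pct_non_pcr": round(100.0 * n_non / n, 1),
    }
    if "sex" in meta.columns:
        n_male = int((meta["sex"].astype(str).str.lower() == "male").sum())
        out["n_male"] = n_male
        out["pct_male"] = round(100.0 * n_male / n, 1)
    if "age" in meta.columns:
        out["median_age"] = float(meta["age"].median())
    return out
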