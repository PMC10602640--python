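"""Core in-memory containers shared across the pipeline.

A cohort is represented by a :class:`CountMatrix` (samples x genera read
counts with per-genus lineage annotation) joined to a sample-metadata
``pandas.DataFrame`` carrying the binary therapy-response label
(pCR / non-pCR) and clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSE_PCR = "pCR"
RESPONSE_NON_PCR = "non-pCR"

#: canonical metadata columns, in file order
META_COLUMNS = ["sample_id", "response", "sex", "age", "grading", "cT", "cN"]

_LABEL_ALIASES = {
    "pcr": RESPONSE_PCR,
    "non-pcr": RESPONSE_NON_PCR,
    "nonpcr": RESPONSE_NON_PCR,
    "non_pcr": RESPONSE_NON_PCR,
}


def normalize_response(label: str) -> str:
    """Map a case/punctuation variant of the response label to canonical form.

    Raises ``ValueError`` for anything that is not recognizably pCR or
    non-pCR.
    """
    key = str(label).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown response label: {label!r} (expected pCR or non-pCR)")
    return _LABEL_ALIASES[key]


@dataclass
class CountMatrix:
    """Samples x genera non-negative integer read counts.

    Attributes
    ----------
    counts
        DataFrame indexed by sample id, columns are genus names, integer
        dtype, no negative entries.
    lineage
        DataFrame indexed by genus name with columns ``kingdom`` and
        ``taxid``. Missing kingdoms are stored as empty strings.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate genus ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.lineage is None:
            self.lineage = pd.DataFrame(
                {"kingdom": "", "taxid": -1}, index=self.counts.columns
            )
        else:
            self.lineage = self.lineage.reindex(self.counts.columns)
            self.lineage["kingdom"] = self.lineage["kingdom"].fillna("")
            self.lineage["taxid"] = self.lineage["taxid"].fillna(-1).astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def select_genera(self, genera) -> "CountMatrix":
        genera = list(genera)
        return CountMatrix(self.counts[genera].copy(), self.lineage.loc[genera].copy())

    def select_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(sample_ids)].copy(), self.lineage.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


def check_meta_alignment(matrix: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Join metadata to a count matrix, erroring on missing samples.

    Returns metadata reindexed to the matrix sample order.
    """
    missing = [s for s in matrix.sample_ids if s not in set(meta["sample_id"])]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")
    return meta.set_index("sample_id").loc[matrix.sample_ids].reset_index()


def response_vector(meta: pd.DataFrame, sample_ids=None) -> np.ndarray:
    """Canonical response labels as an array aligned to ``sample_ids``."""
    idx = meta.set_index("sample_id")["response"]
    if sample_ids is not None:
        idx = idx.loc[list(sample_ids)]
    return idx.map(normalize_response).to_numpy()
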