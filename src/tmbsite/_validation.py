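"""Shared input-validation helpers for specimen-level DataFrames."""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

#: Canonical column order of the specimen dialect.
SPECIMEN_COLUMNS = [
    "specimen_id",
    "patient_id",
    "cancer_type",
    "biopsy_site",
    "collection_date",
    "tmb",
    "purity_pathologist",
    "purity_computational",
    "median_coverage",
    "is_primary_site",
]

MET_RECORD_COLUMNS = ["patient_id", "site", "record_date"]

VARIANT_COLUMNS = [
    "specimen_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "allele_frequency",
    "functional_class",
    "somatic_status",
]

FUNCTIONAL_CLASSES = {"nonsynonymous", "synonymous", "other"}
SOMATIC_STATUSES = {"somatic", "germline", "unknown"}


def require_columns(df: pd.DataFrame, columns: Iterable[str], what: str = "input") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def as_datetime(s: pd.Series) -> pd.Series:
    if pd.api.types.is_datetime64_any_dtype(s):
        return s
    return pd.to_datetime(s, format="ISO8601")
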