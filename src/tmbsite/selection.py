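"""Specimen selection and quality filters for the analysis cohort.

The pipeline order is frozen: latest specimen per patient, then the tumor
purity filter, then the per-cancer small-stratum drop (stratum sizes are
counted *after* the preceding filters). Each filter is a scikit-learn
transformer so the whole selection composes as a
``sklearn.pipeline.Pipeline``; plain functions wrap the transformers.
All filters return subsets of their input rows (records are never mutated)
and are idempotent.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from tmbsite._validation import as_datetime, require_columns

logger = logging.getLogger(__name__)

__all__ = [
    "LatestSpecimenSelector",
    "PurityFilter",
    "StratumSizeFilter",
    "PrimarySiteAnnotator",
    "select_latest_specimen",
    "apply_quality_filters",
    "drop_small_strata",
    "assign_primary_flag",
    "selection_pipeline",
]

DEFAULT_MIN_PURITY = 0.30
DEFAULT_MIN_STRATUM = 50


class _SpecimenTransformer(BaseEstimator, TransformerMixin):
    """Base: stateless row filters over specimen DataFrames."""

    _required: tuple[str, ...] = ()

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return True  # stateless: nothing is learned from data

    def _check(self, X: pd.DataFrame) -> None:
        require_columns(X, self._required, type(self).__name__)


class LatestSpecimenSelector(_SpecimenTransformer):
    """Keep one specimen per patient: the most recently collected.

    Date ties are broken deterministically by the lexicographically smallest
    ``specimen_id``.
    """

    _required = ("patient_id", "collection_date", "specimen_id")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        if len(X) == 0:
            return X.copy()
        order = X.assign(_date=as_datetime(X["collection_date"])).sort_values(
            ["_date", "specimen_id"], ascending=[False, True], kind="mergesort"
        )
        keep = order.drop_duplicates("patient_id", keep="first").index
        return X.loc[X.index.isin(keep)].copy()


class PurityFilter(_SpecimenTransformer):
    """Retain specimens with tumor purity >= ``min_purity`` (inclusive).

    The pathologist's purity estimate is used by default, since specimen
    adequacy review is a pathologist call; the column is configurable.
    """

    _required = ()

    def __init__(self, min_purity: float = DEFAULT_MIN_PURITY, purity_column: str = "purity_pathologist"):
        self.min_purity = min_purity
        self.purity_column = purity_column

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        require_columns(X, [self.purity_column], "PurityFilter")
        out = X[X[self.purity_column] >= self.min_purity].copy()
        n_removed = len(X) - len(out)
        if n_removed:
            logger.info("purity filter (>=%.2f): removed %d of %d specimens", self.min_purity, n_removed, len(X))
        return out


class StratumSizeFilter(_SpecimenTransformer):
    """Drop, within each cancer type independently, all specimens of a
    biopsy-site stratum with fewer than ``min_n`` specimens (a 50-specimen
    stratum survives; 49 does not)."""

    _required = ("cancer_type", "biopsy_site")

    def __init__(self, min_n: int = DEFAULT_MIN_STRATUM):
        self.min_n = min_n

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        if len(X) == 0:
            return X.copy()
        sizes = X.groupby(["cancer_type", "biopsy_site"], sort=False)["biopsy_site"].transform("size")
        out = X[sizes >= self.min_n].copy()
        n_removed = len(X) - len(out)
        if n_removed:
            logger.info("stratum-size filter (>=%d): removed %d specimens", self.min_n, n_removed)
        return out


class PrimarySiteAnnotator(_SpecimenTransformer):
    """Set ``is_primary_site`` from a manually curated cancer-type -> primary-site map."""

    _required = ("cancer_type", "biopsy_site")

    def __init__(self, site_map: Mapping[str, str] | None = None):
        self.site_map = site_map

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        site_map = dict(self.site_map or {})
        missing = sorted(set(X["cancer_type"].unique()) - set(site_map))
        if missing:
            raise ValueError(
                "primary-site map is missing cancer type(s): " + ", ".join(missing)
            )
        out = X.copy()
        out["is_primary_site"] = out["biopsy_site"] == out["cancer_type"].map(site_map)
        return out


def select_latest_specimen(specimens: pd.DataFrame) -> pd.DataFrame:
    """Most recently collected specimen per patient (ties: smallest specimen_id)."""
    return LatestSpecimenSelector().transform(specimens)


def apply_quality_filters(
    specimens: pd.DataFrame,
    min_purity: float = DEFAULT_MIN_PURITY,
    purity_column: str = "purity_pathologist",
) -> pd.DataFrame:
    """Purity filter: keep specimens with purity >= ``min_purity``."""
    return PurityFilter(min_purity, purity_column).transform(specimens)


def drop_small_strata(specimens: pd.DataFrame, min_n: int = DEFAULT_MIN_STRATUM) -> pd.DataFrame:
    """Per-cancer drop of biopsy-site strata with fewer than ``min_n`` specimens."""
    return StratumSizeFilter(min_n).transform(specimens)


def assign_primary_flag(specimens: pd.DataFrame, site_map: Mapping[str, str]) -> pd.DataFrame:
    """Flag specimens whose biopsy site is the curated primary site of their cancer."""
    return PrimarySiteAnnotator(site_map).transform(specimens)


def selection_pipeline(
    min_purity: float = DEFAULT_MIN_PURITY,
    min_stratum: int = DEFAULT_MIN_STRATUM,
    site_map: Mapping[str, str] | None = None,
) -> Pipeline:
    """The frozen selection pipeline: latest -> purity -> stratum size (-> primary flag)."""
    steps = [
        ("latest", LatestSpecimenSelector()),
        ("purity", PurityFilter(min_purity)),
        ("stratum", StratumSizeFilter(min_stratum)),
    ]
    if site_map is not None:
        steps.append(("primary", PrimarySiteAnnotator(site_map)))
    return Pipeline(steps)
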