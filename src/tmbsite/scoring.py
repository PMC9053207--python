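"""TMB scoring from variant-level calls.

The TMB score is the number of somatic nonsynonymous mutations per megabase
of sequenced coding territory (mut/Mb). Calls below the allele-frequency
threshold (default 5%) are treated as noise and excluded; calls at exactly
the threshold count. A specimen is TMB-high when its score reaches the
pan-tumor clinical cutoff of 10 mut/Mb (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from tmbsite._validation import require_columns

__all__ = ["PanelSpec", "score_tmb", "classify_tmb_high", "TMBScorer"]

TMB_HIGH_CUTOFF = 10.0  # mut/Mb, pan-tumor clinical threshold
DEFAULT_AF_THRESHOLD = 0.05


@dataclass(frozen=True)
class PanelSpec:
    """Sequencing panel denominator.

    effective_megabases : Mb of coding territory over which mutations are
    counted. Panels differ (the denominator is assay-specific), so this is
    a required input, never a hard-coded constant.
    """

    effective_megabases: float

    def __post_init__(self) -> None:
        if not self.effective_megabases > 0:
            raise ValueError(
                f"effective_megabases must be positive, got {self.effective_megabases}"
            )


def _qualifying_mask(variants: pd.DataFrame, af_threshold: float) -> pd.Series:
    return (
        (variants["somatic_status"] == "somatic")
        & (variants["functional_class"] == "nonsynonymous")
        & (variants["allele_frequency"] >= af_threshold)
    )


def score_tmb(
    variants: pd.DataFrame,
    panel: PanelSpec,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> float:
    """TMB score (mut/Mb) for the variants of a single specimen.

    Counts calls that are somatic, nonsynonymous, and at allele frequency
    >= ``af_threshold``, divided by the panel's effective megabases. An
    empty variant list scores 0.

    Raises
    ------
    ValueError
        If the variants span more than one ``specimen_id``.
    """
    if len(variants) == 0:
        return 0.0
    require_columns(
        variants,
        ["specimen_id", "allele_frequency", "functional_class", "somatic_status"],
        "variant table",
    )
    ids = variants["specimen_id"].unique()
    if len(ids) > 1:
        raise ValueError(
            f"score_tmb expects variants from one specimen; got {len(ids)} specimen_ids"
        )
    af = variants["allele_frequency"]
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele_frequency must lie in [0, 1]")
    n = int(_qualifying_mask(variants, af_threshold).sum())
    return n / panel.effective_megabases


def classify_tmb_high(score: float, cutoff: float = TMB_HIGH_CUTOFF) -> str:
    """Classify a TMB score as ``"high"`` (score >= cutoff) or ``"low"``."""
    if score < 0:
        raise ValueError(f"TMB score must be non-negative, got {score}")
    return "high" if score >= cutoff else "low"


class TMBScorer(BaseEstimator, TransformerMixin):
    """Transformer: variant table -> per-specimen TMB scores and status.

    Parameters
    ----------
    panel_mb : float
        Effective panel size in megabases.
    af_threshold : float
        Minimum allele frequency for a call to count.
    cutoff : float
        TMB-high threshold in mut/Mb.
    specimen_ids : iterable of str, optional
        Specimens to score even if they have no variants (scored 0).
    """

    def __init__(
        self,
        panel_mb: float = 1.1,
        af_threshold: float = DEFAULT_AF_THRESHOLD,
        cutoff: float = TMB_HIGH_CUTOFF,
        specimen_ids: Iterable[str] | None = None,
    ):
        self.panel_mb = panel_mb
        self.af_threshold = af_threshold
        self.cutoff = cutoff
        self.specimen_ids = specimen_ids

    def fit(self, X: pd.DataFrame, y=None) -> "TMBScorer":
        PanelSpec(self.panel_mb)  # validates
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score every specimen present in the variant table ``X``."""
        PanelSpec(self.panel_mb)
        if len(X):
            require_columns(
                X,
                ["specimen_id", "allele_frequency", "functional_class", "somatic_status"],
                "variant table",
            )
            counts = (
                X[_qualifying_mask(X, self.af_threshold)]
                .groupby("specimen_id", sort=True)
                .size()
            )
            all_ids = pd.Index(X["specimen_id"].unique(), name="specimen_id").sort_values()
            counts = counts.reindex(all_ids, fill_value=0)
        else:
            counts = pd.Series(dtype=int, name="n").rename_axis("specimen_id")
        if self.specimen_ids is not None:
            counts = counts.reindex(
                pd.Index(sorted(self.specimen_ids), name="specimen_id"), fill_value=0
            )
        tmb = counts / self.panel_mb
        out = pd.DataFrame(
            {
                "specimen_id": tmb.index,
                "tmb": tmb.to_numpy(dtype=float),
            }
        )
        out["tmb_status"] = np.where(out["tmb"] >= self.cutoff, "high", "low")
        return out.reset_index(drop=True)
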