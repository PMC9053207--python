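"""Table I/O, run configuration, and the end-to-end pipeline.

One canonical tabular dialect: UTF-8, tab-separated, documented headers,
ISO-8601 dates (CSV is sniffed and accepted on read). Variants are also
readable/writable as minimal VCF with ``AF`` (allele frequency), ``FC``
(functional class), and ``SS`` (somatic status) INFO keys.

Every threshold the pipeline uses is carried in :class:`RunConfig` and
echoed into the run manifest together with specimen counts after each
filter step, so a run is auditable end to end.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from tmbsite import __version__ as _pkg_version
from tmbsite._validation import (
    MET_RECORD_COLUMNS,
    SPECIMEN_COLUMNS,
    VARIANT_COLUMNS,
    require_columns,
)
from tmbsite.dichotomous import compare_sites, site_distribution, tabulate_high
from tmbsite.emm import run_all
from tmbsite.scoring import TMBScorer
from tmbsite.selection import selection_pipeline
from tmbsite.stratified import find_biopsy_pairs, paired_site_test, run_met_controlled

logger = logging.getLogger(__name__)

__all__ = [
    "DIALECT_VERSION",
    "RunConfig",
    "read_specimen_table",
    "write_specimen_table",
    "read_met_records",
    "write_met_records",
    "read_variant_table",
    "write_variant_table",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_site_map",
    "run_pipeline",
]

DIALECT_VERSION = "tmbsite-tables-v1"

_SPECIMEN_BOUNDS = {
    "purity_pathologist": (0.0, 1.0),
    "purity_computational": (0.0, 1.0),
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read the canonical TSV dialect; fall back to comma separation."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"specimen_id": str, "patient_id": str})


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Read a specimen table, validating types and invariants.

    Rows violating invariants (purity outside [0, 1], negative TMB,
    non-positive coverage) are rejected and reported with their file line
    numbers; unparseable dates or numbers raise with the offending line.
    """
    df = _read_delimited(path)
    require_columns(df, [c for c in SPECIMEN_COLUMNS if c != "is_primary_site"], str(path))
    # line numbers: header is line 1
    lines = df.index + 2
    try:
        df["collection_date"] = pd.to_datetime(df["collection_date"], format="ISO8601")
    except ValueError as e:
        raise ValueError(f"{path}: unparseable collection_date: {e}") from e
    for col in ["tmb", "purity_pathologist", "purity_computational", "median_coverage"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: unparseable number in column {col!r} at line(s) "
                + ", ".join(map(str, lines[bad]))
            )
        df[col] = converted
    ok = (
        df["purity_pathologist"].between(0, 1)
        & df["purity_computational"].between(0, 1)
        & (df["tmb"] >= 0)
        & (df["median_coverage"] > 0)
    )
    if (~ok).any():
        logger.warning(
            "%s: rejected %d row(s) violating invariants at line(s) %s",
            path,
            int((~ok).sum()),
            ", ".join(map(str, lines[~ok])),
        )
        df = df[ok]
    if "is_primary_site" in df.columns:
        df["is_primary_site"] = df["is_primary_site"].astype(bool)
    return df.reset_index(drop=True)


def write_specimen_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["collection_date"] = pd.to_datetime(out["collection_date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in SPECIMEN_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_met_records(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    require_columns(df, MET_RECORD_COLUMNS, str(path))
    df["record_date"] = pd.to_datetime(df["record_date"], format="ISO8601")
    return df[MET_RECORD_COLUMNS]


def write_met_records(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["record_date"] = pd.to_datetime(out["record_date"]).dt.strftime("%Y-%m-%d")
    out[MET_RECORD_COLUMNS].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    require_columns(
        df, ["specimen_id", "allele_frequency", "functional_class", "somatic_status"], str(path)
    )
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, encoding="utf-8")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tmbsite
##INFO=<ID=SPECIMEN,Number=1,Type=String,Description="Specimen identifier">
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">
##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">
##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Write variants as minimal text VCF (one record per call)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for r in df.itertuples(index=False):
            info = (
                f"SPECIMEN={r.specimen_id};AF={r.allele_frequency:g};"
                f"FC={r.functional_class};SS={r.somatic_status}"
            )
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\n")


def read_variants_vcf(
    path: str | Path,
    af_key: str = "AF",
    class_key: str = "FC",
    status_key: str = "SS",
    specimen_key: str = "SPECIMEN",
) -> pd.DataFrame:
    """Read variants from a (possibly multi-specimen) VCF via cyvcf2.

    INFO keys for allele frequency, functional class, somatic status, and
    specimen id are configurable; missing class/status default to
    ``nonsynonymous``/``somatic`` so plain somatic VCFs can be scored.
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        rows.append(
            {
                "specimen_id": v.INFO.get(specimen_key) or "unknown",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "allele_frequency": float(v.INFO.get(af_key, 0.0)),
                "functional_class": v.INFO.get(class_key) or "nonsynonymous",
                "somatic_status": v.INFO.get(status_key) or "somatic",
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_site_map(path: str | Path) -> dict[str, str]:
    """Two-column delimited file: cancer_type <tab> primary site."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: site map needs two columns (cancer_type, primary_site)")
    c0, c1 = df.columns[:2]
    return dict(zip(df[c0].astype(str), df[c1].astype(str)))


class RunConfig(BaseModel):
    """Every path and threshold of a pipeline run, in one audited place."""

    specimens: str
    site_map: str
    met_records: str | None = None
    variants: str | None = None
    output_dir: str = "tmbsite_results"

    panel_mb: float = Field(1.1, gt=0)
    af_threshold: float = Field(0.05, ge=0, le=1)
    min_purity: float = Field(0.30, ge=0, le=1)
    min_stratum: int = Field(50, ge=0)
    tmb_high_cutoff: float = Field(10.0, ge=0)
    min_cell: int = Field(10, ge=0)
    window_days: int = Field(90, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    adjust: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write result tables plus a manifest.

    Stages: read -> (optional variant scoring) -> specimen selection ->
    per-cancer EMM contrasts -> dichotomous TMB-high comparisons ->
    met-history-controlled contrasts (if records given) -> paired-biopsy
    tests. Identical config + inputs give identical outputs.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dialect": DIALECT_VERSION,
        "package_version": _pkg_version,
        "config": config.model_dump(),
        "counts": {},
    }

    specimens = read_specimen_table(config.specimens)
    site_map = read_site_map(config.site_map)
    manifest["counts"]["input_specimens"] = len(specimens)

    if config.variants:
        variants = (
            read_variants_vcf(config.variants)
            if str(config.variants).endswith(".vcf")
            else read_variant_table(config.variants)
        )
        scores = TMBScorer(
            panel_mb=config.panel_mb,
            af_threshold=config.af_threshold,
            cutoff=config.tmb_high_cutoff,
            specimen_ids=specimens["specimen_id"],
        ).transform(variants)
        specimens = specimens.drop(columns=["tmb"], errors="ignore").merge(
            scores[["specimen_id", "tmb"]], on="specimen_id", how="left"
        )
        manifest["counts"]["scored_specimens"] = int(specimens["tmb"].notna().sum())

    pipe = selection_pipeline(config.min_purity, config.min_stratum, site_map)
    staged = specimens
    for name, step in pipe.steps:
        staged = step.transform(staged)
        manifest["counts"][f"after_{name}"] = len(staged)
    cohort = staged

    contrasts = run_all(cohort, site_map, alpha=config.alpha, adjust=config.adjust)
    contrasts.to_csv(outdir / "emm_contrasts.tsv", sep="\t", index=False)

    dist = site_distribution(cohort)
    dist.to_csv(outdir / "site_distribution.tsv", sep="\t", index=False)

    counts = tabulate_high(cohort, cutoff=config.tmb_high_cutoff)
    cat = compare_sites(counts, site_map, min_cell=config.min_cell, alpha=config.alpha)
    counts.to_csv(outdir / "tmb_high_counts.tsv", sep="\t", index=False)
    cat.to_csv(outdir / "tmb_high_comparisons.tsv", sep="\t", index=False)

    if config.met_records:
        met = read_met_records(config.met_records)
        target_sites = {
            c: sorted(
                set(cohort.loc[cohort["cancer_type"] == c, "biopsy_site"]) - {site_map[c]}
            )
            for c in cohort["cancer_type"].unique()
            if c in site_map
        }
        met_con = run_met_controlled(
            cohort, met, site_map, target_sites, alpha=config.alpha
        )
        met_con.to_csv(outdir / "met_controlled_contrasts.tsv", sep="\t", index=False)
        manifest["counts"]["met_records"] = len(met)

    pairs = find_biopsy_pairs(specimens, window_days=config.window_days)
    pairs.to_csv(outdir / "biopsy_pairs.tsv", sep="\t", index=False)
    manifest["counts"]["biopsy_pairs"] = len(pairs)
    paired_rows = []
    for (sa, sb), sub in pairs.groupby(["site_a", "site_b"]):
        res = paired_site_test(sub)
        paired_rows.append(
            {
                "site_a": sa,
                "site_b": sb,
                "n_pairs": res.n,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "tested": res.tested,
                "reason": res.reason,
            }
        )
    pd.DataFrame(
        paired_rows,
        columns=["site_a", "site_b", "n_pairs", "statistic", "p_value", "method", "tested", "reason"],
    ).to_csv(outdir / "paired_tests.tsv", sep="\t", index=False)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
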