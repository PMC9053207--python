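import numpy as np
import pandas as pd
import pytest

from tmbsite import CohortConfig, SiteEffectSpec, generate_cohort


def make_specimens(rows) -> pd.DataFrame:
    """Build a specimen table from (sid, pid, cancer, site, date, tmb, pp, pc, cov) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "patient_id",
            "cancer_type",
            "biopsy_site",
            "collection_date",
            "tmb",
            "purity_pathologist",
            "purity_computational",
            "median_coverage",
        ],
    )
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    df["is_primary_site"] = False
    return df


@pytest.fixture
def two_site_config() -> CohortConfig:
    return CohortConfig(
        site_effects=[
            SiteEffectSpec(cancer_type="NSCLC", site="lung", is_primary=True, n_specimens=400),
            SiteEffectSpec(cancer_type="NSCLC", site="brain", delta_log=0.3, n_specimens=300),
        ],
        seed=7,
    )


@pytest.fixture
def small_cohort(two_site_config):
    return generate_cohort(two_site_config)


@pytest.fixture
def ols_fixture() -> pd.DataFrame:
    """Six specimens, two sites, one real covariate — fixed values for oracle checks."""
    return make_specimens(
        [
            ("S1", "P1", "X", "a", "2019-01-01", 3.0, 0.5, 0.5, 480.0),
            ("S2", "P2", "X", "a", "2019-01-02", 5.5, 0.6, 0.55, 510.0),
            ("S3", "P3", "X", "a", "2019-01-03", 8.0, 0.7, 0.65, 650.0),
            ("S4", "P4", "X", "b", "2019-01-04", 11.0, 0.45, 0.5, 530.0),
            ("S5", "P5", "X", "b", "2019-01-05", 14.5, 0.8, 0.75, 505.0),
            ("S6", "P6", "X", "b", "2019-01-06", 6.0, 0.55, 0.6, 470.0),
        ]
    )


def random_stratum(rng: np.random.Generator, n: int, n_sites: int = 3) -> pd.DataFrame:
    sites = [f"site{i}" for i in range(n_sites)]
    df = make_specimens(
        [
            (
                f"S{i}",
                f"P{i}",
                "X",
                sites[int(rng.integers(n_sites))],
                "2019-01-01",
                float(np.round(rng.lognormal(1.5, 0.7), 3)),
                float(rng.uniform(0.3, 1.0)),
                float(rng.uniform(0.3, 1.0)),
                float(rng.normal(500, 80)),
            )
            for i in range(n)
        ]
    )
    return df
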