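"""Met-history control, biopsy pairing, exact signed-rank test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers_oracle as oracle
from conftest import make_specimens
from tmbsite import CohortConfig, SiteEffectSpec, generate_cohort
from tmbsite.stratified import (
    exact_signed_rank,
    filter_by_met_history,
    find_biopsy_pairs,
    paired_site_test,
    run_met_controlled,
)


def _primary(sid, pid, date, tmb=5.0):
    df = make_specimens([(sid, pid, "NSCLC", "lung", date, tmb, 0.6, 0.6, 500.0)])
    df["is_primary_site"] = True
    return df


def _met(sid, pid, date, site="brain", tmb=8.0):
    return make_specimens([(sid, pid, "NSCLC", site, date, tmb, 0.6, 0.6, 500.0)])


def _recs(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "site", "record_date"])
    df["record_date"] = pd.to_datetime(df["record_date"])
    return df


class TestMetHistoryFilter:
    def test_primary_without_record_excluded(self):
        spec = pd.concat([_primary("S1", "P1", "2019-01-01"), _met("S2", "P2", "2019-01-01")])
        out = filter_by_met_history(spec, _recs([]), "brain")
        assert set(out["specimen_id"]) == {"S2"}

    def test_record_after_collection_excluded(self):
        spec = _primary("S1", "P1", "2019-01-01")
        out = filter_by_met_history(spec, _recs([("P1", "brain", "2019-02-01")]), "brain")
        assert len(out) == 0

    def test_record_one_day_before_included(self):
        spec = _primary("S1", "P1", "2019-01-02")
        out = filter_by_met_history(spec, _recs([("P1", "brain", "2019-01-01")]), "brain")
        assert set(out["specimen_id"]) == {"S1"}

    def test_record_at_other_site_does_not_qualify(self):
        spec = _primary("S1", "P1", "2019-06-01")
        out = filter_by_met_history(spec, _recs([("P1", "liver", "2019-01-01")]), "brain")
        assert len(out) == 0

    def test_target_site_specimens_pass_unchanged_and_output_is_subset(self):
        spec = pd.concat(
            [_primary("S1", "P1", "2019-01-01"), _met("S2", "P2", "2019-01-01"),
             _met("S3", "P3", "2019-01-01", site="liver")]
        )
        out = filter_by_met_history(spec, _recs([]), "brain")
        assert set(out["specimen_id"]) == {"S2"}
        assert set(out["specimen_id"]) <= set(spec["specimen_id"])


class TestFindBiopsyPairs:
    def _two(self, d1, d2, s1="lung", s2="brain"):
        return make_specimens(
            [
                ("S1", "P1", "NSCLC", s1, d1, 4.0, 0.6, 0.6, 500.0),
                ("S2", "P1", "NSCLC", s2, d2, 9.0, 0.6, 0.6, 500.0),
            ]
        )

    def test_gap_90_in_91_out(self):
        assert len(find_biopsy_pairs(self._two("2019-01-01", "2019-04-01"))) == 1  # 90 days
        assert len(find_biopsy_pairs(self._two("2019-01-01", "2019-04-02"))) == 0  # 91 days

    def test_same_site_pairs_excluded(self):
        assert len(find_biopsy_pairs(self._two("2019-01-01", "2019-01-11", s2="lung"))) == 0

    def test_minimal_gap_pair_chosen(self):
        spec = make_specimens(
            [
                ("S1", "P1", "NSCLC", "lung", "2019-01-01", 4.0, 0.6, 0.6, 500.0),
                ("S2", "P1", "NSCLC", "brain", "2019-03-01", 9.0, 0.6, 0.6, 500.0),
                ("S3", "P1", "NSCLC", "brain", "2019-01-10", 7.0, 0.6, 0.6, 500.0),
            ]
        )
        out = find_biopsy_pairs(spec)
        assert len(out) == 1
        assert out.iloc[0]["gap_days"] == 9
        # S3 (the 9-day brain specimen) is chosen over S2 (59 days away)
        assert 7.0 in {out.iloc[0]["tmb_a"], out.iloc[0]["tmb_b"]}

    def test_invariant_to_row_order(self):
        spec = make_specimens(
            [
                ("S1", "P1", "NSCLC", "lung", "2019-01-01", 4.0, 0.6, 0.6, 500.0),
                ("S2", "P1", "NSCLC", "brain", "2019-02-01", 9.0, 0.6, 0.6, 500.0),
                ("S3", "P2", "NSCLC", "lung", "2019-05-01", 3.0, 0.6, 0.6, 500.0),
                ("S4", "P2", "NSCLC", "liver", "2019-05-20", 6.0, 0.6, 0.6, 500.0),
            ]
        )
        a = find_biopsy_pairs(spec)
        b = find_biopsy_pairs(spec.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_site_pair_orientation(self):
        out = find_biopsy_pairs(self._two("2019-01-01", "2019-01-20"), site_pair=("brain", "lung"))
        assert out.iloc[0]["site_a"] == "brain" and out.iloc[0]["tmb_a"] == 9.0


class TestPairedTest:
    def test_nine_all_positive_exact_p(self):
        w, p, n = exact_signed_rank(np.arange(1.0, 10.0))
        assert p == 2 / 512
        assert n == 9

    def test_symmetric_differences_give_p_one(self):
        pairs = pd.DataFrame({"tmb_a": [5.0, 1.0, 6.0, 2.0], "tmb_b": [1.0, 5.0, 2.0, 6.0]})
        res = paired_site_test(pairs)
        assert res.p_value == pytest.approx(1.0)

    def test_single_pair_not_tested(self):
        res = paired_site_test(pd.DataFrame({"tmb_a": [5.0], "tmb_b": [1.0]}))
        assert not res.tested and "fewer than 2" in res.reason

    def test_all_zero_differences_not_tested(self):
        res = paired_site_test(pd.DataFrame({"tmb_a": [5.0, 3.0], "tmb_b": [5.0, 3.0]}))
        assert not res.tested

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.integers(-20, 20).filter(lambda v: v != 0), min_size=2, max_size=12
        ).map(lambda xs: np.array(xs, float) / 2.0)
    )
    def test_exact_p_matches_full_enumeration(self, diffs):
        _, p, _ = exact_signed_rank(diffs)
        assert p == pytest.approx(oracle.brute_force_signed_rank_p(diffs), abs=1e-12)

    def test_t_log_method(self):
        pairs = pd.DataFrame({"tmb_a": [8.0, 9.0, 12.0, 7.0], "tmb_b": [4.0, 5.0, 6.0, 3.0]})
        res = paired_site_test(pairs, method="t-log")
        assert res.tested and res.p_value < 0.05


class TestMetControlled:
    def _config(self, boost):
        return CohortConfig(
            site_effects=[
                SiteEffectSpec(cancer_type="NSCLC", site="lung", is_primary=True, n_specimens=600),
                SiteEffectSpec(cancer_type="NSCLC", site="brain", delta_log=0.4, n_specimens=400),
            ],
            beta_coverage=0.0,
            beta_purity_path=0.0,
            beta_purity_comp=0.0,
            multi_specimen_prob=0.0,
            met_prob=0.4,
            met_tmb_boost_log=boost,
            seed=21,
        )

    def test_no_confounding_met_controlled_matches_unrestricted(self):
        spec, _, met = generate_cohort(self._config(0.0), include_variants=False)
        full = run_met_controlled(spec, met, {"NSCLC": "lung"}, {"NSCLC": ["brain"]})
        from tmbsite.emm import run_all

        unres = run_all(spec, {"NSCLC": "lung"})
        e_ctrl = full.iloc[0]["estimate"]
        e_unres = unres.set_index("site").loc["brain", "estimate"]
        assert e_ctrl == pytest.approx(e_unres, abs=1.0)
        assert np.sign(e_ctrl) == np.sign(e_unres) == 1

    def test_constructed_confounder_is_removed(self):
        # met-bearing primary patients share the site's elevation: controlling
        # for metastasis history should null the contrast
        spec, _, met = generate_cohort(self._config(0.4), include_variants=False)
        ctrl = run_met_controlled(spec, met, {"NSCLC": "lung"}, {"NSCLC": ["brain"]})
        ci_lo, ci_hi = ctrl.iloc[0][["ci_low", "ci_high"]]
        assert ci_lo < 0 < ci_hi or abs(ctrl.iloc[0]["estimate"]) < 0.8

    def test_no_eligible_primaries_skips_stratum(self):
        spec = pd.concat(
            [_primary("S1", "P1", "2019-01-01"), _met("S2", "P2", "2019-01-01")]
        )
        out = run_met_controlled(spec, _recs([]), {"NSCLC": "lung"}, {"NSCLC": ["brain"]})
        assert len(out) == 0
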