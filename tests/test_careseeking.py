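"""Eligibility filtering, ANC4+ coverage, care-seeking strata, covariate rates."""

import math

import numpy as np
import pandas as pd
import pytest

import covlink as cl

from conftest import make_women, weighted_mean_oracle


class TestFilterEligible:
    def test_recall_window_boundary(self):
        df = make_women([{"months_since_birth": m} for m in (12, 35, 36, 48)])
        kept = cl.filter_eligible(df)
        assert sorted(kept["months_since_birth"]) == [12, 35]
        assert kept.attrs["n_excluded"] == 2

    def test_empty_input(self):
        df = make_women([]).iloc[:0]
        kept = cl.filter_eligible(df)
        assert len(kept) == 0

    def test_negative_months_rejected(self):
        df = make_women([{"months_since_birth": -1}, {"months_since_birth": 2}])
        kept = cl.filter_eligible(df)
        assert list(kept["months_since_birth"]) == [2]

    def test_idempotent(self):
        cfg = cl.default_sim_config(n_clusters=10, women_per_cluster=10, seed=3)
        df = cl.generate_household_survey(cfg)
        once = cl.filter_eligible(df)
        twice = cl.filter_eligible(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_uniform_months_keep_rate(self):
        # uniform 0-59 months: expect ~60% kept at n=1000
        cfg = cl.default_sim_config(n_clusters=50, women_per_cluster=20, seed=8)
        df = cl.generate_household_survey(cfg)
        kept = cl.filter_eligible(df)
        se = math.sqrt(0.6 * 0.4 / 1000)
        assert abs(len(kept) / 1000 - 0.6) < 3 * se

    def test_duplicate_woman_id_raises(self):
        df = make_women([{}, {}])
        df["woman_id"] = ["w0", "w0"]
        with pytest.raises(ValueError, match="duplicate"):
            cl.filter_eligible(df)


class TestAnc4Coverage:
    def test_equal_weights(self):
        df = make_women([{"anc_visits": v} for v in (4, 3, 5)])
        assert cl.anc4_coverage(df) == pytest.approx(2 / 3)

    def test_all_attend(self):
        df = make_women([{"anc_visits": v} for v in (4, 6, 8)])
        assert cl.anc4_coverage(df) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cl.anc4_coverage(make_women([]).iloc[:0])

    def test_matches_weighted_oracle(self, rng):
        df = make_women(
            [
                {"anc_visits": int(rng.integers(0, 9)), "weight": float(rng.uniform(0.1, 4.0))}
                for _ in range(500)
            ]
        )
        oracle = weighted_mean_oracle((df["anc_visits"] >= 4).tolist(), df["weight"].tolist())
        assert cl.anc4_coverage(df) == pytest.approx(oracle, abs=1e-12)

    def test_weight_scale_invariance(self, rng):
        df = make_women(
            [{"anc_visits": int(rng.integers(0, 9)), "weight": float(rng.uniform(0.5, 2.0))}
             for _ in range(100)]
        )
        scaled = df.assign(weight=df["weight"] * 37.5)
        assert cl.anc4_coverage(df) == pytest.approx(cl.anc4_coverage(scaled), abs=1e-12)


class TestStratumCareseeking:
    def test_hand_count(self):
        rows = []
        for _ in range(3):
            rows.append({"anc_visits": 4, "source_type": "hospital",
                         "source_authority": "public", "residence": "urban"})
        for _ in range(3):
            rows.append({"anc_visits": 5, "source_type": "health_center",
                         "source_authority": "public", "residence": "rural"})
        rows += [{"anc_visits": v} for v in (0, 1, 2, 3)]
        table = cl.stratum_careseeking(make_women(rows))
        assert table.shares[("hospital", "public", "urban")] == pytest.approx(0.3)
        assert table.shares[("health_center", "public", "rural")] == pytest.approx(0.3)
        assert table.anc4_coverage == pytest.approx(0.6)
        assert table.non_facility_share == pytest.approx(0.0)

    def test_no_anc4_women_gives_empty_table(self):
        table = cl.stratum_careseeking(make_women([{"anc_visits": 2}, {"anc_visits": 0}]))
        assert len(table.shares) == 0
        assert table.anc4_coverage == 0.0

    def test_null_source_goes_to_non_facility_bucket(self):
        rows = [
            {"anc_visits": 4, "source_type": "hospital", "source_authority": "public",
             "residence": "urban"},
            {"anc_visits": 6},  # ANC4+ but no facility source
            {"anc_visits": 1},
        ]
        table = cl.stratum_careseeking(make_women(rows))
        assert table.non_facility_share == pytest.approx(1 / 3)
        assert float(table.shares.sum()) == pytest.approx(1 / 3)

    def test_partition_property(self, rng):
        cfg = cl.default_sim_config(n_clusters=40, women_per_cluster=20, seed=13)
        df = cl.filter_eligible(cl.generate_household_survey(cfg))
        table = cl.stratum_careseeking(df)
        total = float(table.shares.sum()) + table.non_facility_share
        assert total == pytest.approx(table.anc4_coverage, abs=1e-10)
        assert table.anc4_coverage == pytest.approx(cl.anc4_coverage(df), abs=1e-12)

    def test_generator_consistency(self):
        cfg = cl.default_sim_config(n_clusters=100, women_per_cluster=20, seed=21)
        df = cl.filter_eligible(cl.generate_household_survey(cfg))
        table = cl.stratum_careseeking(df)
        n = len(df)
        for stratum, share in cfg.careseeking_shares.items():
            if stratum == cl.NON_FACILITY:
                continue
            expected = cfg.p_anc4 * share
            se = math.sqrt(expected * (1 - expected) / n) * 1.2  # weight design effect
            assert abs(table.shares.get(stratum, 0.0) - expected) < 3 * se


class TestCovariateRates:
    def test_early_anc_month_boundary(self):
        rows = [
            {"anc_visits": 1, "first_visit_month": 2},
            {"anc_visits": 1, "first_visit_month": 4},
            {"anc_visits": 1, "first_visit_month": 5},
            {"anc_visits": 0},
        ]
        covs = cl.covariate_rates(make_women(rows))
        assert covs.early_anc_rate == pytest.approx(0.5)

    def test_all_components_received(self):
        rows = [
            {"anc_visits": 2, **{f"comp_{c}": True for c in cl.COMPONENTS}}
            for _ in range(4)
        ]
        covs = cl.covariate_rates(make_women(rows))
        assert covs.blood_sample_rate == covs.urine_sample_rate == covs.bp_rate == 1.0

    def test_matches_weighted_oracle(self, rng):
        rows = []
        for _ in range(500):
            v = int(rng.integers(0, 9))
            rows.append(
                {
                    "anc_visits": v,
                    "first_visit_month": float(rng.integers(1, 10)) if v else np.nan,
                    "comp_blood_sample": bool(v and rng.random() < 0.5),
                    "weight": float(rng.uniform(0.1, 3.0)),
                }
            )
        df = make_women(rows)
        covs = cl.covariate_rates(df)
        oracle_blood = weighted_mean_oracle(df["comp_blood_sample"].tolist(),
                                            df["weight"].tolist())
        early_flags = [(not math.isnan(m)) and m <= 4 for m in df["first_visit_month"]]
        oracle_early = weighted_mean_oracle(early_flags, df["weight"].tolist())
        assert covs.blood_sample_rate == pytest.approx(oracle_blood, abs=1e-12)
        assert covs.early_anc_rate == pytest.approx(oracle_early, abs=1e-12)

    def test_anc_denominator_switch(self):
        rows = [
            {"anc_visits": 2, "comp_blood_sample": True},
            {"anc_visits": 0},
        ]
        df = make_women(rows)
        assert cl.covariate_rates(df, "all").blood_sample_rate == pytest.approx(0.5)
        assert cl.covariate_rates(df, "anc").blood_sample_rate == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cl.covariate_rates(df, "sometimes")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cl.covariate_rates(make_women([]).iloc[:0])
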