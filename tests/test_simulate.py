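"""Generator behaviour: determinism, degenerate laws, margins, closed-form truth."""

import numpy as np
import pandas as pd
import pytest

import covlink as cl
from covlink.simulate import ConfigurationError


def small_config(**kw):
    defaults = dict(n_clusters=20, women_per_cluster=10, n_facilities=60, seed=5)
    defaults.update(kw)
    return cl.default_sim_config(**defaults)


class TestHouseholdGenerator:
    def test_seed_determinism(self):
        cfg = small_config()
        a = cl.generate_household_survey(cfg)
        b = cl.generate_household_survey(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_output(self):
        a = cl.generate_household_survey(small_config(seed=1))
        b = cl.generate_household_survey(small_config(seed=2))
        assert not a.equals(b)

    @pytest.mark.parametrize("p_anc4,check", [(1.0, "all"), (0.0, "none")])
    def test_degenerate_anc4_law(self, p_anc4, check):
        df = cl.generate_household_survey(small_config(p_anc4=p_anc4))
        anc4 = df["anc_visits"] >= 4
        assert anc4.all() if check == "all" else not anc4.any()

    def test_anc4_margin_within_sampling_error(self):
        # 10,000 women, weighted ANC4+ share within 3 design-adjusted binomial SEs of 0.6
        cfg = small_config(n_clusters=500, women_per_cluster=20, p_anc4=0.6)
        df = cl.generate_household_survey(cfg)
        w = df["weight"].to_numpy()
        est = float(np.sum(w * (df["anc_visits"] >= 4)) / w.sum())
        deff = 1.0 + np.var(w) / np.mean(w) ** 2  # unequal-weighting design effect
        se = np.sqrt(0.6 * 0.4 / len(df) * deff)
        assert abs(est - 0.6) < 3 * se

    def test_record_invariants(self):
        df = cl.generate_household_survey(small_config())
        assert (df["weight"] > 0).all()
        no_anc = df["anc_visits"] == 0
        assert df.loc[no_anc, "first_visit_month"].isna().all()
        comp_cols = [c for c in df.columns if c.startswith("comp_")]
        assert not df.loc[no_anc, comp_cols].any().any()
        # care source only for ANC4+ women
        assert df.loc[df["anc_visits"] < 4, "source_type"].isna().all()
        assert df["woman_id"].is_unique

    def test_source_stratum_matches_residence(self):
        df = cl.generate_household_survey(small_config())
        src = df[df["source_type"].notna()]
        # a drawn stratum's location is stored as the woman's residence
        strata = set(cl.default_sim_config().strata)
        for _, row in src.iterrows():
            assert (row["source_type"], row["source_authority"], row["residence"]) in strata

    def test_invalid_shares_raise_naming_field(self):
        shares = dict(cl.default_sim_config().careseeking_shares)
        shares[("hospital", "public", "urban")] += 0.2
        with pytest.raises(ConfigurationError, match="careseeking_shares"):
            small_config(careseeking_shares=shares)


class TestFacilityGenerator:
    def test_seed_determinism(self):
        cfg = small_config()
        pd.testing.assert_frame_equal(
            cl.generate_facility_survey(cfg), cl.generate_facility_survey(cfg)
        )

    @pytest.mark.parametrize("rate,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_readiness(self, rate, expect):
        cfg = small_config()
        rates = {s: {iv: rate for iv in cl.INTERVENTIONS} for s in cfg.strata}
        cfg = cfg.replace(readiness_rates=rates)
        fac = cl.generate_facility_survey(cfg)
        table = cl.stratum_readiness(fac, cl.default_checklist())
        assert np.allclose(table[cl.INTERVENTIONS].to_numpy(), expect)

    def test_stratum_rate_within_sampling_error(self):
        stratum = ("health_center", "public", "rural")
        cfg = small_config(
            n_facilities=1000,
            strata=[stratum],
            facility_shares={stratum: 1.0},
            careseeking_shares={stratum: 1.0},
            readiness_rates={stratum: {iv: 0.7 for iv in cl.INTERVENTIONS}},
        )
        fac = cl.generate_facility_survey(cfg)
        scores = cl.score_facilities(fac, cl.default_checklist())
        share = scores["malaria"].mean()
        assert abs(share - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 1000)

    def test_every_stratum_receives_a_facility(self):
        cfg = small_config(n_facilities=len(cl.default_sim_config().strata))
        fac = cl.generate_facility_survey(cfg)
        present = set(map(tuple, fac[["facility_type", "authority", "location"]].to_numpy()))
        assert present == set(cfg.strata)

    def test_too_few_facilities_raises(self):
        with pytest.raises(ConfigurationError, match="n_facilities"):
            small_config(n_facilities=3)


class TestTrueCoverage:
    def test_single_stratum(self):
        s = ("hospital", "public", "urban")
        cfg = small_config(
            strata=[s], facility_shares={s: 1.0}, careseeking_shares={s: 1.0},
            readiness_rates={s: {"malaria": 0.5}}, p_anc4=1.0,
        )
        assert cl.true_availability_coverage(cfg, "malaria") == pytest.approx(0.5)

    def test_ceiling_identity_when_all_ready(self):
        cfg = small_config(p_anc4=0.7)
        rates = {s: {iv: 1.0 for iv in cl.INTERVENTIONS} for s in cfg.strata}
        non_fac = cfg.careseeking_shares.get(cl.NON_FACILITY, 0.0)
        cfg = cfg.replace(readiness_rates=rates)
        expected = 0.7 * (1.0 - non_fac)
        assert cl.true_availability_coverage(cfg, "syphilis") == pytest.approx(expected)

    def test_hand_arithmetic_two_strata(self):
        a = ("hospital", "public", "urban")
        b = ("health_post", "public", "rural")
        cfg = small_config(
            strata=[a, b],
            facility_shares={a: 0.5, b: 0.5},
            careseeking_shares={a: 0.5, b: 0.5},
            readiness_rates={a: {"diabetes": 0.2}, b: {"diabetes": 1.0}},
            p_anc4=0.6,
        )
        assert cl.true_availability_coverage(cfg, "diabetes") == pytest.approx(0.36)

    def test_unknown_intervention_raises(self):
        with pytest.raises(KeyError, match="not_a_thing"):
            cl.true_availability_coverage(small_config(), "not_a_thing")


class TestCountryPanel:
    def test_noiseless_coverage_is_exact_inverse_logit(self):
        pc = cl.default_panel_config(n_countries=10, noise_sd=0.0, seed=4)
        panel = cl.generate_country_panel(pc)
        beta = pc.true_beta["pre_eclampsia"]
        eta = (
            beta["intercept"]
            + beta["blood_sample_rate"] * panel["blood_sample_rate"]
            + beta["anc4_rate"] * panel["anc4_rate"]
        )
        expected = 1.0 / (1.0 + np.exp(-eta))
        assert np.allclose(panel["coverage_pre_eclampsia"], expected, atol=1e-9)

    def test_zero_intercept_only_gives_half(self):
        pc = cl.PanelConfig(
            n_countries=5, true_beta={"malaria": {"intercept": 0.0}}, noise_sd=0.0, seed=1
        )
        panel = cl.generate_country_panel(pc)
        assert np.allclose(panel["coverage_malaria"], 0.5)

    def test_determinism_and_bounds(self):
        pc = cl.default_panel_config(n_countries=30, seed=9)
        a = cl.generate_country_panel(pc)
        b = cl.generate_country_panel(pc)
        pd.testing.assert_frame_equal(a, b)
        cov = a["coverage_pre_eclampsia"]
        assert ((cov > 0) & (cov < 1)).all()

    def test_refit_recovers_truth_within_two_se_most_replicates(self):
        # generator/estimator consistency: at n=200 the fitted coefficients
        # cover the generating ones (within 2 robust SEs, all coordinates)
        # in at least 90% of replicates
        truth = np.array([-6.44, 4.91, 2.56])
        hits = 0
        reps = 40
        for r in range(reps):
            pc = cl.default_panel_config(n_countries=200, noise_sd=0.2, seed=1000 + r)
            panel = cl.generate_country_panel(pc)
            res = cl.fit_fractional_logit(
                panel, "coverage_pre_eclampsia", ["blood_sample_rate", "anc4_rate"]
            )
            if np.all(np.abs(res.params - truth) <= 2 * res.bse):
                hits += 1
        assert hits >= 0.9 * reps


def test_linked_estimate_converges_to_truth_with_size():
    """Mean absolute linking error shrinks as the survey grows."""
    sizes = [(20, 10, 80), (60, 15, 250), (150, 20, 800)]
    mean_errors = []
    for n_cl, wpc, n_fac in sizes:
        errs = []
        for r in range(20):
            cfg = cl.default_sim_config(
                n_clusters=n_cl, women_per_cluster=wpc, n_facilities=n_fac,
                seed=7000 + r,
            )
            hh = cl.filter_eligible(cl.generate_household_survey(cfg))
            fac = cl.generate_facility_survey(cfg)
            ready = cl.stratum_readiness(fac, cl.default_checklist())
            est = cl.link_coverage(cl.stratum_careseeking(hh), ready, "malaria")
            errs.append(abs(est.value - cl.true_availability_coverage(cfg, "malaria")))
        mean_errors.append(np.mean(errs))
    assert mean_errors[0] > mean_errors[1] > mean_errors[2]
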