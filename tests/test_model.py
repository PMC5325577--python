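"""Threshold-model operations: schedules, filters, priors, the sampler's
invariants, EBV extraction, and chain persistence."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from threshped import (ChainConfig, ConfigError, DegenerateDataError,
                       IntegrityError, ModelSpec, Pedigree, PedigreeEntry,
                       PosteriorChain, PriorSpec, derive_eval_year,
                       extract_ebv, filter_records, gibbs_fit, iw_mode,
                       pmcmc, posterior_summary, stored_samples)


class TestStoredSamples:
    @pytest.mark.parametrize("total,burn,thin,expected", [
        (100_000, 20_000, 20, 4000),   # the production schedule
        (100, 0, 1, 100),
        (1000, 200, 10, 80),
        (1001, 200, 10, 80),           # floor division
    ])
    def test_count(self, total, burn, thin, expected):
        assert stored_samples(total, burn, thin) == expected

    def test_burnin_exceeds_total(self):
        with pytest.raises(ConfigError):
            stored_samples(100, 100, 1)
        with pytest.raises(ConfigError):
            ChainConfig(total_iterations=100, burn_in=100)

    def test_realized_count_matches_config(self):
        ped = Pedigree([PedigreeEntry(f"A{i}", sex="M" if i % 2 else "F")
                        for i in range(20)])
        rec = pd.DataFrame({
            "animal": [f"A{i}" for i in range(20)],
            "sex": ["M" if i % 2 else "F" for i in range(20)],
            "age_months": 30, "eval_year": 2001,
            "hip_score": ([1, 3, 5, 7] * 5),
        })
        cfg = ChainConfig(total_iterations=430, burn_in=100, thin=7, seed=0)
        chain = gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)), chain=cfg)
        assert chain.n_stored == cfg.n_stored == stored_samples(430, 100, 7)


class TestIwMode:
    def test_values(self):
        assert iw_mode(1.0, 2.0) == pytest.approx(0.5)
        assert iw_mode(1.0, 0.002) == pytest.approx(0.002 / 2.002)

    def test_large_nu_limit(self):
        assert iw_mode(3.0, 1e9) == pytest.approx(3.0, rel=1e-6)

    def test_invalid_nu(self):
        with pytest.raises(ConfigError):
            iw_mode(1.0, 0.0)


class TestEvalYear:
    @pytest.mark.parametrize("birth,age,expected", [
        ("1990-01", 24, 1992),
        ("1990-11", 26, 1993),      # month arithmetic crosses the year
        ("2000-06", 0, 2000),
        ("2000-06-15", 30, 2002),
    ])
    def test_derivation(self, birth, age, expected):
        assert derive_eval_year(birth, age) == expected

    def test_unparseable(self):
        with pytest.raises(ValueError):
            derive_eval_year("nodate", 24)


class TestFilterRecords:
    def test_boundary_inclusive_at_24(self):
        rec = pd.DataFrame({"age_months": [23, 24, 30]})
        assert len(filter_records(rec)) == 2

    def test_identity_when_all_old_enough(self):
        rec = pd.DataFrame({"age_months": [24, 60, 120]})
        assert len(filter_records(rec)) == 3

    def test_hand_counted_file(self):
        rec = pd.DataFrame({"age_months": [12, 18, 23, 24, 25, 36, 48, 60,
                                           72, 84]})
        assert len(filter_records(rec)) == 7

    def test_empty_result_is_error(self):
        with pytest.raises(DegenerateDataError):
            filter_records(pd.DataFrame({"age_months": [12, 20]}))


class TestPmcmc:
    def test_constant_positive(self):
        assert pmcmc(np.ones(100)) == 0.0

    def test_symmetric_alternating(self):
        x = np.tile([1.0, -1.0], 50)
        assert pmcmc(x) == 1.0
        assert np.mean(x) == 0.0

    def test_standard_normal_mean_bound(self):
        x = np.random.default_rng(0).standard_normal(4000)
        assert abs(x.mean()) < 0.05   # 3 sigma of 1/sqrt(4000)


def _toy_records(n=40, k=7, trait="hip", seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "animal": [f"A{i}" for i in range(n)],
        "sex": rng.choice(["M", "F"], n),
        "age_months": rng.integers(24, 90, n),
        "eval_year": rng.integers(2000, 2004, n),
        f"{trait}_score": rng.integers(1, k + 1, n).astype(float),
    })


def _toy_pedigree(n=40):
    return Pedigree([PedigreeEntry(f"A{i}", sex="M" if i % 2 else "F")
                     for i in range(n)])


class TestGibbsFitValidation:
    def test_single_category_is_degenerate(self):
        ped = _toy_pedigree(10)
        rec = _toy_records(10)
        rec["hip_score"] = 1.0
        with pytest.raises(DegenerateDataError):
            gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)))

    def test_unknown_animal_is_integrity_error(self):
        ped = _toy_pedigree(10)
        rec = _toy_records(10)
        rec.loc[0, "animal"] = "GHOST"
        with pytest.raises(IntegrityError, match="GHOST"):
            gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)))

    def test_score_out_of_range(self):
        ped = _toy_pedigree(10)
        rec = _toy_records(10)
        rec.loc[0, "hip_score"] = 8.0
        with pytest.raises(DegenerateDataError):
            gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)))


class TestChainInvariants:
    def test_cutpoints_increasing_and_first_zero(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        for t in chain.traits:
            cuts = chain.cut_samples[t]
            assert np.allclose(cuts[:, 0], 0.0)
            assert (np.diff(cuts, axis=1) > 0).all()

    def test_g0_positive_definite_every_sample(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        for g in chain.g_samples:
            np.linalg.cholesky(g)      # raises if not PD

    def test_implied_rg_bounded(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        rg = chain.g_samples[:, 0, 1] / np.sqrt(
            chain.g_samples[:, 0, 0] * chain.g_samples[:, 1, 1])
        assert (np.abs(rg) <= 1.0).all()

    def test_residual_correlation_bounded(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        assert (np.abs(chain.rhe_samples) < 1.0).all()


class TestEbv:
    def test_unconnected_founder_shrunk_to_zero(self):
        """A founder without records or phenotyped descendants stays at the
        prior mean; phenotyped animals move away from it."""
        n = 30
        entries = [PedigreeEntry(f"A{i}", sex="M" if i % 2 else "F")
                   for i in range(n)] + [PedigreeEntry("LONER", sex="M")]
        ped = Pedigree(entries)
        rec = _toy_records(n, seed=3)
        chain = gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)),
                          chain=ChainConfig(total_iterations=1500, burn_in=500,
                                            thin=2, seed=3))
        ebv = extract_ebv(chain).set_index("animal")
        spread = np.abs(ebv.loc[[f"A{i}" for i in range(n)], "ebv"]).mean()
        assert abs(ebv.loc["LONER", "ebv"]) < spread

    def test_identical_twins_get_equal_ebvs(self):
        """Full sibs with identical records are exchangeable."""
        entries = [PedigreeEntry("S", sex="M"), PedigreeEntry("D", sex="F"),
                   PedigreeEntry("T1", "S", "D", "M"),
                   PedigreeEntry("T2", "S", "D", "M")]
        ped = Pedigree(entries)
        rec = pd.DataFrame({
            "animal": ["T1", "T2"] * 8,
            "sex": "M", "age_months": 36, "eval_year": 2002,
            "hip_score": [2.0, 2.0, 5.0, 5.0] * 4,
        })
        chain = gibbs_fit(ped, rec, spec=ModelSpec(traits=("hip",)),
                          chain=ChainConfig(total_iterations=4000, burn_in=1000,
                                            thin=2, seed=0))
        ebv = extract_ebv(chain).set_index("animal")["ebv"]
        assert ebv["T1"] == pytest.approx(ebv["T2"], abs=0.1)

    def test_ebv_correlates_with_true_bv(self, fit_h2_06):
        ds, chain = fit_h2_06
        ebv = extract_ebv(chain).set_index("animal")
        truth = ds.true_bv_wide()
        joined = ebv.join(truth, how="inner")
        r = np.corrcoef(joined["ebv"], joined["hip"])[0, 1]
        assert r > 0.5


class TestPriorSampling:
    def test_prior_only_matches_inverse_wishart(self):
        """With no records attached the chain explores the (a, G0) prior,
        so stored G0 marginals must match the inverse-Wishart density."""
        ped = Pedigree([PedigreeEntry(f"A{i}", sex="M" if i % 2 else "F")
                        for i in range(30)])
        nu, V = 5.0, 1.0
        chain = gibbs_fit(ped, None, spec=ModelSpec(traits=("hip",)),
                          priors=PriorSpec(V=[[V]], nu=nu),
                          chain=ChainConfig(total_iterations=16_500,
                                            burn_in=500, thin=4, seed=7))
        g = chain.g_samples[:, 0, 0]
        # marginal of a 1x1 IW(scale=V*nu, df=nu)
        ref = stats.invgamma(a=nu / 2, scale=V * nu / 2)
        ks = stats.kstest(g, ref.cdf).statistic
        assert ks < 0.08

    def test_prior_mode_matches_formula(self):
        assert iw_mode(1.0, 0.002) == pytest.approx(9.99e-4, rel=1e-3)


class TestSummaryAndPersistence:
    def test_posterior_summary_columns(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        summ = posterior_summary(chain)
        assert {"parameter", "mean", "sd", "sem", "lag1_autocorr",
                "pmcmc"} <= set(summ.columns)
        assert (summ["sem"] <= summ["sd"] + 1e-12).all()

    def test_save_load_round_trip(self, tmp_path, fit_bivariate_small):
        _, chain = fit_bivariate_small
        chain.save(tmp_path / "chain")
        again = PosteriorChain.load(tmp_path / "chain")
        np.testing.assert_allclose(again.g_samples, chain.g_samples,
                                   rtol=1e-12)
        np.testing.assert_allclose(again.rhe_samples, chain.rhe_samples,
                                   rtol=1e-12)
        for t in chain.traits:
            np.testing.assert_allclose(again.cut_samples[t],
                                       chain.cut_samples[t], rtol=1e-12)
        pd.testing.assert_frame_equal(extract_ebv(again), extract_ebv(chain),
                                      rtol=1e-12)
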