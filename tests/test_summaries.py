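"""Genetic summaries: heritability/correlation transforms, prevalence,
trends, the four-path decomposition, and effect reporting."""

import numpy as np
import pandas as pd
import pytest

from threshped import (ChainConfig, ModelSpec, Pedigree, PedigreeEntry,
                       SimulationTruth, TruncationSelection, breed_filter,
                       four_path, genetic_correlation, genetic_trend,
                       gibbs_fit, heritability, hip_breakdown, loess_smooth,
                       phenotypic_trend, prevalence, sex_age_report,
                       simulate_dataset, sire_dam_contrast,
                       summarize_genetics)


class TestHeritability:
    @pytest.mark.parametrize("g,expected", [(1.0, 0.5), (3.0, 0.75),
                                            (1e-9, pytest.approx(0, abs=1e-8))])
    def test_values(self, g, expected):
        assert heritability(g) == expected

    def test_sample_wise_not_transform_of_mean(self):
        g = np.array([0.5, 4.0])
        sample_wise = heritability(g).mean()
        of_mean = heritability(g.mean())
        assert sample_wise != pytest.approx(of_mean)
        assert sample_wise == pytest.approx((1 / 3 + 4 / 5) / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0)


class TestGeneticCorrelation:
    @pytest.mark.parametrize("gh,ge,ghe,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (1.0, 1.0, 0.0, 0.0),
        (2.0, 0.5, -0.5, -0.5),
    ])
    def test_values(self, gh, ge, ghe, expected):
        assert genetic_correlation(gh, ge, ghe) == pytest.approx(expected)

    def test_thinning_stability(self, fit_bivariate_small):
        """Sample-wise summaries commute with chain subsampling up to
        Monte-Carlo error."""
        _, chain = fit_bivariate_small
        full = summarize_genetics(chain).rg_mean
        g = chain.g_samples[::2]
        sub = genetic_correlation(g[:, 0, 0], g[:, 1, 1], g[:, 0, 1]).mean()
        assert sub == pytest.approx(full, abs=0.05)


class TestPrevalence:
    def test_hip_example(self):
        rec = pd.DataFrame({"hip_score": [1, 2, 3, 5, 6]})
        assert prevalence(rec, "hip") == pytest.approx(40.0)

    def test_all_normal_elbows(self):
        rec = pd.DataFrame({"elbow_score": [1, 1, 1, 1]})
        assert prevalence(rec, "elbow") == 0.0

    def test_elbow_example(self):
        rec = pd.DataFrame({"elbow_score": [1, 1, 2, 4]})
        assert prevalence(rec, "elbow") == pytest.approx(50.0)

    def test_borderline_in_denominator_only(self):
        rec = pd.DataFrame({"hip_score": [1, 4, 5, 7]})
        bd = hip_breakdown(rec)
        assert bd["dysplastic"] == pytest.approx(50.0)
        assert bd["borderline"] == pytest.approx(25.0)
        assert bd["non_dysplastic"] + bd["borderline"] + bd["dysplastic"] \
            == pytest.approx(100.0)

    def test_no_scores_is_error(self):
        with pytest.raises(ValueError):
            prevalence(pd.DataFrame({"hip_score": [np.nan]}), "hip")


class TestPhenotypicTrend:
    def test_single_year_fraction(self):
        rec = pd.DataFrame({"animal": ["a", "b", "c"],
                            "hip_score": [1, 1, 2]})
        by = pd.Series({"a": 2000, "b": 2000, "c": 2000})
        ts = phenotypic_trend(rec, by, "hip")
        assert ts.table["value"].iloc[0] == pytest.approx(2 / 3)

    def test_two_year_hand_count(self):
        rec = pd.DataFrame({
            "animal": list("abcdef"),
            "hip_score": [1, 2, 1, 1, 3, 1],
        })
        by = pd.Series({"a": 2000, "b": 2000, "c": 2001, "d": 2001,
                        "e": 2001, "f": 2002})
        ts = phenotypic_trend(rec, by, "hip")
        got = dict(zip(ts.table["year"], ts.table["value"]))
        assert got == {2000: pytest.approx(0.5), 2001: pytest.approx(2 / 3),
                       2002: pytest.approx(1.0)}

    def test_all_excellent_is_flat_one(self):
        rec = pd.DataFrame({"animal": list("abcd"), "hip_score": [1] * 4})
        by = pd.Series({"a": 2000, "b": 2000, "c": 2001, "d": 2001})
        ts = phenotypic_trend(rec, by, "hip")
        assert (ts.table["value"] == 1.0).all()


def _ebv_series(ped, values):
    return pd.Series(values, index=pd.Index(ped.ids, dtype=object))


class TestGeneticTrend:
    def test_all_zero_is_flat(self):
        ped = Pedigree([PedigreeEntry(f"A{i}", sex="M", birth_year=2000 + i)
                        for i in range(5)])
        ts = genetic_trend(_ebv_series(ped, np.zeros(5)), ped)
        assert (ts.table["value"] == 0).all()

    def test_single_year_population(self):
        ped = Pedigree([PedigreeEntry(f"A{i}", sex="M", birth_year=2000)
                        for i in range(5)])
        ts = genetic_trend(_ebv_series(ped, np.arange(5.0)), ped)
        assert len(ts.table) == 1
        assert "smooth" not in ts.table.columns

    def test_selection_gives_negative_slope(self):
        """Truncation selection on the phenotype drives mean true breeding
        value down across birth years; no selection leaves it flat."""
        sel = TruncationSelection(proportion=0.2, sexes="both")
        truth = SimulationTruth.from_heritabilities(
            0.6, trait="hip", selection=sel, seed=5,
            n_founders=200, n_generations=5, n_sires=30, n_dams=90,
            offspring_per_dam=3)
        ds = simulate_dataset(truth)
        bv = ds.true_bv.set_index("animal")["true_bv"]
        ts = genetic_trend(bv, ds.pedigree)
        slope = np.polyfit(ts.table["year"], ts.table["value"], 1)[0]
        assert slope < -0.05

        flat_truth = SimulationTruth.from_heritabilities(
            0.6, trait="hip", seed=5, n_founders=200, n_generations=5,
            n_sires=30, n_dams=90, offspring_per_dam=3)
        ds0 = simulate_dataset(flat_truth)
        bv0 = ds0.true_bv.set_index("animal")["true_bv"]
        ts0 = genetic_trend(bv0, ds0.pedigree)
        slope0 = np.polyfit(ts0.table["year"], ts0.table["value"], 1)[0]
        assert abs(slope0) < abs(slope) / 2


class TestLoess:
    def test_recovers_smooth_curve(self):
        x = np.linspace(0, 10, 60)
        rng = np.random.default_rng(0)
        y = np.sin(x / 3) + 0.05 * rng.standard_normal(60)
        sm = loess_smooth(x, y, span=0.5)
        assert np.abs(sm - np.sin(x / 3)).mean() < 0.05

    def test_short_series_passthrough(self):
        y = np.array([1.0, 2.0])
        np.testing.assert_array_equal(loess_smooth([0, 1], y), y)


class TestFourPath:
    def _three_gen(self):
        return Pedigree([
            PedigreeEntry("GS", sex="M", birth_year=2000),
            PedigreeEntry("GD", sex="F", birth_year=2000),
            PedigreeEntry("GS2", sex="M", birth_year=2000),
            PedigreeEntry("GD2", sex="F", birth_year=2000),
            PedigreeEntry("S", "GS", "GD", "M", 2002),
            PedigreeEntry("D", "GS2", "GD2", "F", 2002),
            PedigreeEntry("O", "S", "D", "M", 2004),
        ])

    def test_single_member_series(self):
        ped = self._three_gen()
        values = _ebv_series(ped, np.zeros(len(ped)))
        values["GS"] = -0.3
        fp = four_path(values, ped)
        ss = fp.table[fp.table["category"] == "SS"]
        assert len(ss) == 1
        assert ss["mean_ebv"].iloc[0] == pytest.approx(-0.3)

    def test_constant_ebvs_flat_quadratic(self):
        ped = Pedigree(
            [PedigreeEntry(f"GS{k}", sex="M", birth_year=2000 + k)
             for k in range(3)]
            + [PedigreeEntry(f"S{k}", f"GS{k}", "", "M", 2004 + k)
               for k in range(3)]
            + [PedigreeEntry(f"O{k}", f"S{k}", "", "M", 2008 + k)
               for k in range(3)])
        values = _ebv_series(ped, np.full(len(ped), 0.7))
        fp = four_path(values, ped)
        fit = fp.fits["SS"]
        assert fit["intercept"] == pytest.approx(0.7)
        assert fit["linear"] == pytest.approx(0.0, abs=1e-10)
        assert fit["quadratic"] == pytest.approx(0.0, abs=1e-10)

    def test_sires_only_selection_dominates_sire_path(self):
        """Selecting sires only, the SS/SD animals carry lower true
        breeding values than the DS/DD animals."""
        sel = TruncationSelection(proportion=0.15, sexes="sires", on="true_bv")
        truth = SimulationTruth.from_heritabilities(
            0.6, trait="hip", selection=sel, seed=6,
            n_founders=200, n_generations=5, n_sires=20, n_dams=90,
            offspring_per_dam=3)
        ds = simulate_dataset(truth)
        bv = ds.true_bv.set_index("animal")["true_bv"]
        contrast = sire_dam_contrast(bv, ds.pedigree, seed=0)
        assert contrast["difference"] < 0
        fp = four_path(bv, ds.pedigree)
        last = fp.table.groupby("category").apply(
            lambda g: g.loc[g["year"].idxmax(), "mean_ebv"],
            include_groups=False)
        assert (last["SS"] + last["SD"]) / 2 < (last["DS"] + last["DD"]) / 2

    def test_trend_accounting_identity(self):
        """On a pedigree whose grand-parental categories are disjoint, the
        population trend is the n-weighted average of the four category
        trends plus non-grandparent animals."""
        ped = self._three_gen()
        rng = np.random.default_rng(1)
        values = _ebv_series(ped, rng.standard_normal(len(ped)))
        fp = four_path(values, ped)
        ts = genetic_trend(values, ped)
        year0 = ts.table[ts.table["year"] == 2000]
        cat_rows = fp.table[fp.table["year"] == 2000]
        member_ids = {"GS", "GD", "GS2", "GD2"}
        weighted = (cat_rows["mean_ebv"] * cat_rows["n"]).sum()
        non_members = [a for a in ped.ids
                       if a not in member_ids
                       and ped.birth_year[ped.order_index[a]] == 2000]
        total = weighted + values[non_members].sum()
        n_total = cat_rows["n"].sum() + len(non_members)
        assert year0["value"].iloc[0] == pytest.approx(total / n_total)


class TestSexAgeReport:
    def _fit(self, sex_effect, seed, n_iter=2500, **demo):
        # ~440 records per run: large enough that the nominal 5% level of
        # the pMCMC < 0.05 call is accurate
        demo = dict(n_founders=200, n_generations=2, n_sires=25, n_dams=80,
                    offspring_per_dam=3) | demo
        truth = SimulationTruth.from_heritabilities(
            0.4, trait="hip", seed=seed, sex_effect=(sex_effect,), **demo)
        ds = simulate_dataset(truth)
        chain = gibbs_fit(ds.pedigree, ds.records,
                          spec=ModelSpec(traits=("hip",)),
                          chain=ChainConfig(total_iterations=n_iter,
                                            burn_in=500, thin=2, seed=seed))
        return sex_age_report(chain)

    def test_null_sex_effect_mostly_nonsignificant(self):
        hits = 0
        for seed in range(20):
            rep = self._fit(0.0, seed)
            row = rep[(rep["trait"] == "hip") & (rep["effect"] == "sex_MvsF")]
            hits += int(row["significant"].iloc[0])
        assert hits <= 2          # >= 90% non-significant under the null

    def test_negative_shift_detected(self):
        """A strong male-favorable shift yields a significant negative
        male-minus-female contrast."""
        rep = self._fit(-0.5, seed=99, n_iter=4000, n_founders=200,
                        n_dams=80)
        row = rep[(rep["trait"] == "hip") & (rep["effect"] == "sex_MvsF")]
        assert row["estimate"].iloc[0] < 0
        assert row["significant"].iloc[0]

    def test_degenerate_chain_flagged(self, fit_bivariate_small):
        _, chain = fit_bivariate_small
        import copy
        frozen = copy.deepcopy(chain)
        frozen.beta_samples = np.zeros_like(frozen.beta_samples)
        rep = sex_age_report(frozen)
        assert rep["degenerate"].all()
        assert not rep["significant"].any()


class TestBreedFilter:
    def test_strict_thresholds(self):
        counts = pd.DataFrame({
            "breed": ["a", "b", "c", "d", "e"],
            "hip_count": [1000, 1001, 5000, 999, 2000],
            "elbow_count": [600, 501, 500, 800, 2000],
        })
        assert breed_filter(counts) == ["b", "e"]
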