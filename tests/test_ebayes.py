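import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deptraj.catalogues import metabolomic_catalogue
from deptraj.ebayes import (
    ebayes_moderate,
    fit_analyte_models,
    lod_filter,
    planned_contrasts,
    select_metabolomic_features,
    standardise_metabolomics,
)
from deptraj.simulate import (
    BiomarkerPanel,
    GeneratorConfig,
    PanelSpec,
    default_metabolomic_panel_spec,
    default_protein_panel_spec,
    generate_biomarker_panel,
    generate_cohort,
)


def sample_frame(cohort):
    df = cohort.covariates.rename(columns={"true_class": "trajectory_class"})
    return df


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=77))


class TestPanelFiltering:
    def test_default_fixture_keeps_67_of_92_proteins(self, cohort):
        panel = generate_biomarker_panel(cohort, default_protein_panel_spec(), seed=1)
        assert len(panel.metadata) == 92
        kept = lod_filter(panel)
        assert len(kept.analytes) == 67

    def test_zero_fractions_leave_panel_unchanged(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0, low_fraction=0.0), seed=2
        )
        assert lod_filter(panel).analytes == panel.analytes

    def test_threshold_is_inclusive_at_half(self, cohort):
        spec = default_protein_panel_spec(n_high_lod=0, low_fraction=0.0)
        panel = generate_biomarker_panel(cohort, spec, seed=3)
        # force an exact 0.5 below-LOD fraction on one analyte
        panel.metadata.loc[0, "below_lod_fraction"] = 0.5
        kept = lod_filter(panel)
        assert panel.metadata.loc[0, "analyte"] not in kept.analytes

    def test_metabolomic_catalogue_counts(self):
        cat = metabolomic_catalogue()
        assert len(cat) == 57
        expected = {
            "cholesterol": 9,
            "apolipoproteins_lipids": 12,
            "particle_size": 3,
            "fatty_acids": 16,
            "glycolysis": 3,
            "amino_acids": 8,
            "ketone_bodies": 3,
            "fluid_balance": 2,
            "inflammation": 1,
        }
        assert cat["category"].value_counts().to_dict() == expected

    def test_subclass_exclusion_yields_57(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_metabolomic_panel_spec(), seed=4
        )
        kept = select_metabolomic_features(panel)
        assert len(kept.analytes) == 57
        assert "lipoprotein_subclass" not in set(kept.metadata["category"])

    def test_catalogue_without_subclasses_is_identity(self, cohort):
        spec = PanelSpec(metadata=metabolomic_catalogue(include_subclasses=False))
        panel = generate_biomarker_panel(cohort, spec, seed=5)
        assert select_metabolomic_features(panel).analytes == panel.analytes

    def test_subclass_only_panel_empties(self, cohort):
        cat = metabolomic_catalogue(include_subclasses=True)
        spec = PanelSpec(metadata=cat[cat["category"] == "lipoprotein_subclass"])
        panel = generate_biomarker_panel(cohort, spec, seed=6)
        assert select_metabolomic_features(panel).analytes == []

    def test_unknown_category_rejected(self, cohort):
        meta = pd.DataFrame(
            {"analyte": ["x"], "family": ["metabolomic"], "category": ["mystery"]}
        )
        panel = generate_biomarker_panel(cohort, PanelSpec(metadata=meta), seed=7)
        with pytest.raises(ValueError, match="unknown analyte categories"):
            select_metabolomic_features(panel)


class TestAnalyteModels:
    def test_single_analyte_matches_standalone_regression(self, cohort):
        import statsmodels.api as sm

        from deptraj.associations import build_design

        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0), seed=8
        )
        one = panel.values[["IL6"]]
        sample = sample_frame(cohort)
        fits = fit_analyte_models(one, sample)
        X, class_terms, _ = build_design(
            sample, "trajectory_class", fits_covariates := (
                "sex", "maternal_education", "maternal_social_class", "bmi_age10"
            ),
        )
        ols = sm.OLS(one.loc[sample["subject_id"], "IL6"].to_numpy(), X).fit()
        j = fits.design_columns.index(class_terms[0])
        assert fits.coef[0, j] == pytest.approx(ols.params[class_terms[0]], rel=1e-8)
        assert fits.s2[0] == pytest.approx(float(ols.mse_resid), rel=1e-8)

    def test_planted_log_shift_recovered(self, cohort):
        spec = default_protein_panel_spec(n_high_lod=0)
        spec.class_shifts["HGF"] = {3: 0.3}
        panel = generate_biomarker_panel(cohort, spec, seed=9)
        fits = fit_analyte_models(panel.values, sample_frame(cohort))
        j = fits.design_columns.index("trajectory_class[3]")
        k = fits.analytes.index("HGF")
        assert fits.coef[k, j] == pytest.approx(0.3, abs=0.08)

    def test_zero_variance_analyte_excluded(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0), seed=10
        )
        values = panel.values.copy()
        values["FLAT"] = 1.0
        fits = fit_analyte_models(values, sample_frame(cohort))
        assert "FLAT" in fits.excluded
        assert "FLAT" not in fits.analytes


class TestModeration:
    def test_monte_carlo_hyperparameter_recovery(self):
        """Variances simulated from a scaled inverse-chi-square prior with
        d0=4, s0^2=2 are recovered by the moment estimator."""
        rng = np.random.default_rng(123)
        d0, s02, d, m = 4.0, 2.0, 20, 5000
        sigma2 = s02 * d0 / rng.chisquare(d0, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        d0_hat, s02_hat, s2t = ebayes_moderate(s2, d)
        assert d0_hat == pytest.approx(4.0, abs=0.5)
        assert s02_hat == pytest.approx(2.0, abs=0.1)
        assert np.all((s2t > np.minimum(s2, s02_hat) - 1e-12)
                      & (s2t < np.maximum(s2, s02_hat) + 1e-12))

    def test_prior_df_zero_disables_shrinkage(self, rng):
        s2 = rng.uniform(0.5, 2.0, size=30)
        d0, s02, s2t = ebayes_moderate(s2, 10, prior_df=0.0)
        np.testing.assert_array_equal(s2t, s2)

    def test_infinite_prior_collapses_to_pooled_value(self, rng):
        s2 = rng.uniform(0.5, 2.0, size=30)
        d0, s02, s2t = ebayes_moderate(s2, 10, prior_df=np.inf)
        np.testing.assert_allclose(s2t, s02)

    def test_equal_prior_and_residual_df_gives_midpoint(self, rng):
        s2 = rng.uniform(0.5, 2.0, size=30)
        d = 10
        d0, s02, s2t = ebayes_moderate(s2, d, prior_df=float(d))
        np.testing.assert_allclose(s2t, 0.5 * (s02 + s2), rtol=1e-12)

    def test_equal_variances_give_infinite_d0(self):
        s2 = np.full(20, 1.7)
        d0, s02, s2t = ebayes_moderate(s2, 15)
        assert np.isinf(d0)
        np.testing.assert_allclose(s2t, s02)

    def test_shrinkage_monotone_in_prior_df(self, rng):
        """The residual pull away from the prior shrinks as d0 grows:
        |s~^2 - s0^2| = d/(d0+d) |s^2 - s0^2| for each analyte."""
        s2 = rng.uniform(0.2, 3.0, size=25)
        d = 10
        for d0 in (2.0, 50.0):
            _, s02, s2t = ebayes_moderate(s2, d, prior_df=d0)
            np.testing.assert_allclose(
                np.abs(s2t - s02), d / (d0 + d) * np.abs(s2 - s02), rtol=1e-10
            )
        _, s02_a, s2t_a = ebayes_moderate(s2, d, prior_df=2.0)
        _, s02_b, s2t_b = ebayes_moderate(s2, d, prior_df=50.0)
        assert np.all(
            np.abs(s2t_b - s02_b) / np.abs(s2 - s02_b)
            <= np.abs(s2t_a - s02_a) / np.abs(s2 - s02_a) + 1e-12
        )


class TestPlannedContrasts:
    def test_moderated_t_equals_ordinary_t_at_zero_prior_df(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0), seed=11
        )
        fits = fit_analyte_models(panel.values, sample_frame(cohort))
        mod = planned_contrasts(fits, prior_df=0.0)
        plain = planned_contrasts(fits, moderate=False)
        np.testing.assert_allclose(
            mod.table["t"].to_numpy(), plain.table["t"].to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(
            mod.table["p_value"].to_numpy(), plain.table["p_value"].to_numpy(),
            rtol=1e-10,
        )

    def test_estimates_invariant_to_moderation(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0), seed=12
        )
        fits = fit_analyte_models(panel.values, sample_frame(cohort))
        a = planned_contrasts(fits, moderate=True).table
        b = planned_contrasts(fits, moderate=False).table
        np.testing.assert_allclose(a["estimate"], b["estimate"], rtol=1e-12)

    def test_self_contrast_gives_zero_and_p_one(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(n_high_lod=0), seed=13
        )
        fits = fit_analyte_models(panel.values, sample_frame(cohort))
        zero = np.zeros(len(fits.design_columns))
        eb = planned_contrasts(fits, contrasts=[zero])
        assert (eb.table["estimate"] == 0).all()
        assert (eb.table["p_value"] == 1.0).all()

    def test_null_panel_has_few_fdr_flags(self, cohort):
        panel = generate_biomarker_panel(
            cohort, default_protein_panel_spec(), seed=14
        )
        fits = fit_analyte_models(lod_filter(panel).values, sample_frame(cohort))
        eb = planned_contrasts(fits, q=0.1)
        # 67 null analytes x 3 contrasts: expected false positives ~ q per
        # rejected family; allow a small absolute count
        assert eb.table["fdr_significant"].sum() <= 6

    def test_power_on_planted_shifts(self):
        """Five analytes shifted by 0.5 SD for one class are detected with
        high per-analyte power across replicate panels."""
        hits = np.zeros(5)
        reps = 25
        targets = ["IL6", "HGF", "FGF21", "CCL11", "CDCP1"]
        for rep in range(reps):
            cohort = generate_cohort(GeneratorConfig(n_subjects=2000, seed=900 + rep))
            spec = default_protein_panel_spec(n_high_lod=0)
            for t in targets:
                spec.class_shifts[t] = {3: 0.5}
            panel = generate_biomarker_panel(cohort, spec, seed=rep)
            fits = fit_analyte_models(panel.values, sample_frame(cohort))
            eb = planned_contrasts(fits, contrasts=["trajectory_class[3]"], q=0.1)
            tab = eb.table.set_index("analyte")
            for k, t in enumerate(targets):
                hits[k] += bool(tab.loc[t, "fdr_significant"])
        assert np.all(hits / reps >= 0.8)

    def test_standardise_metabolomics_gives_unit_sd(self, rng):
        df = pd.DataFrame(
            {"a": rng.lognormal(0, 0.4, 500), "b": rng.normal(0, 3.0, 500)}
        )
        out = standardise_metabolomics(df)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, rtol=1e-12)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
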