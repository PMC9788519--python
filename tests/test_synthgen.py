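"""Generator tests: planted-effect fidelity, GEV recovery-time law,
longitudinal linearity, cytokine coupling, spectra and outlier injection."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenorevert.errors import ConfigError
from phenorevert.preprocess import assign_days_since_covid
from phenorevert.screen import univariate_screen
from phenorevert.synthgen import (
    GeneratorConfig,
    _base_levels,
    default_panel_14,
    default_panel_38,
    generate_cytokines,
    generate_longitudinal,
    generate_population,
    generate_spectrum,
    inject_outliers,
)
from phenorevert.pipeline import _log_matrix


def _pure_gev_config(**kw) -> GeneratorConfig:
    """GEV recovery times with the age/severity modulation switched off."""
    kw.setdefault("age_effect_on_recovery", 0.0)
    kw.setdefault("severity_classes", {"mild-moderate": 1.0, "severe": 1.0})
    return GeneratorConfig(**kw)


class TestConfig:
    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError, match="n_controls"):
            GeneratorConfig(n_controls=-1)

    def test_bad_block_rho_rejected(self):
        with pytest.raises(ConfigError, match="rho"):
            GeneratorConfig(block_structure=[(5, 1.0)])

    def test_nonpositive_gev_scale_rejected(self):
        with pytest.raises(ConfigError, match="gev_scale"):
            GeneratorConfig(gev_scale=0.0)

    def test_unknown_panel_variable_rejected(self):
        cfg = GeneratorConfig(informative_panel=[("NotAVariable", 1.0, 1)])
        with pytest.raises(ConfigError, match="NotAVariable"):
            generate_population(cfg)

    def test_unknown_cytokine_rejected(self):
        with pytest.raises(ConfigError, match="markers"):
            GeneratorConfig(cytokine_folds={"IL-99": 2.0})

    def test_default_panels_have_documented_sizes(self):
        assert len(default_panel_38()) == 38
        assert len(default_panel_14()) == 14
        effects38 = [e for _, e, _ in default_panel_38()]
        assert min(effects38) >= 0.6 and max(effects38) <= 2.0


class TestPopulation:
    def test_row_counts_and_variables(self, population, default_config):
        assert len(population) == 800
        assert len(population.variables) == 41 + 112 + 3

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_controls=50, n_acute=50, seed=7)
        a = generate_population(cfg)
        b = generate_population(GeneratorConfig(n_controls=50, n_acute=50, seed=7))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_panel_has_no_group_differences(self):
        cfg = GeneratorConfig(informative_panel=[], seed=3)
        pop = generate_population(cfg)
        logx = _log_matrix(pop).to_numpy()
        hc = (pop.data["cohort"] == "HC").to_numpy()
        diff = ((logx[~hc].mean(axis=0) - logx[hc].mean(axis=0))
                / logx[hc].std(axis=0, ddof=1))
        assert np.abs(diff).max() < 0.2

    def test_planted_effect_recovered_by_screen(self):
        cfg = GeneratorConfig(informative_panel=[("Glucose", 1.0, +1)], seed=4)
        pop = generate_population(cfg)
        y = (pop.data["cohort"] != "HC").astype(int).to_numpy()
        res = univariate_screen(_log_matrix(pop), y, pop.data)
        glu = next(r for r in res if r.variable == "Glucose")
        assert glu.effect_sd == pytest.approx(1.0, abs=0.15)

    def test_effect_size_fidelity_at_large_n(self):
        # planted effect recovered within 0.1 SD at n=1000/group
        cfg = GeneratorConfig(n_controls=1000, n_acute=1000,
                              informative_panel=[("Histidine", 0.8, -1),
                                                 ("V1TG", 1.5, +1)], seed=0)
        pop = generate_population(cfg)
        y = (pop.data["cohort"] != "HC").astype(int).to_numpy()
        res = {r.variable: r for r in
               univariate_screen(_log_matrix(pop), y, pop.data)}
        assert res["Histidine"].effect_sd == pytest.approx(-0.8, abs=0.1)
        assert res["V1TG"].effect_sd == pytest.approx(1.5, abs=0.1)

    def test_panel_variables_below_pruning_threshold(self, population,
                                                     population_logx):
        names = [n for n, _, _ in default_panel_38()]
        corr = population_logx[names].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.8


class TestLongitudinal:
    def test_recovery_days_follow_configured_gev(self):
        cfg = _pure_gev_config(n_acute=10000, sampling_bins=[(1, 7)],
                               sampling_probs=[1.0], seed=11)
        lon = generate_longitudinal(cfg)
        t = lon.data.groupby("subject_id")["true_recovery_day"].first().to_numpy()
        ks = sps.kstest(t, lambda x: sps.genextreme.cdf(
            x, -cfg.gev_shape, loc=cfg.gev_location, scale=cfg.gev_scale))
        assert ks.pvalue > 0.01

    def test_age_effect_raises_recovery_time_of_elderly(self):
        cfg = _pure_gev_config(n_acute=2000, age_effect_on_recovery=1.0, seed=12)
        lon = generate_longitudinal(cfg)
        per = lon.data.groupby("subject_id")[["true_recovery_day", "age"]].first()
        old = per.loc[per["age"] >= 65, "true_recovery_day"].mean()
        young = per.loc[per["age"] < 65, "true_recovery_day"].mean()
        assert old > young

    def test_severity_multiplier_raises_recovery_time(self):
        cfg = GeneratorConfig(n_acute=2000, age_effect_on_recovery=0.0, seed=13)
        lon = generate_longitudinal(cfg)
        per = lon.data.groupby("subject_id")[["true_recovery_day", "severity"]].first()
        sev = per.groupby("severity")["true_recovery_day"].mean()
        assert sev["severe"] > sev["mild-moderate"]

    def test_noiseless_displacement_is_linear_ramp(self):
        # displacement at day d equals (1 - d/T) of the acute effect, exactly
        cfg = _pure_gev_config(noise_cv=0.0, biological_cv=0.0,
                               age_covariate_sd_per_year=0.0, sex_effects={},
                               n_acute=20, sampling_bins=[(5, 5), (20, 20)],
                               sampling_probs=[1.0, 1.0], seed=14)
        lon = generate_longitudinal(cfg)
        mu = dict(zip(cfg.variable_names(), _base_levels(cfg)))
        glu = np.log(lon.data["Glucose"].to_numpy()) - mu["Glucose"]
        day = assign_days_since_covid(lon).data["days_since_covid"].to_numpy()
        t = lon.data["true_recovery_day"].to_numpy()
        expected_ratio = np.maximum(0.0, 1.0 - day / t)
        acute = glu[day == 0]
        # each subject's acute displacement is identical (no noise)
        assert np.allclose(acute, acute[0])
        assert np.allclose(glu, expected_ratio * acute[0], atol=1e-12)

    def test_requires_sampling_bins(self):
        with pytest.raises(ConfigError, match="sampling_bins"):
            generate_longitudinal(GeneratorConfig(sampling_bins=[]))

    def test_determinism(self):
        a = generate_longitudinal(GeneratorConfig(n_acute=30, seed=9))
        b = generate_longitudinal(GeneratorConfig(n_acute=30, seed=9))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCytokines:
    @pytest.fixture(scope="class")
    def labeled(self):
        cfg = GeneratorConfig(n_acute=100, seed=5)
        return cfg, assign_days_since_covid(generate_longitudinal(cfg))

    def test_healthy_fold_change_near_zero(self):
        cfg = GeneratorConfig(n_controls=120, n_acute=0, seed=6)
        pop = generate_population(cfg)
        cyt = generate_cytokines(cfg, pop)
        cfg2 = GeneratorConfig(n_controls=120, n_acute=0, seed=61)
        cyt2 = generate_cytokines(cfg2, generate_population(cfg2))
        m1 = cyt.groupby("marker")["level"].mean()
        m2 = cyt2.groupby("marker")["level"].mean()
        assert np.abs(np.log2(m1 / m2)).max() < 0.35

    def test_acute_fold_matches_configuration(self):
        cfg = GeneratorConfig(n_controls=200, n_acute=200, seed=7,
                              cytokine_folds={"IL-6": 2.0})
        pop = assign_days_since_covid(generate_population(cfg))
        cyt = generate_cytokines(cfg, pop)
        il6 = cyt[cyt["marker"] == "IL-6"].merge(
            pop.data[["sample_id", "cohort"]], on="sample_id")
        fc = np.log2(il6.loc[il6["cohort"] == "AC", "level"].mean()
                     / il6.loc[il6["cohort"] == "HC", "level"].mean())
        assert fc == pytest.approx(1.0, abs=0.25)

    def test_mcp1_decay_tracks_recovery_time(self, labeled):
        cfg, lon = labeled
        cyt = generate_cytokines(cfg, lon)
        decay = cyt[cyt["marker"] == "MCP-1"].groupby("subject_id")["decay_days"].first()
        truth = lon.data.groupby("subject_id")["true_recovery_day"].first()
        r = np.corrcoef(decay, truth[decay.index])[0, 1]
        assert r == pytest.approx(cfg.mcp1_coupling, abs=0.12)


class TestSpectrum:
    def test_no_peaks_zero_intensity(self):
        spec = generate_spectrum(GeneratorConfig(), [])
        assert np.all(spec.intensity == 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError, match="width"):
            generate_spectrum(GeneratorConfig(), [(2.0, 0.0, 1.0)])

    def test_center_outside_range_rejected(self):
        with pytest.raises(ConfigError, match="range"):
            generate_spectrum(GeneratorConfig(), [(10.0, 0.01, 1.0)])

    def test_total_area_tracks_peak_areas(self):
        spec = generate_spectrum(GeneratorConfig(), [(3.0, 0.02, 2.0), (6.0, 0.02, 3.0)])
        area = np.trapezoid(spec.intensity, spec.ppm)
        assert area == pytest.approx(5.0, rel=1e-3)


class TestInjectOutliers:
    def test_zero_outliers_table_unchanged(self, population):
        out, ids = inject_outliers(population, 0, 50.0)
        assert ids == []
        pd.testing.assert_frame_equal(out.data, population.data)

    def test_outliers_are_farthest_points(self):
        cfg = GeneratorConfig(n_controls=80, n_acute=0, seed=2)
        pop = generate_population(cfg)
        out, ids = inject_outliers(pop, 3, 50.0, seed=9)
        x = out.data[out.variables].to_numpy()
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        dist = np.linalg.norm(z - z.mean(axis=0), axis=1)
        top3 = out.data.loc[np.argsort(dist)[-3:], "sample_id"]
        assert sorted(top3) == sorted(ids)

    def test_seeded_reproducibility(self, population):
        a, ids_a = inject_outliers(population, 2, 10.0, seed=4)
        b, ids_b = inject_outliers(population, 2, 10.0, seed=4)
        assert ids_a == ids_b
        pd.testing.assert_frame_equal(a.data, b.data)
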