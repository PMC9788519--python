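"""Day labeling, spectral binning, DBSCAN sample QC and autoscaling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorevert.errors import ConfigError, DataError
from phenorevert.preprocess import (
    BinGrid,
    QCConfig,
    assign_days_since_covid,
    bin_spectrum,
    extract_glyc_spc,
    log_standardize,
    qc_filter_dbscan,
)
from phenorevert.sampletable import METADATA_COLUMNS, SampleTable
from phenorevert.synthgen import (
    GeneratorConfig,
    Spectrum,
    generate_population,
    generate_spectrum,
    inject_outliers,
)


def _table(rows: list[dict], variables: list[str]) -> SampleTable:
    df = pd.DataFrame(rows)
    for col in METADATA_COLUMNS:
        if col not in df:
            df[col] = [None] * len(df)
    for col in ("collection_date", "hospitalization_date", "covid_report_date"):
        df[col] = pd.to_datetime(df[col])
    return SampleTable(df, variables)


class TestAssignDays:
    def _hospitalized(self, deltas_first, followups=()):
        hosp = pd.Timestamp("2020-05-01")
        rows = []
        for i, d in enumerate([deltas_first] + list(followups)):
            rows.append({
                "sample_id": f"s{i}", "subject_id": "P1", "cohort": "AC" if i == 0 else "RE",
                "collection_date": hosp + pd.Timedelta(days=d),
                "hospitalization_date": hosp, "age": 50.0, "sex": "M",
                "severity": "severe", "vaccinated": False, "x": 1.0,
            })
        return _table(rows, ["x"])

    def test_qualifying_first_sample_becomes_day_zero(self):
        # first sample 3 d post-admission, follow-up 33 d after the first
        out = assign_days_since_covid(self._hospitalized(3, [36]))
        assert out.data["days_since_covid"].tolist() == [0, 33]
        assert out.data["acute"].tolist() == [True, False]

    def test_late_first_sample_counts_from_hospitalization(self):
        out = assign_days_since_covid(self._hospitalized(10))
        assert out.data["days_since_covid"].tolist() == [10]
        assert not out.data["acute"].any()

    def test_nhr_days_from_report_date(self):
        rows = [{"sample_id": "n1", "subject_id": "N1", "cohort": "NHR",
                 "collection_date": pd.Timestamp("2021-09-20"),
                 "covid_report_date": pd.Timestamp("2021-07-07"),
                 "age": 40.0, "sex": "F", "severity": "none",
                 "vaccinated": True, "x": 1.0}]
        out = assign_days_since_covid(_table(rows, ["x"]))
        assert out.data["days_since_covid"].tolist() == [75]

    def test_missing_dates_excluded(self, caplog):
        rows = [{"sample_id": "n1", "subject_id": "N1", "cohort": "NHR",
                 "collection_date": pd.Timestamp("2021-09-20"),
                 "age": 40.0, "sex": "F", "severity": "none",
                 "vaccinated": True, "x": 1.0}]
        with caplog.at_level("WARNING"):
            out = assign_days_since_covid(_table(rows, ["x"]))
        assert len(out) == 0
        assert "covid_report_date" in caplog.text

    def test_invariant_to_row_order(self):
        table = self._hospitalized(3, [36, 60])
        shuffled = SampleTable(
            table.data.iloc[::-1].reset_index(drop=True), table.variables)
        a = assign_days_since_covid(table).data.set_index("sample_id")
        b = assign_days_since_covid(shuffled).data.set_index("sample_id")
        for sid in a.index:
            assert a.loc[sid, "days_since_covid"] == b.loc[sid, "days_since_covid"]
            assert a.loc[sid, "acute"] == b.loc[sid, "acute"]


class TestBinSpectrum:
    def test_grid_has_300_bins(self):
        assert BinGrid().n_bins == 300

    def test_uniform_spectrum_gives_equal_bins_summing_to_one(self):
        grid = BinGrid()
        ppm = np.arange(0.5, 9.5, 0.001)  # 30 points per 0.03-ppm bucket
        bins = bin_spectrum(Spectrum(ppm, np.ones_like(ppm)), grid)
        assert bins.sum() == pytest.approx(1.0)
        nonzero = bins[~grid.excluded_mask()]
        assert np.allclose(nonzero, nonzero[0], rtol=1e-12)
        assert np.all(bins[grid.excluded_mask()] == 0)

    def test_peak_near_glyca_center_dominates_glyca_bin(self):
        grid = BinGrid()
        spec = generate_spectrum(GeneratorConfig(), [(2.05, 0.008, 1.0)])
        bins = bin_spectrum(spec, grid)
        assert int(np.argmax(bins)) == grid.named_bin_index("GlycA")

    def test_all_zero_spectrum_rejected(self):
        ppm = np.linspace(0.5, 9.5, 1001)
        with pytest.raises(DataError, match="normalization"):
            bin_spectrum(Spectrum(ppm, np.zeros_like(ppm)))

    def test_water_region_excluded_from_total(self):
        # intensity only inside the excluded region -> normalization undefined
        ppm = np.linspace(0.5, 9.5, 9001)
        inten = np.where((ppm >= 4.75) & (ppm < 4.95), 1.0, 0.0)
        with pytest.raises(DataError):
            bin_spectrum(Spectrum(ppm, inten))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_global_intensity_scaling(self, scale):
        spec = generate_spectrum(GeneratorConfig(), [(3.0, 0.02, 1.0), (7.0, 0.05, 2.0)])
        base = bin_spectrum(spec)
        scaled = bin_spectrum(Spectrum(spec.ppm, spec.intensity * scale))
        assert np.allclose(base, scaled, atol=1e-12)


class TestExtractGlycSPC:
    def test_flat_spectrum_gives_equal_values(self):
        ppm = np.linspace(0.5, 9.5, 18001)
        vals = extract_glyc_spc(bin_spectrum(Spectrum(ppm, np.ones_like(ppm))))
        assert vals[0] == pytest.approx(vals[1], rel=2e-3)
        assert vals[0] == pytest.approx(vals[2], rel=2e-3)

    def test_spc_peak_dominates_spc_value(self):
        spec = generate_spectrum(GeneratorConfig(), [(3.22, 0.008, 1.0)])
        glyca, glycb, spc = extract_glyc_spc(bin_spectrum(spec))
        assert spc > glyca and spc > glycb

    def test_glyca_glycb_bins_adjacent(self):
        grid = BinGrid()
        ia, ib = grid.named_bin_index("GlycA"), grid.named_bin_index("GlycB")
        assert ib - ia == 1

    def test_bins_distinct(self):
        grid = BinGrid()
        idx = {grid.named_bin_index(n) for n in ("GlycA", "GlycB", "SPC")}
        assert len(idx) == 3


def _naive_dbscan_noise(z: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Reference O(n^2) DBSCAN: a point is noise iff it is not a core point
    and not within eps of any core point."""
    d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    neighbors = (d <= eps).sum(axis=1)  # includes self
    core = neighbors >= min_pts
    reachable = (d[:, core] <= eps).any(axis=1) if core.any() else np.zeros(len(z), bool)
    return ~(core | reachable)


class TestQCFilter:
    def test_tight_cluster_nothing_discarded(self):
        cfg = GeneratorConfig(n_controls=100, n_acute=0, seed=1)
        pop = generate_population(cfg)
        kept, discarded = qc_filter_dbscan(pop, QCConfig(eps=50.0))
        assert discarded == []
        assert len(kept) == 100

    def test_injected_outliers_discarded(self):
        cfg = GeneratorConfig(n_controls=100, n_acute=0, seed=2)
        pop, ids = inject_outliers(generate_population(cfg), 3, 50.0, seed=9)
        kept, discarded = qc_filter_dbscan(pop)
        assert sorted(discarded) == sorted(ids)
        assert len(kept) == 97

    def test_defaults_match_protocol(self):
        qc = QCConfig()
        assert qc.min_pts == 5 and qc.eps == 20.0

    def test_too_few_samples_rejected(self):
        cfg = GeneratorConfig(n_controls=3, n_acute=0, seed=3)
        with pytest.raises(DataError, match="min_pts"):
            qc_filter_dbscan(generate_population(cfg))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        z = rng.normal(size=(n, 5))
        # plant a few dispersed points so noise actually occurs
        z[: max(1, n // 20)] += rng.normal(scale=20, size=(max(1, n // 20), 5))
        eps = float(rng.uniform(1.0, 6.0))
        zstd = (z - z.mean(axis=0)) / z.std(axis=0)
        expected = _naive_dbscan_noise(zstd, eps, 5)
        from sklearn.cluster import DBSCAN
        got = DBSCAN(eps=eps, min_samples=5).fit_predict(zstd) == -1
        assert np.array_equal(expected, got)


class TestLogStandardize:
    def test_training_mode_centers_and_scales(self, population):
        z, stats = log_standardize(population)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_projection_of_training_table_is_identical(self, population):
        z, stats = log_standardize(population)
        z2, _ = log_standardize(population, stats)
        assert np.allclose(z.to_numpy(), z2.to_numpy())

    def test_doubling_a_variable_leaves_standardized_column_unchanged(self, population):
        z, _ = log_standardize(population)
        doubled = population.copy()
        doubled.data["Glucose"] *= 2.0
        z2, _ = log_standardize(doubled)
        assert np.allclose(z["Glucose"], z2["Glucose"])

    def test_zeros_replaced_by_half_minimum(self):
        df = pd.DataFrame({"v": [0.0, 2.0, 4.0, 8.0]})
        z, stats = log_standardize(df)
        assert stats.zero_replacement["v"] == 1.0  # half of min positive (2)
        assert np.isfinite(z.to_numpy()).all()

    def test_constant_variable_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with caplog.at_level("WARNING"):
            z, stats = log_standardize(df)
        assert "b" not in z.columns
        assert "constant" in caplog.text

    def test_projection_missing_variable_rejected(self, population):
        _, stats = log_standardize(population)
        with pytest.raises(DataError, match="missing"):
            log_standardize(pd.DataFrame({"Glucose": [1.0, 2.0]}), stats)
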