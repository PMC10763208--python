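import numpy as np
import pandas as pd
import pytest

from leaflayers import (
    BandDefinition,
    GAConfig,
    InversionResult,
    LayerPartition,
    LeafBiochem,
    LeafSpectrum,
    TwoLayerLeafModel,
    UniformLeafModel,
    default_bands,
    invert_sample,
    parameter_correlations,
    rmse,
    summarize_parameters,
    two_layer_forward,
)
from leaflayers.inversion import band_mask


class TestBands:
    def test_default_bands_partition_the_grid(self, grid):
        masks = [band_mask(grid, b) for b in default_bands()]
        total = np.zeros(len(grid), dtype=int)
        for m in masks:
            total += m
        assert np.all(total == 1)  # each band owned exactly once
        assert masks[0].sum() == 161  # [400, 560]
        assert masks[1].sum() == 220  # (560, 780]
        assert masks[2].sum() == 220  # (780, 1000]

    def test_band_edges_owned_by_left_band(self, grid):
        blue, yellow, _ = default_bands()
        i560 = np.searchsorted(grid.wavelengths, 560)
        assert band_mask(grid, blue)[i560]
        assert not band_mask(grid, yellow)[i560]

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 700, 600)


class TestRmse:
    def test_zero_on_identical_spectra(self, grid):
        R = np.random.default_rng(0).uniform(0.1, 0.6, 601)
        for band in (None, *default_bands()):
            assert rmse(R, R, band, grid) == 0.0

    def test_constant_relative_offset_closed_form(self, grid):
        """R_mod = R_meas (1 + c) gives |c| * rms(R_meas) / mean(R_meas)."""
        rng = np.random.default_rng(1)
        R = rng.uniform(0.1, 0.6, 601)
        c = 0.17
        band = default_bands()[1]
        m = band_mask(grid, band)
        expected = c * np.sqrt(np.mean(R[m] ** 2)) / np.mean(R[m])
        assert rmse(R, R * (1 + c), band, grid) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_loop(self, grid):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0.1, 0.7, 601), rng.uniform(0.1, 0.7, 601)
        acc = sum((x - y) ** 2 for x, y in zip(a, b))
        naive = np.sqrt(acc / 601) / (sum(a) / 601)
        assert rmse(a, b, None, grid) == pytest.approx(naive, abs=1e-12)

    def test_plain_variant_is_unnormalized(self, grid):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0.1, 0.7, 601), rng.uniform(0.1, 0.7, 601)
        plain = rmse(a, b, None, grid, relative=False)
        assert rmse(a, b, None, grid) == pytest.approx(plain / np.mean(a), abs=1e-12)

    def test_zero_mean_reflectance_rejected(self, grid):
        with pytest.raises(ValueError):
            rmse(np.zeros(601), np.ones(601) * 0.1, None, grid)


def _results_from_partitions(parts):
    return [
        InversionResult(
            sample_id=f"s{i}",
            partition=p,
            fitness=0.0,
            rmse_full=0.0,
            rmse_by_band={},
            trace=np.zeros(1),
        )
        for i, p in enumerate(parts)
    ]


class TestSummaries:
    def test_single_result_degenerate_stats(self):
        parts = [LayerPartition(2.0, 0.5, 0.9, 0.8)]
        tab = summarize_parameters(_results_from_partitions(parts))
        assert tab.loc["Min", "N2"] == tab.loc["Max", "N2"] == tab.loc["Mean", "N2"]
        assert tab.loc["Variance", "cab12"] == 0.0

    def test_two_results_hand_arithmetic(self):
        parts = [
            LayerPartition(2.0, 0.5, 0.8, 0.8),
            LayerPartition(2.0, 0.5, 1.0, 0.8),
        ]
        tab = summarize_parameters(_results_from_partitions(parts))
        assert tab.loc["Mean", "cab12"] == pytest.approx(0.9)
        assert tab.loc["Variance", "cab12"] == pytest.approx(0.01)

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(4)
        parts = [
            LayerPartition(
                rng.uniform(2, 2.05), rng.uniform(0.1, 3),
                rng.uniform(0, 1), rng.uniform(0, 1),
            )
            for _ in range(100)
        ]
        tab = summarize_parameters(_results_from_partitions(parts))
        vals = np.array([p.N2 for p in parts])
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        assert tab.loc["Mean", "N2"] == pytest.approx(mean, abs=1e-10)
        assert tab.loc["Variance", "N2"] == pytest.approx(var, abs=1e-10)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        parts = [
            LayerPartition(2.0, rng.uniform(0.1, 3), rng.uniform(0, 1), 0.5)
            for _ in range(20)
        ]
        a = summarize_parameters(_results_from_partitions(parts))
        b = summarize_parameters(_results_from_partitions(parts[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_parameters([])


class TestCorrelations:
    def _biochems(self, cabs):
        return [LeafBiochem(N=1.0, cab=c, cw=0.01, cm=0.005) for c in cabs]

    def test_perfectly_linear_pair(self):
        cabs = [10.0, 20.0, 30.0, 40.0]
        parts = [LayerPartition(2.0, 0.1 + 0.01 * c, 0.5, 0.5) for c in cabs]
        tab = parameter_correlations(_results_from_partitions(parts), self._biochems(cabs))
        assert tab.loc["N2", "cab"] == pytest.approx(1.0)

    def test_anti_linear_pair(self):
        cabs = [10.0, 20.0, 30.0, 40.0]
        parts = [LayerPartition(2.0, 3.0 - 0.05 * c, 0.5, 0.5) for c in cabs]
        tab = parameter_correlations(_results_from_partitions(parts), self._biochems(cabs))
        assert tab.loc["N2", "cab"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        cabs = rng.uniform(10, 100, 30)
        n2 = rng.uniform(0.1, 3, 30)
        parts = [LayerPartition(2.0, v, 0.5, 0.5) for v in n2]
        tab = parameter_correlations(_results_from_partitions(parts), self._biochems(cabs))
        x, y = n2, cabs
        r_oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert tab.loc["N2", "cab"] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        cabs = [10.0, 20.0, 30.0]
        parts = [LayerPartition(2.0, 0.5, 0.5, 0.5) for _ in cabs]
        tab = parameter_correlations(_results_from_partitions(parts), self._biochems(cabs))
        assert np.isnan(tab.loc["N2", "cab"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            parameter_correlations([], [])


class TestModelFitting:
    def test_self_inversion_recovers_partition(self, constants):
        bio = LeafBiochem(N=1.0, cab=40.0, cw=0.02, cm=0.006)
        truth = LayerPartition(N1=2.005, N2=0.6, cab12=0.85, cm12=0.7)
        measured = two_layer_forward(constants, bio, truth)
        res = TwoLayerLeafModel(
            measured, bio, constants, config=GAConfig(pop_size=60, generations=80, seed=2)
        ).fit()
        assert abs(res.partition.cab12 - truth.cab12) < 0.05
        assert res.fitness < 6.01

    def test_fit_is_deterministic(self, constants, biochem, partition, fast_ga):
        measured = two_layer_forward(constants, biochem, partition)
        a = TwoLayerLeafModel(measured, biochem, constants, config=fast_ga).fit()
        b = TwoLayerLeafModel(measured, biochem, constants, config=fast_ga).fit()
        assert a.params.equals(b.params)
        assert np.array_equal(a.trace, b.trace)

    def test_zero_generations_returns_best_of_initial_population(
        self, constants, biochem, partition
    ):
        measured = two_layer_forward(constants, biochem, partition)
        cfg = GAConfig(pop_size=16, generations=0, seed=9)
        model = TwoLayerLeafModel(measured, biochem, constants, config=cfg)
        res = model.fit()
        X0 = np.random.default_rng(9).random((16, 4))
        y0 = model._objective(X0)
        assert res.fitness == pytest.approx(float(y0.min()), abs=1e-9)

    def test_band_split_mode_runs_and_reports_compromise(
        self, constants, biochem, partition
    ):
        measured = two_layer_forward(constants, biochem, partition)
        cfg = GAConfig(pop_size=20, generations=10, seed=1, divisions=6)
        res = TwoLayerLeafModel(
            measured, biochem, constants, config=cfg, mode="bands"
        ).fit()
        assert res.fitness >= 0
        assert set(res.rmse_by_band) == {b.name for b in default_bands()}

    def test_invert_sample_wraps_model(self, constants, biochem, partition, fast_ga):
        measured = two_layer_forward(constants, biochem, partition)
        res = invert_sample(measured, biochem, constants, fast_ga, sample_id="x1")
        assert res.sample_id == "x1"
        assert res.fitness >= 0
        direct = TwoLayerLeafModel(measured, biochem, constants, config=fast_ga).fit()
        assert res.fitness == pytest.approx(direct.fitness)

    def test_uniform_baseline_recovers_structure(self, constants):
        from leaflayers import uniform_forward

        bio = LeafBiochem(N=1.8, cab=35.0, cw=0.015, cm=0.005)
        measured = uniform_forward(constants, bio)
        res = UniformLeafModel(
            measured, bio, constants, config=GAConfig(pop_size=30, generations=40, seed=4)
        ).fit()
        assert res.N_fitted == pytest.approx(1.8, abs=0.05)
        assert res.rmse_full < 0.01

    def test_baseline_self_fit_recovers_within_noise_floor(self, constants):
        """Uniform-leaf spectra + noise: the fitted baseline reconstructs the
        clean spectrum to better than the injected noise level."""
        from leaflayers import uniform_forward

        rng = np.random.default_rng(77)
        for _ in range(3):
            bio = LeafBiochem(
                N=rng.uniform(1.2, 2.5), cab=rng.uniform(10, 80),
                cw=rng.uniform(0.004, 0.05), cm=rng.uniform(0.002, 0.012),
            )
            clean = uniform_forward(constants, bio).R
            noisy = np.clip(clean + rng.normal(0, 0.01, clean.shape), 0, 1)
            meas = LeafSpectrum(grid=constants.grid, R=noisy)
            res = UniformLeafModel(
                meas, bio, constants,
                config=GAConfig(pop_size=30, generations=40, seed=3),
            ).fit()
            floor = rmse(noisy, clean, None, constants.grid)
            recovery = rmse(clean, res.fitted_spectrum.R, None, constants.grid)
            assert recovery <= floor

    def test_summary_contains_parameters_and_metrics(
        self, constants, biochem, partition, fast_ga
    ):
        measured = two_layer_forward(constants, biochem, partition)
        res = TwoLayerLeafModel(measured, biochem, constants, config=fast_ga).fit()
        text = res.summary()
        for token in ("N1", "N2", "cab12", "cm12", "fitness", "RMSE"):
            assert token in text
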