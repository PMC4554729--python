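import json

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from secrbayes.covariates.kriging import empirical_variogram
from secrbayes.data_model import build_capture_history, read_capture_records, read_trap_deployment
from secrbayes.errors import ConfigError
from secrbayes.state_space import read_state_space
from secrbayes.synthetic import (
    gaussian_random_field,
    generate_scenario,
    generate_sign_survey,
    generate_trap_grid,
)


class TestTrapGrid:
    def test_default_design_sixty_traps(self):
        traps = generate_trap_grid(5, 4, 4.0, 3, 1000.0, seed=0, n_occasions=93)
        assert traps.n_traps == 60
        assert traps.trap_days == 60 * 93

    def test_min_spacing_by_construction(self):
        traps = generate_trap_grid(5, 4, 4.0, 3, 1000.0, seed=1, n_occasions=5)
        assert pdist(traps.coords()).min() >= 1000.0

    def test_single_cell_single_trap(self):
        traps = generate_trap_grid(1, 1, 4.0, 1, 500.0, seed=2, n_occasions=3)
        assert traps.n_traps == 1
        assert 0 <= traps.x[0] <= 4000.0 and 0 <= traps.y[0] <= 4000.0

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ConfigError):
            generate_trap_grid(1, 1, 1.0, 3, 1450.0, seed=0)


class TestGaussianRandomField:
    def test_zero_sill_all_zero(self):
        pts = np.random.default_rng(0).random((50, 2)) * 1000
        np.testing.assert_array_equal(gaussian_random_field(pts, 500.0, 0.0, seed=1), 0.0)

    def test_seed_determinism(self):
        pts = np.random.default_rng(0).random((80, 2)) * 1000
        a = gaussian_random_field(pts, 500.0, 2.0, seed=3)
        b = gaussian_random_field(pts, 500.0, 2.0, seed=3)
        c = gaussian_random_field(pts, 500.0, 2.0, seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_variogram_recovery(self):
        """One draw at n=500: empirical semivariogram tracks the model."""
        rng = np.random.default_rng(5)
        pts = rng.random((500, 2)) * 20_000
        sill, range_m = 2.0, 3000.0
        field = gaussian_random_field(pts, range_m, sill, seed=9)
        centers, gammas, counts = empirical_variogram(pts, field, n_bins=10)
        model = sill * (1.0 - np.exp(-centers / range_m))
        # weighted relative agreement across bins
        rel = np.abs(gammas - model) / sill
        assert np.average(rel, weights=counts) < 0.25


class TestSignSurveyGeneration:
    def _centroids(self, n=20):
        return np.column_stack([np.arange(n) * 4000.0, np.zeros(n)])

    def test_strongly_negative_field_no_positives(self):
        c = self._centroids()
        surveys = generate_sign_survey(
            np.full(20, -50.0), np.full(20, -50.0), c, 16, 1.0, seed=0
        )
        assert all(s.n_prey_positive == 0 and s.n_grazing_positive == 0 for s in surveys)

    def test_zero_field_half_positive(self):
        c = self._centroids()
        totals = positives = 0
        for seed in range(30):
            for s in generate_sign_survey(np.zeros(20), np.zeros(20), c, 16, 1.0, seed=seed):
                totals += s.n_segments
                positives += s.n_prey_positive
        assert positives / totals == pytest.approx(0.5, abs=0.03)

    def test_monotone_link(self):
        rng = np.random.default_rng(1)
        c = self._centroids()
        field = rng.normal(0.0, 2.0, size=20)
        surveys = generate_sign_survey(field, field, c, 36, 1.0, seed=2)
        props = np.array([s.n_prey_positive / s.n_segments for s in surveys])
        assert np.corrcoef(field, props)[0, 1] > 0.5

    def test_segment_bounds_enforced(self):
        with pytest.raises(ConfigError):
            generate_sign_survey(np.zeros(2), np.zeros(2), self._centroids(2), 40, 1.0, seed=0)


class TestScenario:
    def test_bitwise_reproducibility(self, coarse_scenario):
        again = generate_scenario(42, pixel_area_km2=7.84)
        np.testing.assert_array_equal(again.traps.x, coarse_scenario.traps.x)
        np.testing.assert_array_equal(again.history.y, coarse_scenario.history.y)
        np.testing.assert_array_equal(again.centers, coarse_scenario.centers)
        np.testing.assert_array_equal(again.elevation, coarse_scenario.elevation)
        assert [s == t for s, t in zip(again.surveys, coarse_scenario.surveys)]

    def test_density_zero_empty_history(self):
        sc = generate_scenario(3, density=0.0, pixel_area_km2=7.84)
        assert sc.history is None and sc.n_true == 0

    def test_masked_area_matches_psi_density_consistency(self, coarse_scenario):
        p = coarse_scenario.params
        implied = p["psi"] * p["M"] / coarse_scenario.state_space.suitable_area_km2 * 100.0
        assert implied == pytest.approx(p["density_target"], rel=0.01)

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigError):
            generate_scenario(1, bogus=3)

    def test_write_roundtrip(self, tmp_path, coarse_scenario):
        sc = coarse_scenario
        out = tmp_path / "bundle"
        sc.write(out)
        traps = read_trap_deployment(out / "traps.csv")
        np.testing.assert_allclose(traps.x, sc.traps.x)
        ss = read_state_space(out / "statespace.csv", sc.params["pixel_area_km2"])
        np.testing.assert_array_equal(ss.suitable, sc.state_space.suitable)
        records = read_capture_records(out / "captures.csv")
        hist = build_capture_history(records, traps, None)
        np.testing.assert_array_equal(hist.y, sc.history.y)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 42
        assert manifest["n_true"] == sc.n_true
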