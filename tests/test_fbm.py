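"""Tests for the exact FBM sampler against its closed-form statistics."""

import numpy as np
import pytest

from fbmdrop.fbm import (
    FBMParams,
    ParameterError,
    _fgn_hosking,
    fbm_covariance,
    generate_fbm_1d,
    generate_fbm_2d,
    increment_correlation,
    sample_fbm_paths,
)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(hurst=0.0), "hurst"),
        (dict(hurst=1.0), "hurst"),
        (dict(hurst=-0.3), "hurst"),
        (dict(hurst=0.5, sigma=0.0), "sigma"),
        (dict(hurst=0.5, sigma=-1.0), "sigma"),
        (dict(hurst=0.5, dt=0.0), "dt"),
        (dict(hurst=0.5, t_max=0.001, dt=0.01), "t_max"),
    ],
)
def test_invalid_params_name_offending_field(kwargs, field):
    with pytest.raises(ParameterError, match=field):
        FBMParams(**kwargs)


class TestCovarianceClosedForm:
    def test_variance_power_law(self):
        p = FBMParams(hurst=0.7, sigma=2.0)
        for t in (0.5, 1.0, 3.0):
            assert fbm_covariance(t, t, p) == pytest.approx(4.0 * t**1.4)

    def test_zero_time_gives_zero(self):
        p = FBMParams(hurst=0.3)
        assert fbm_covariance(0.0, 5.0, p) == 0.0

    def test_brownian_special_case_is_min(self):
        p = FBMParams(hurst=0.5)
        assert fbm_covariance(2.0, 5.0, p) == pytest.approx(2.0)
        assert fbm_covariance(7.0, 3.0, p) == pytest.approx(3.0)

    def test_negative_time_rejected(self):
        p = FBMParams(hurst=0.5)
        with pytest.raises(ParameterError):
            fbm_covariance(-1.0, 2.0, p)


class TestIncrementCorrelation:
    @pytest.mark.parametrize(
        "h, expected",
        [(0.5, 0.0), (0.9, 2.0**0.8 - 1.0), (0.1, 2.0**-0.8 - 1.0)],
    )
    def test_values(self, h, expected):
        assert increment_correlation(h) == pytest.approx(expected)

    def test_signs_match_diffusion_regimes(self):
        assert increment_correlation(0.2) < 0  # anti-persistent
        assert increment_correlation(0.8) > 0  # persistent

    @pytest.mark.parametrize("h", [0.0, 1.0, -0.1])
    def test_out_of_range_rejected(self, h):
        with pytest.raises(ParameterError):
            increment_correlation(h)


class TestSampling:
    def test_path_starts_at_origin_and_has_expected_length(self):
        p = FBMParams(hurst=0.3, t_max=2.0, dt=0.1, seed=0)
        path = generate_fbm_1d(p)
        assert path.values[0] == 0.0
        assert len(path.values) == p.n_steps + 1 == 21
        assert np.allclose(np.diff(path.times), 0.1)

    def test_seed_determinism_bit_identical(self):
        p = FBMParams(hurst=0.8, t_max=1.0, dt=0.01, seed=42)
        a = generate_fbm_1d(p)
        b = generate_fbm_1d(p)
        assert np.array_equal(a.values, b.values)

    def test_brownian_variance_linear_in_time(self, rng):
        p = FBMParams(hurst=0.5, t_max=8.0, dt=1.0)
        paths = sample_fbm_paths(p, 20000, rng)
        var = paths.var(axis=0)
        assert np.allclose(var[1:], p.times[1:], rtol=0.06)

    def test_empirical_covariance_matches_closed_form(self, rng, fast_params):
        """Monte-Carlo covariance of sampled paths vs the analytic oracle."""
        n = 20000
        paths = sample_fbm_paths(fast_params, n, rng)
        emp = np.cov(paths[:, 1:].T)
        t = fast_params.times[1:]
        theo = np.array([[fbm_covariance(a, b, fast_params) for b in t] for a in t])
        se = np.sqrt((np.outer(np.diag(theo), np.diag(theo)) + theo**2) / n)
        assert np.all(np.abs(emp - theo) < 4.0 * se)

    def test_hosking_fallback_agrees_with_closed_form(self, rng):
        """The O(n^2) recursion is a second exact route to the same law."""
        p = FBMParams(hurst=0.7, t_max=12.0, dt=1.0)
        fgn = _fgn_hosking(p, 12, 30000, rng)
        paths = np.cumsum(fgn, axis=1)
        emp = np.cov(paths.T)
        t = p.times[1:]
        theo = np.array([[fbm_covariance(a, b, p) for b in t] for a in t])
        se = np.sqrt((np.outer(np.diag(theo), np.diag(theo)) + theo**2) / 30000)
        assert np.all(np.abs(emp - theo) < 4.0 * se)

    def test_self_similarity_sd_scales_as_t_to_h(self, rng):
        """Regress log SD of B(T) on log T; slope recovers H within 0.05."""
        h = 0.7
        sds = []
        horizons = [1.0, 4.0, 16.0]
        for t_max in horizons:
            p = FBMParams(hurst=h, t_max=t_max, dt=t_max / 32)
            paths = sample_fbm_paths(p, 20000, rng)
            sds.append(paths[:, -1].std())
        slope = np.polyfit(np.log(horizons), np.log(sds), 1)[0]
        assert slope == pytest.approx(h, abs=0.05)


class TestPlanarPaths:
    def test_origin_translation(self):
        p = FBMParams(hurst=0.9, t_max=1.0, dt=0.1, seed=7)
        path = generate_fbm_2d(p, origin=(0.3, 0.7))
        assert path.values[0] == pytest.approx([0.3, 0.7])
        assert path.values.shape == (11, 2)

    def test_coordinates_are_distinct_draws(self):
        p = FBMParams(hurst=0.9, t_max=1.0, dt=0.01, seed=3)
        path = generate_fbm_2d(p)
        assert not np.allclose(path.values[:, 0], path.values[:, 1])

    def test_coordinate_independence(self, rng):
        """x and y displacements of many paths are uncorrelated."""
        p = FBMParams(hurst=0.5, t_max=1.0, dt=0.125)
        n = 20000
        xy = sample_fbm_paths(p, 2 * n, rng)
        dx, dy = xy[:n, -1], xy[n:, -1]
        corr = np.corrcoef(dx, dy)[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(n)

    def test_csv_round_trip(self, tmp_path):
        p = FBMParams(hurst=0.6, t_max=0.5, dt=0.1, seed=1)
        path = generate_fbm_2d(p, origin=(0.1, 0.2))
        out = tmp_path / "path.csv"
        path.to_csv(out)
        text = out.read_text()
        assert text.splitlines()[0] == "t,x,y"
        assert len(text.splitlines()) == p.n_steps + 2
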