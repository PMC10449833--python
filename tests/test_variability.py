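"""Tests for the propagation of trial-by-trial input statistics."""

import numpy as np
import pytest

from epsvnet.drive import InputDistribution, InputSpec, build_covariance
from epsvnet.engine import TrialProtocol
from epsvnet.tf import TFGrid, interpolate_tf
from epsvnet.variability import (
    TrialCovariance,
    find_operating_regimes,
    map_through_tf,
    simulate_trial_covariance,
    sweep_factor_variability,
    sweep_mean_variability,
)


def _delta_method_e_variance(grid, dist, h=1e-4):
    """First-order (delta-method) output variance: grad f . sigma . grad f,
    with the gradient of the interpolated E transfer-function estimated
    by central finite differences at the cloud mean."""
    grad = np.empty(3)
    for d in range(3):
        e = np.zeros(3)
        e[d] = h
        hi = interpolate_tf(grid, dist.mu + e, populations=("PC",))[0]
        lo = interpolate_tf(grid, dist.mu - e, populations=("PC",))[0]
        grad[d] = (hi - lo) / (2 * h)
    return float(grad @ dist.sigma @ grad)


class TestMapThroughTf:
    def test_zero_covariance_gives_zero_variance(self, smooth_grid):
        dist = InputDistribution(mu=np.array([1.0, 0.5, -0.5]), sigma=np.zeros((3, 3)))
        mapped = map_through_tf(smooth_grid, dist, n=500, seed=1)
        assert mapped.e_variance == pytest.approx(0.0, abs=1e-20)

    def test_small_sigma_variance_matches_delta_method(self, smooth_grid):
        """In the small-noise regime the sampled output variance agrees
        with the first-order analytic propagation within 10%, across
        10 random distributions."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            mu = rng.uniform(-4, 4, size=3)
            stds = rng.uniform(0.05, 0.15, size=3)
            rho = rng.uniform(-0.5, 0.5)
            sigma = np.diag(stds**2)
            sigma[0, 1] = sigma[1, 0] = rho * stds[0] * stds[1]
            dist = InputDistribution(mu=mu, sigma=sigma)
            mapped = map_through_tf(smooth_grid, dist, n=20_000, seed=7)
            expected = _delta_method_e_variance(smooth_grid, dist)
            assert mapped.e_variance == pytest.approx(expected, rel=0.10)

    def test_wide_distribution_rejected(self, smooth_grid):
        dist = InputDistribution(mu=np.zeros(3), sigma=36.0 * np.eye(3))
        with pytest.raises(ValueError, match="too wide"):
            map_through_tf(smooth_grid, dist, n=2000, seed=3)

    def test_cloud_clipped_at_rate_floor(self, smooth_grid):
        """Points that would push a final input rate negative are clipped
        to the floor, not discarded."""
        spec = InputSpec(baseline={"PC": 16.0, "PV": 90.0, "SST": 2.0, "VIP": 12.0})
        dist = InputDistribution(
            mu=np.array([0.0, 0.0, -1.5]), sigma=np.diag([0.1, 0.1, 1.0])
        )
        mapped = map_through_tf(smooth_grid, dist, n=4000, seed=5, spec=spec)
        assert mapped.n_clipped_rate > 0
        assert len(mapped.outputs) == 4000
        assert mapped.inputs[:, 2].min() >= -2.0

    def test_output_covariance_shape_and_symmetry(self, smooth_grid):
        dist = InputDistribution(mu=np.zeros(3), sigma=np.eye(3))
        mapped = map_through_tf(smooth_grid, dist, n=5000, seed=2)
        assert mapped.covariance.shape == (3, 3)
        assert np.allclose(mapped.covariance, mapped.covariance.T)
        assert np.all(np.linalg.eigvalsh(mapped.covariance) >= -1e-12)


class TestSimulateTrialCovariance:
    def test_requires_two_trials(self, ei_net):
        dist = InputDistribution(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            simulate_trial_covariance(ei_net, InputSpec(), dist, n_trials=1)

    def test_sample_covariance_is_symmetric_psd(self, ei_net):
        dist = InputDistribution(
            mu=np.zeros(3), sigma=build_covariance((1.8, 0.6, 0.6), (0.3, 0.0, 0.0))
        )
        protocol = TrialProtocol(total=600.0, preparation=200.0, settle=100.0, measure=300.0)
        tc = simulate_trial_covariance(
            ei_net, InputSpec(), dist, n_trials=8, protocol=protocol, seed=31
        )
        assert np.allclose(tc.matrix, tc.matrix.T)
        assert np.all(np.linalg.eigvalsh(tc.matrix) >= -1e-9)
        assert tc.e_variance >= 0
        assert tc.n_trials == 8

    def test_deterministic_given_seed(self, ei_net):
        dist = InputDistribution(mu=np.zeros(3), sigma=0.25 * np.eye(3))
        protocol = TrialProtocol(total=400.0, preparation=100.0, settle=100.0, measure=200.0)
        a = simulate_trial_covariance(ei_net, InputSpec(), dist, 4, protocol, seed=9)
        b = simulate_trial_covariance(ei_net, InputSpec(), dist, 4, protocol, seed=9)
        assert np.array_equal(a.matrix, b.matrix)


class TestSweeps:
    def test_mean_sweep_values_nonnegative_and_unmasked_inside_hull(self, smooth_grid):
        vm = sweep_mean_variability(
            smooth_grid,
            (np.array([-2.0, 0.0, 2.0]), np.array([-2.0, 0.0, 2.0]), np.array([0.0])),
            n=2000, seed=1,
        )
        assert vm.values.shape == (3, 3, 1)
        assert not vm.mask.any()
        assert np.all(vm.values >= 0)
        assert np.all(vm.std == np.sqrt(vm.values))

    def test_mean_sweep_masks_cells_outside_hull(self, smooth_grid):
        vm = sweep_mean_variability(
            smooth_grid,
            (np.array([0.0, 50.0]), np.array([0.0]), np.array([0.0])),
            n=1000, seed=1,
        )
        assert not vm.mask[0, 0, 0]
        assert vm.mask[1, 0, 0]
        assert np.isnan(vm.values[1, 0, 0])

    def test_covariance_sweep_masks_non_psd_cells(self, smooth_grid):
        """Cells rejected by the PSD screen coincide exactly with a direct
        eigenvalue test of the assembled matrix."""
        ep_axis = np.linspace(-1.5, 1.5, 7)
        es_axis = np.linspace(-1.5, 1.5, 7)
        variances = (1.8, 0.6, 0.6)
        vm = sweep_factor_variability(
            smooth_grid, np.zeros(3), ep_axis, es_axis,
            factor="covariance", variances=variances, n=1000, seed=4,
        )
        for i, ep in enumerate(ep_axis):
            for j, es in enumerate(es_axis):
                sigma = np.array(
                    [
                        [1.8, ep, es],
                        [ep, 0.6, 0.0],
                        [es, 0.0, 0.6],
                    ]
                )
                is_psd = np.linalg.eigvalsh(sigma).min() >= -1e-10
                assert vm.mask[i, j] == (not is_psd)

    def test_balance_sweep_produces_values_on_valid_cells(self, smooth_grid):
        vm = sweep_factor_variability(
            smooth_grid, np.zeros(3),
            np.array([-3.0, -1.0, 1.0, 3.0]), np.array([-3.0, -1.0, 1.0, 3.0]),
            factor="balance", total_variance=3.0, cov_magnitude=0.5,
            n=1000, seed=4,
        )
        assert (~vm.mask).sum() > 0
        assert np.all(vm.values[~vm.mask] >= 0)

    def test_anticorrelated_ei_inputs_maximise_variance(self, linear_grid):
        """With a transfer-function that rises in E-drive and falls in
        P-drive, an anti-correlated E-P cloud is orthogonal to the
        iso-rate planes and yields a larger output variance than a
        correlated cloud of the same total variance."""
        mu = np.zeros(3)
        corr = build_covariance((1.0, 1.0, 0.2), (0.9, 0.0, 0.0))
        anti = build_covariance((1.0, 1.0, 0.2), (-0.9, 0.0, 0.0))
        v_corr = map_through_tf(
            linear_grid, InputDistribution(mu=mu, sigma=corr), n=20000, seed=6
        ).e_variance
        v_anti = map_through_tf(
            linear_grid, InputDistribution(mu=mu, sigma=anti), n=20000, seed=6
        ).e_variance
        assert v_anti > v_corr

    def test_dataframe_export(self, smooth_grid):
        vm = sweep_factor_variability(
            smooth_grid, np.zeros(3), np.array([0.0, 0.3]), np.array([0.0, 0.3]),
            factor="covariance", n=500, seed=2,
        )
        df = vm.to_dataframe()
        assert len(df) == 4
        assert {"σ_EP", "σ_ES", "e_variance", "rejected"} <= set(df.columns)


class TestOperatingRegimes:
    def test_regimes_found_on_synthetic_grid(self):
        """A grid constructed with known PV-high/SST-low and SST-high/
        PV-low corners yields the expected regime locations."""
        ax = np.linspace(-4.0, 4.0, 5)
        grid = TFGrid.from_function(
            (ax, ax, ax),
            {
                "PC": lambda e, p, s: 5.0 + 0.0 * e,
                "PV": lambda e, p, s: 10.0 + p - s,
                "SST": lambda e, p, s: 10.0 - p + s,
            },
        )
        regimes = find_operating_regimes(grid)
        pv = regimes["pv_dominated"]
        sst = regimes["sst_dominated"]
        assert pv[1] == 4.0 and pv[2] == -4.0  # high P drive, low S drive
        assert sst[1] == -4.0 and sst[2] == 4.0
        mixed = regimes["mixed"]
        assert abs(mixed[1] - mixed[2]) <= 8.0


def test_trial_covariance_validation():
    with pytest.raises(ValueError):
        TrialCovariance(matrix=np.ones((2, 2)), n_trials=10)
    m = np.array([[1.0, 0.2, 0.0], [0.3, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError):
        TrialCovariance(matrix=m, n_trials=10)
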