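"""Monte Carlo sliding simulator: walk statistics and trace rendering."""

import numpy as np
import pytest

from slidefret import (FilamentGeometry, FretCoupling, SlideSimConfig,
                       fret_efficiencies, fret_from_distance,
                       pearson_correlation, register_to_distance,
                       render_intensities, simulate_slide_trace,
                       simulate_three_color, simulate_trajectory)
from slidefret.slide_sim import (alignment_center, allowed_range,
                                 micro_steps_per_frame, register_diffusion)


@pytest.fixture
def geometry():
    return FilamentGeometry(filament_length=99, duplex_length=39)


class TestTrajectory:
    def test_zero_diffusion_is_static(self, geometry):
        cfg = SlideSimConfig(d_um2=0.0, n_frames=10, seed=1)
        pos = simulate_trajectory(cfg, geometry, n_steps=100)
        assert np.all(pos == pos[0])

    def test_reflecting_bounds_respected(self, geometry):
        cfg = SlideSimConfig(d_um2=0.9e-3, n_frames=5, x_max=10.0, seed=3)
        pos = simulate_trajectory(cfg, geometry, n_steps=50_000)
        assert pos.min() >= 0.0 and pos.max() <= 10.0

    def test_msd_slope_matches_diffusion_coefficient(self, geometry):
        """Time-origin-averaged MSD of the free walk grows as 2 D t within 5 %."""
        cfg = SlideSimConfig(d_um2=0.9e-3, n_frames=1, seed=17)
        d_reg = register_diffusion(cfg, geometry)
        tau_micro = cfg.step_size**2 / (2 * d_reg)
        n_steps, n_walks, max_lag = 10_000, 100, 100
        rng = np.random.default_rng(17)
        lags = np.arange(1, max_lag + 1)
        msd = np.zeros(max_lag)
        for _ in range(n_walks):
            x = simulate_trajectory(cfg, geometry, n_steps=n_steps, rng=rng,
                                    bounded=False)
            for i, lag in enumerate(lags):
                msd[i] += np.mean((x[lag:] - x[:-lag]) ** 2)
        msd /= n_walks
        slope = np.polyfit(lags * tau_micro, msd, 1)[0]
        assert slope == pytest.approx(2 * d_reg, rel=0.05)

    def test_bounded_occupancy_uniform(self, geometry):
        """Detailed balance: long bounded walk occupies [0, X] uniformly."""
        cfg = SlideSimConfig(d_um2=0.9e-3, x_max=10.0, seed=5)
        pos = simulate_trajectory(cfg, geometry, n_steps=2_000_000, x_init=5.0)
        counts, _ = np.histogram(pos, bins=10, range=(0, 10))
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.1) < 0.02)

    def test_zero_range_with_diffusion_warns(self):
        g = FilamentGeometry(filament_length=9, duplex_length=9)
        cfg = SlideSimConfig(d_um2=0.9e-3, n_frames=5, x_max=0.0)
        with pytest.warns(UserWarning):
            simulate_trajectory(cfg, g, n_steps=10)


class TestRenderIntensities:
    def test_static_position_closed_form(self, geometry):
        cfg = SlideSimConfig(d_um2=0.0, n_frames=50, seed=2)
        coupling = FretCoupling()
        center = alignment_center(cfg, geometry)
        x0 = 30.0
        pos = np.full(50 * micro_steps_per_frame(cfg, geometry), x0)
        tr = render_intensities(pos, geometry, coupling, cfg, noise=False)
        e = fret_from_distance(register_to_distance(x0, center, geometry),
                               coupling)
        assert np.allclose(tr.channels["acceptor1"], 500 * e)
        assert np.allclose(tr.channels["donor"], 500 * (1 - e))

    def test_noiseless_channel_sum_is_budget(self, geometry):
        cfg = SlideSimConfig(n_frames=200, seed=4)
        tr = simulate_slide_trace(cfg, geometry, noise=False)
        total = tr.channels["donor"] + tr.channels["acceptor1"]
        assert np.allclose(total, 500.0)

    def test_noise_inflates_sum_variance_as_two_gaussians(self, geometry):
        cfg = SlideSimConfig(d_um2=0.0, n_frames=10_000, noise_amplitude=40.0,
                             seed=6)
        tr = simulate_slide_trace(cfg, geometry, noise=True)
        resid = tr.total_intensity() - 500.0
        assert np.std(resid) == pytest.approx(np.sqrt(2) * 40.0, rel=0.05)

    def test_mean_fret_falls_with_filament_length(self):
        """Longer filaments dilute time near the acceptor: lower mean E."""
        means = []
        for L in (21, 39, 99):
            cfg = SlideSimConfig(n_frames=3000, seed=8)
            g = FilamentGeometry(filament_length=L, duplex_length=39)
            tr = simulate_slide_trace(cfg, g, noise=False)
            means.append(float(np.mean(tr.channels["acceptor1"])) / 500.0)
        assert means[0] > means[1] > means[2]

    def test_length_mismatch_rejected(self, geometry):
        cfg = SlideSimConfig(n_frames=10)
        with pytest.raises(ValueError):
            render_intensities(np.zeros(123), geometry, FretCoupling(), cfg)


class TestThreeColor:
    def geometry3(self):
        return FilamentGeometry(filament_length=99, duplex_length=39,
                                acceptor_positions=(0.0, 33.0))

    def test_pinned_at_acceptor1(self):
        g = self.geometry3()
        cfg = SlideSimConfig(d_um2=0.0, n_frames=100, seed=9)
        center1 = alignment_center(cfg, g, 0)
        cfg.x_max = None
        # pin the walk at acceptor-1 alignment via a zero-width range there
        tr = simulate_three_color(
            SlideSimConfig(d_um2=0.0, n_frames=100, seed=9, x_max=0.0), g,
            noise=False)
        # x = 0 is the closest approach to acceptor 1 and far from acceptor 2
        fr = fret_efficiencies(tr)
        assert np.all(fr.efficiencies["efret1"] > 0.4)
        assert np.all(fr.efficiencies["efret2"] < 0.05)

    def test_static_midway_both_constant(self):
        g = self.geometry3()
        cfg = SlideSimConfig(d_um2=0.0, n_frames=50, seed=10)
        tr = simulate_three_color(cfg, g, noise=False)
        for name in ("acceptor1", "acceptor2"):
            assert np.ptp(tr.channels[name]) == 0.0

    def test_noiseless_three_channel_sum_conserved(self):
        g = self.geometry3()
        tr = simulate_three_color(SlideSimConfig(n_frames=500, seed=11), g,
                                  noise=False)
        assert np.allclose(tr.total_intensity(), 500.0)

    def test_diffusing_acceptors_anticorrelated(self):
        g = self.geometry3()
        tr = simulate_three_color(SlideSimConfig(n_frames=2000, seed=12), g)
        fr = fret_efficiencies(tr)
        r = pearson_correlation(fr.efficiencies["efret1"],
                                fr.efficiencies["efret2"])
        assert r < 0

    def test_coincident_acceptors_rejected(self):
        g = FilamentGeometry(filament_length=99, duplex_length=39,
                             acceptor_positions=(10.0, 10.0))
        with pytest.raises(ValueError):
            simulate_three_color(SlideSimConfig(n_frames=10), g)


class TestConfigValidation:
    def test_step_size_range(self):
        with pytest.raises(ValueError):
            SlideSimConfig(step_size=0.2)
        with pytest.raises(ValueError):
            SlideSimConfig(step_size=0.0)

    def test_allowed_range_derivation(self, geometry):
        cfg = SlideSimConfig(min_overlap=9.0)
        assert allowed_range(cfg, geometry) == 99 + 39 - 18
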