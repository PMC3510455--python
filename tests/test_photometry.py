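"""Channel corrections, gamma estimation and FRET efficiency computation."""

import numpy as np
import pytest

from slidefret import (CorrectionSet, FilamentGeometry, FretCoupling,
                       IntensityCorrector, IntensityTrace, SlideSimConfig,
                       apply_corrections, estimate_gamma, fret_efficiencies,
                       pearson_correlation, simulate_slide_trace)


def const_trace(**channels):
    return IntensityTrace({k: np.full(60, float(v)) for k, v in channels.items()})


class TestApplyCorrections:
    def test_identity(self):
        tr = const_trace(donor=550, acceptor1=250)
        out = apply_corrections(tr, CorrectionSet())
        for name in tr.channels:
            assert np.array_equal(out.channels[name], tr.channels[name])

    def test_background_subtraction(self):
        tr = const_trace(donor=550, acceptor1=250)
        out = apply_corrections(
            tr, CorrectionSet(background={"donor": 50, "acceptor1": 50}))
        assert out.channels["donor"][0] == 500
        assert out.channels["acceptor1"][0] == 200

    def test_leakage_after_background(self):
        tr = const_trace(donor=500, acceptor1=60)
        out = apply_corrections(tr, CorrectionSet(leakage_donor_to_a1=0.1))
        assert out.channels["acceptor1"][0] == pytest.approx(10.0)

    def test_gamma_scales_acceptor2(self):
        tr = const_trace(donor=100, acceptor1=100, acceptor2=50)
        out = apply_corrections(tr, CorrectionSet(gamma=1.4))
        assert out.channels["acceptor2"][0] == pytest.approx(70.0)

    def test_missing_channel_rejected(self):
        tr = const_trace(donor=100)
        with pytest.raises(KeyError):
            apply_corrections(tr, CorrectionSet(leakage_donor_to_a1=0.1))

    def test_zero_corrections_idempotent(self):
        tr = const_trace(donor=500, acceptor1=100)
        once = apply_corrections(tr, CorrectionSet())
        twice = apply_corrections(once, CorrectionSet())
        for name in tr.channels:
            assert np.array_equal(once.channels[name], twice.channels[name])


def bleach_trace(gamma_true=1.4, noise_sd=0.0, seed=0):
    """Acceptor-2 photobleaches at frame 100; acceptor-1 takes up the loss
    scaled by 1/gamma (detection mismatch)."""
    rng = np.random.default_rng(seed)
    n = 200
    a2 = np.where(np.arange(n) < 100, 60.0, 0.0)
    a1 = np.where(np.arange(n) < 100, 100.0, 100.0 + gamma_true * 60.0)
    donor = np.full(n, 340.0)
    if noise_sd:
        a1 = a1 + rng.normal(0, noise_sd, n)
        a2 = a2 + rng.normal(0, noise_sd, n)
        donor = donor + rng.normal(0, noise_sd, n)
    return IntensityTrace({"donor": donor, "acceptor1": a1, "acceptor2": a2})


class TestEstimateGamma:
    @pytest.mark.parametrize("gamma_true", [2.0, 1.0])
    def test_clean_step(self, gamma_true):
        assert estimate_gamma(bleach_trace(gamma_true)) == pytest.approx(
            gamma_true)

    def test_noisy_round_trip(self):
        g = estimate_gamma(bleach_trace(1.4, noise_sd=5.0, seed=1))
        assert g == pytest.approx(1.4, rel=0.10)

    def test_scale_invariance(self):
        tr = bleach_trace(1.4, noise_sd=2.0, seed=2)
        scaled = IntensityTrace({k: 3.0 * v for k, v in tr.channels.items()})
        assert estimate_gamma(scaled) == pytest.approx(estimate_gamma(tr),
                                                       rel=1e-6)

    def test_no_step_rejected(self):
        rng = np.random.default_rng(3)
        tr = IntensityTrace({
            "donor": np.full(200, 300.0),
            "acceptor1": rng.normal(100, 5, 200),
            "acceptor2": rng.normal(60, 5, 200),
        })
        with pytest.raises(ValueError):
            estimate_gamma(tr)


class TestFretEfficiencies:
    @pytest.mark.parametrize("channels, expected", [
        ({"donor": 0, "acceptor1": 500}, {"efret1": 1.0}),
        ({"donor": 100, "acceptor1": 100, "acceptor2": 100},
         {"efret1": 1 / 3, "efret2": 1 / 3}),
        ({"donor": 250, "acceptor1": 200, "acceptor2": 50},
         {"efret1": 0.4, "efret2": 0.1}),
    ])
    def test_values(self, channels, expected):
        fr = fret_efficiencies(const_trace(**channels))
        for name, val in expected.items():
            assert fr.efficiencies[name][0] == pytest.approx(val)

    def test_nonpositive_total_flagged(self):
        tr = IntensityTrace({"donor": np.array([100.0, 0.0]),
                             "acceptor1": np.array([100.0, 0.0])})
        fr = fret_efficiencies(tr)
        assert np.isnan(fr.efficiencies["efret1"][1])
        assert list(fr.metadata["invalid_frames"]) == [1]

    def test_round_trip_through_simulator(self):
        """Noiseless rendered intensities invert to the geometric efficiency."""
        g = FilamentGeometry(filament_length=99, duplex_length=39)
        cfg = SlideSimConfig(n_frames=300, seed=21)
        tr = simulate_slide_trace(cfg, g, FretCoupling(), noise=False)
        e = fret_efficiencies(tr).efficiencies["efret1"]
        assert np.allclose(e, tr.channels["acceptor1"] / 500.0, atol=1e-12)


class TestPearson:
    def test_perfect_correlation(self):
        e = np.linspace(0, 1, 50)
        assert pearson_correlation(e, e) == pytest.approx(1.0)
        assert pearson_correlation(e, 1 - e) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.linspace(0, 1, 10))


class TestIntensityCorrector:
    def test_sklearn_params_round_trip(self):
        c = IntensityCorrector(leakage_donor_to_a1=0.12, gamma=1.4)
        params = c.get_params()
        assert params["leakage_donor_to_a1"] == 0.12
        c2 = IntensityCorrector(**params)
        assert c2.get_params() == params

    def test_auto_gamma_fit_transform(self):
        traces = [bleach_trace(1.4, noise_sd=2.0, seed=4)]
        corr = IntensityCorrector(gamma="auto").fit(traces)
        assert corr.gamma_ == pytest.approx(1.4, rel=0.10)
        out = corr.transform(traces)
        assert np.allclose(out[0].channels["acceptor2"],
                           corr.gamma_ * traces[0].channels["acceptor2"])

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            IntensityCorrector().transform([const_trace(donor=1, acceptor1=1)])
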