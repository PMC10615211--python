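"""Log-normal mixture fitting, derived metrics, and model-order choice."""

import math

import numpy as np
import pytest

from granulekit import (
    LogNormalComponent,
    MixtureFit,
    SyntheticSpec,
    ValidationError,
    choose_model,
    derive_granule_metrics,
    fit_mixture,
    simulate_granules,
    to_distribution,
)
from conftest import volume_dist_from_components


class TestFitMixture:
    def test_noise_free_bimodal_recovery_within_1_percent(self, wt_volume_dist):
        fit = fit_mixture(wt_volume_dist, n_components=2, seed=0)
        b, a = fit.components
        assert b.mu == pytest.approx(math.log(5.0), rel=0.01)
        assert b.sigma == pytest.approx(0.25, rel=0.01)
        assert b.weight == pytest.approx(0.30, rel=0.01)
        assert a.mu == pytest.approx(math.log(20.0), rel=0.01)
        assert a.sigma == pytest.approx(0.20, rel=0.01)

    def test_single_lognormal_identity_recovery(self):
        dist = volume_dist_from_components([(math.log(10.0), 0.4, 1.0)])
        fit = fit_mixture(dist, n_components=1, seed=0)
        (comp,) = fit.components
        assert comp.weight == 1.0
        assert comp.mu == pytest.approx(math.log(10.0), rel=0.01)
        assert comp.sigma == pytest.approx(0.4, rel=0.01)

    def test_simulated_particles_recovery(self):
        # 1e5 particles from the same truth, binned, fitted
        spec = SyntheticSpec(
            seed=11,
            components=((5.0, 0.25, 0.30), (20.0, 0.20, 0.70)),
            n_particles=100_000,
        )
        data, truth = simulate_granules(spec)
        fit = fit_mixture(to_distribution(data, "volume"), 2, seed=11)
        b, a = fit.components
        assert b.mu == pytest.approx(math.log(5.0), rel=0.05)
        assert b.sigma == pytest.approx(0.25, rel=0.05)
        assert a.mu == pytest.approx(math.log(20.0), rel=0.05)
        assert a.sigma == pytest.approx(0.20, rel=0.05)
        assert abs(b.weight - 0.30) < 0.05

    def test_deterministic_given_seed(self, wt_volume_dist):
        f1 = fit_mixture(wt_volume_dist, 2, seed=3)
        f2 = fit_mixture(wt_volume_dist, 2, seed=3)
        assert f1.to_dict() == f2.to_dict()

    def test_b_label_always_smaller_median(self):
        # weight layouts that tempt the optimiser to swap component order
        for comps in (
            [(math.log(5.0), 0.25, 0.70), (math.log(20.0), 0.20, 0.30)],
            [(math.log(5.0), 0.25, 0.10), (math.log(20.0), 0.20, 0.90)],
        ):
            fit = fit_mixture(volume_dist_from_components(comps), 2, seed=0)
            assert fit.component_B.median < fit.component_A.median

    def test_number_weighted_distribution_rejected(self):
        data, _ = simulate_granules(SyntheticSpec.from_preset("WT", seed=0))
        dist = to_distribution(data, "number")
        with pytest.raises(ValidationError, match="volume-weighted"):
            fit_mixture(dist, 2)

    def test_too_few_nonzero_bins_rejected(self):
        # very narrow peak on a coarse grid: fewer than 8 occupied bins
        dist = volume_dist_from_components(
            [(math.log(10.0), 0.03, 1.0)], n_bins=12
        )
        assert np.count_nonzero(dist.relative_share > 0) < 8
        with pytest.raises(ValidationError, match="8 bins"):
            fit_mixture(dist, 2)

    def test_invalid_component_count_rejected(self, wt_volume_dist):
        with pytest.raises(ValidationError, match="n_components"):
            fit_mixture(wt_volume_dist, 3)

    def test_sigma_to_zero_limit_recovers_generating_diameters(self):
        dist = volume_dist_from_components(
            [(math.log(5.0), 0.02, 0.30), (math.log(20.0), 0.02, 0.70)],
            n_bins=400,
        )
        fit = fit_mixture(dist, 2, seed=0)
        assert fit.component_B.mean_diameter == pytest.approx(5.0, rel=0.01)
        assert fit.component_A.mean_diameter == pytest.approx(20.0, rel=0.01)

    def test_fitted_b_volume_tracks_generator_weight_monotonically(self):
        fitted = []
        for i, w in enumerate((0.05, 0.15, 0.25, 0.35, 0.45)):
            spec = SyntheticSpec(
                seed=100 + i,
                components=((5.0, 0.30, w), (21.0, 0.22, 1.0 - w)),
                n_particles=100_000,
            )
            data, _ = simulate_granules(spec)
            fit = fit_mixture(to_distribution(data, "volume"), 2, seed=i)
            fitted.append(derive_granule_metrics(fit).b_volume_percent)
        assert fitted == sorted(fitted)


class TestDeriveGranuleMetrics:
    def test_two_component_metrics(self):
        fit = MixtureFit(
            components=(
                LogNormalComponent(mu=math.log(5.0), sigma=1e-9, weight=0.3),
                LogNormalComponent(mu=math.log(20.0), sigma=1e-9, weight=0.7),
            ),
            sse=0.0, converged=True, n_starts_used=1,
            fitted_curve=np.zeros(1), seed=0,
        )
        m = derive_granule_metrics(fit)
        assert m.b_volume_percent == pytest.approx(30.0)
        assert m.mean_diameter_B == pytest.approx(5.0)
        assert m.mean_diameter_A == pytest.approx(20.0)

    def test_unimodal_closed_form_mean(self):
        fit = MixtureFit(
            components=(
                LogNormalComponent(mu=math.log(10.0), sigma=0.5, weight=1.0),
            ),
            sse=0.0, converged=True, n_starts_used=1,
            fitted_curve=np.zeros(1), seed=0,
        )
        m = derive_granule_metrics(fit)
        assert m.b_volume_percent == 0.0
        assert m.mean_diameter_B is None
        assert m.mean_diameter_A == pytest.approx(10.0 * math.exp(0.125))

    def test_recovery_metrics_match_generator(self, wt_volume_dist):
        fit = fit_mixture(wt_volume_dist, 2, seed=0)
        m = derive_granule_metrics(fit)
        assert m.b_volume_percent == pytest.approx(30.0, rel=0.01)
        assert m.mean_diameter_B == pytest.approx(
            5.0 * math.exp(0.25**2 / 2), rel=0.01
        )
        assert m.mean_diameter_A == pytest.approx(
            20.0 * math.exp(0.20**2 / 2), rel=0.01
        )

    def test_unconverged_fit_rejected(self, wt_volume_dist):
        fit = fit_mixture(wt_volume_dist, 2, seed=0)
        bad = MixtureFit(
            components=fit.components, sse=fit.sse, converged=False,
            n_starts_used=1, fitted_curve=fit.fitted_curve, seed=0,
        )
        from granulekit import FitError

        with pytest.raises(FitError):
            derive_granule_metrics(bad)


class TestChooseModel:
    def test_force_unimodal(self, wt_volume_dist):
        assert choose_model(wt_volume_dist, force_unimodal=True) == 1

    def test_clearly_bimodal_synthetic_data(self):
        data, _ = simulate_granules(SyntheticSpec.from_preset("WT", seed=4))
        assert choose_model(to_distribution(data, "volume"), seed=4) == 2

    def test_single_component_data_demoted(self):
        data, _ = simulate_granules(
            SyntheticSpec.from_preset("bgc1_like", seed=4)
        )
        assert choose_model(to_distribution(data, "volume"), seed=4) == 1

    def test_weight_invariants_of_fit(self, wt_volume_dist):
        fit = fit_mixture(wt_volume_dist, 2, seed=1)
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0, abs=1e-9)
        assert fit.sse >= 0
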