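import math

import numpy as np
import pytest

from skiptics.dose import (
    DoseObservation,
    estimate_diffusion_fraction,
    fit_curve_from_points,
    fit_dose_model,
    fit_response_curve,
    read_dose_tsv,
    skipping_threshold,
    total_nuclear_tdp43,
    write_dose_tsv,
)
from skiptics.errors import DataError
from skiptics.simulate import DoseSimSpec, SimConfig, noiseless, simulate_dose


class TestTotalNuclear:
    def test_nlsm_diffusion_arithmetic(self):
        assert total_nuclear_tdp43(1.0, 2.0, "NLSm", 0.45) == pytest.approx(1.9)

    @pytest.mark.parametrize("construct", ["WT", "NLSm"])
    def test_zero_construct_is_identity(self, construct):
        assert total_nuclear_tdp43(1.0, 0.0, construct) == 1.0

    def test_autoregulated_endogenous(self):
        assert total_nuclear_tdp43(0.5, 1.5, "WT") == pytest.approx(2.0)

    def test_wt_equals_nlsm_at_full_diffusion(self):
        assert total_nuclear_tdp43(0.8, 1.7, "WT") == total_nuclear_tdp43(
            0.8, 1.7, "NLSm", diffusion_fraction=1.0
        )

    def test_linearity_in_construct_level(self):
        base = total_nuclear_tdp43(1.0, 1.0, "NLSm", 0.45)
        assert total_nuclear_tdp43(1.0, 3.0, "NLSm", 0.45) - 1.0 == pytest.approx(
            3 * (base - 1.0)
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"endogenous_level": -0.1, "construct_level": 1.0},
            {"endogenous_level": 1.0, "construct_level": -1.0},
        ],
    )
    def test_negative_levels_rejected(self, kwargs):
        with pytest.raises(ValueError):
            total_nuclear_tdp43(construct="WT", **kwargs)


class TestResponseCurve:
    def test_linear_interpolation_between_knots(self):
        curve = fit_curve_from_points([1.0, 1.5, 2.0], [0.0, 40.0, 90.0])
        assert curve(1.75) == pytest.approx(65.0)

    def test_pool_adjacent_violators_merges_pair(self):
        curve = fit_curve_from_points(
            [1.0, 1.2, 1.3, 2.0], [0.0, 10.0, 5.0, 50.0]
        )
        assert curve(1.2) == pytest.approx(7.5)
        assert curve(1.3) == pytest.approx(7.5)
        assert curve(1.25) == pytest.approx(7.5)

    def test_single_distinct_fold_errors(self):
        with pytest.raises(DataError):
            fit_curve_from_points([1.5, 1.5], [0.0, 10.0])

    def test_clamped_beyond_range(self):
        curve = fit_curve_from_points([1.0, 2.0], [10.0, 90.0])
        assert curve(0.5) == 10.0 and curve(5.0) == 90.0

    def test_fitted_curve_is_monotone_on_grid(self, rng):
        folds = rng.uniform(1.0, 4.0, size=30)
        values = rng.uniform(0.0, 100.0, size=30)
        curve = fit_curve_from_points(folds, values)
        grid = curve(np.linspace(0.5, 5.0, 200))
        assert np.all(np.diff(grid) >= -1e-9)

    def test_fit_from_observations_uses_construct_rule(self):
        obs = [
            DoseObservation("WT", 0.0, 1.0, 0.0),
            DoseObservation("WT", 1.0, 1.0, 90.0),
        ]
        curve = fit_response_curve(obs)
        assert curve(1.5) == pytest.approx(45.0)


class TestDiffusionEstimate:
    def test_noiseless_recovery_is_exact(self):
        sim = simulate_dose(noiseless(SimConfig(seed=42)))
        est = estimate_diffusion_fraction(sim.wt, sim.nlsm)
        assert est.median == pytest.approx(0.45, abs=1e-6)
        assert est.high - est.low < 1e-6

    def test_monte_carlo_recovery_under_noise(self):
        """With 5% multiplicative response noise, the per-replicate median
        estimate stays in [0.40, 0.50] for >= 95% of 200 seeded replicates."""
        in_band = 0
        medians = []
        for rep in range(200):
            sim = simulate_dose(SimConfig(seed=100_000 + rep))
            est = estimate_diffusion_fraction(sim.wt, sim.nlsm)
            medians.append(est.median)
            in_band += 0.40 <= est.median <= 0.50
        assert in_band / 200 >= 0.95
        assert abs(float(np.median(medians)) - 0.45) <= 0.05

    def test_no_overlapping_response_range_errors(self):
        wt = [
            DoseObservation("WT", 0.1, 1.0, 20.0),
            DoseObservation("WT", 0.5, 1.0, 40.0),
        ]
        nlsm = [DoseObservation("NLSm", 2.0, 1.0, 95.0)]  # above the WT maximum
        with pytest.raises(DataError):
            estimate_diffusion_fraction(wt, nlsm)


class TestSkippingThreshold:
    @pytest.fixture
    def curve(self):
        return fit_curve_from_points([1.0, 1.5, 2.0], [0.0, 40.0, 90.0])

    def test_floor_at_knot(self, curve):
        assert skipping_threshold(curve, 40.0) == pytest.approx(1.5)

    def test_linear_inversion(self, curve):
        assert skipping_threshold(curve, 8.0) == pytest.approx(1.1)

    def test_flat_zero_curve_not_attained(self):
        curve = fit_curve_from_points([1.0, 2.0], [0.0, 0.0])
        assert math.isinf(skipping_threshold(curve, 5.0))

    def test_floor_zero_attained_at_one(self, curve):
        assert skipping_threshold(curve, 0.0) == 1.0

    @pytest.mark.parametrize("floor", [-1.0, 101.0])
    def test_floor_out_of_range_rejected(self, curve, floor):
        with pytest.raises(ValueError):
            skipping_threshold(curve, floor)

    def test_nondecreasing_in_floor(self, curve):
        floors = np.linspace(1, 89, 30)
        thresholds = [skipping_threshold(curve, f) for f in floors]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))

    def test_nonincreasing_in_steepness(self):
        shallow = fit_curve_from_points([1.0, 3.0], [0.0, 60.0])
        steep = fit_curve_from_points([1.0, 1.5], [0.0, 60.0])
        for floor in (5.0, 20.0, 50.0):
            assert skipping_threshold(steep, floor) <= skipping_threshold(
                shallow, floor
            )


class TestDoseModelFit:
    def test_full_fit_summary(self):
        sim = simulate_dose(noiseless(SimConfig(seed=9)))
        fit = fit_dose_model(list(sim.observations), detection_floor=8.0)
        assert fit.diffusion_fraction == pytest.approx(0.45, abs=1e-6)
        # fitted WT curve: value 5 at fold 1.1, 18.125 at 1.25; invert at 8
        assert fit.threshold_fold == pytest.approx(1.1 + 0.15 * 3 / 13.125)
        summary = fit.summary()
        assert summary["threshold_attained"] is True
        assert summary["n_wt"] == 7 and summary["n_nlsm"] == 6

    def test_requires_two_wt_points(self):
        with pytest.raises(DataError):
            fit_dose_model([DoseObservation("WT", 1.0, 1.0, 50.0)])

    def test_tsv_round_trip(self, tmp_path):
        sim = simulate_dose(SimConfig(seed=3))
        path = tmp_path / "dose.tsv"
        write_dose_tsv(sim.observations, path)
        back = read_dose_tsv(path)
        assert len(back) == len(sim.observations)
        for a, b in zip(back, sim.observations):
            assert a.construct == b.construct
            assert a.construct_level == b.construct_level
            assert a.skipping_percent == pytest.approx(b.skipping_percent)


def test_observation_validation():
    with pytest.raises(ValueError):
        DoseObservation("XX", 1.0, 1.0, 10.0)
    with pytest.raises(ValueError):
        DoseObservation("WT", 1.0, 1.0, 120.0)
    with pytest.raises(ValueError):
        DoseObservation("WT", -1.0, 1.0, 10.0)


def test_dose_spec_rejects_nonmonotone_knots():
    with pytest.raises(ValueError):
        DoseSimSpec(curve_knots=((1.0, 10.0), (2.0, 5.0)))
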