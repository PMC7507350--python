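"""Permeability estimation: recovery, invariances, ROI handling."""

import numpy as np
import pytest

from microperm.geometry import measure_geometry
from microperm.grid import VoxelGrid
from microperm.permeability import (
    PermeabilityResult,
    TracerEquilibratedError,
    aggregate_rois,
    estimate_permeability,
    sample_rois,
)
from microperm.synth import TracerStackPair, make_vessel_phantom, simulate_tracer_stacks
from microperm.synth.tracer import ground_truth_for_kdt


@pytest.fixture(scope="module")
def phantom(aniso_grid):
    _, labels, _ = make_vessel_phantom(
        seed=5, grid=aniso_grid, n_branches=4, radius_range_um=(4.0, 8.0), oracle=False
    )
    return labels


def bias_factor(k_dt: float) -> float:
    """Two-timepoint finite-difference bias of the exponential fill-in."""
    return -np.expm1(-k_dt) / k_dt


class TestRecovery:
    @pytest.mark.parametrize("k_dt", [1e-3, 1e-2, 1e-1])
    def test_noiseless_recovery_within_bias_factor(self, phantom, k_dt):
        truth = ground_truth_for_kdt(phantom, k_dt=k_dt, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        res = estimate_permeability(pair, phantom)
        assert res.P_um_per_s == pytest.approx(
            truth.P_true_um_s * bias_factor(k_dt), rel=1e-6
        )

    def test_bias_factor_small_at_small_kdt(self):
        # ≈ −0.05% at k·Δt = 1e-3; ≈ −0.5% at 1e-2
        assert bias_factor(1e-3) == pytest.approx(1.0, abs=5.1e-4)
        assert bias_factor(1e-2) == pytest.approx(0.995, abs=2e-4)

    def test_identical_stacks_give_zero(self, phantom):
        truth = ground_truth_for_kdt(phantom, k_dt=0.1, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        frozen = TracerStackPair(
            stack_t1=pair.stack_t1, stack_t2=pair.stack_t1.copy(),
            grid=pair.grid, t1_s=0.0, t2_s=900.0,
        )
        res = estimate_permeability(frozen, phantom)
        assert res.P_um_per_s == 0.0

    def test_equilibrated_matrix_raises(self, phantom):
        uniform = np.full(phantom.grid.shape, 1000.0)
        pair = TracerStackPair(
            stack_t1=uniform, stack_t2=uniform, grid=phantom.grid, t1_s=0.0, t2_s=900.0
        )
        with pytest.raises(TracerEquilibratedError, match="equilibrated"):
            estimate_permeability(pair, phantom)

    def test_negative_dIm_flagged_not_clamped(self, phantom):
        truth = ground_truth_for_kdt(phantom, k_dt=0.1, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        bleached = TracerStackPair(
            stack_t1=pair.stack_t2, stack_t2=pair.stack_t1,  # reversed: matrix dims
            grid=pair.grid, t1_s=0.0, t2_s=900.0,
        )
        res = estimate_permeability(bleached, phantom)
        assert res.P_um_per_s < 0
        assert any("negative_dIm" in w for w in res.warnings)


class TestInvariances:
    def test_intensity_scale_invariance(self, phantom):
        truth = ground_truth_for_kdt(phantom, k_dt=0.05, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        base = estimate_permeability(pair, phantom).P_um_per_s
        for c in (0.1, 3.7, 1000.0):
            scaled = TracerStackPair(
                stack_t1=c * pair.stack_t1, stack_t2=c * pair.stack_t2,
                grid=pair.grid, t1_s=0.0, t2_s=900.0,
            )
            assert estimate_permeability(scaled, phantom).P_um_per_s == pytest.approx(
                base, rel=1e-12
            )

    def test_constant_offset_biases_P_down(self, phantom):
        # background raises ΔI but not ΔIm, so P shrinks — the reason the
        # estimator offers explicit background subtraction
        truth = ground_truth_for_kdt(phantom, k_dt=0.05, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        base = estimate_permeability(pair, phantom).P_um_per_s
        offset = TracerStackPair(
            stack_t1=pair.stack_t1 + 200.0, stack_t2=pair.stack_t2 + 200.0,
            grid=pair.grid, t1_s=0.0, t2_s=900.0,
        )
        biased = estimate_permeability(offset, phantom).P_um_per_s
        assert biased < base
        corrected = estimate_permeability(offset, phantom, background=200.0).P_um_per_s
        assert corrected == pytest.approx(base, rel=1e-12)

    def test_monotone_in_dIm(self, phantom):
        truth = ground_truth_for_kdt(phantom, k_dt=0.05, dt_s=900.0)
        pair = simulate_tracer_stacks(phantom, truth, dt_s=900.0)
        matrix = ~phantom.labels
        Ps = []
        for bump in (0.0, 5.0, 10.0):
            s2 = pair.stack_t2.copy()
            s2[matrix] += bump
            p = TracerStackPair(
                stack_t1=pair.stack_t1, stack_t2=s2, grid=pair.grid, t1_s=0.0, t2_s=900.0
            )
            Ps.append(estimate_permeability(p, phantom).P_um_per_s)
        assert Ps[0] < Ps[1] < Ps[2]

    def test_result_invariant_checked(self, phantom):
        geom = measure_geometry(phantom)
        with pytest.raises(ValueError, match="inconsistent"):
            PermeabilityResult(
                P_um_per_s=123.0, Iv1=1000.0, Im1=0.0, Im2=10.0, dt_s=900.0,
                geometry=geom,
            )


class TestRoiSampling:
    def test_deterministic_per_seed(self, aniso_grid):
        a = sample_rois(aniso_grid, (20.0, 30.0, 30.0), n_rois=3, seed=11)
        b = sample_rois(aniso_grid, (20.0, 30.0, 30.0), n_rois=3, seed=11)
        assert a.boxes == b.boxes

    def test_three_rois_within_bounds(self, aniso_grid):
        plan = sample_rois(aniso_grid, (20.0, 30.0, 30.0), n_rois=3, seed=0)
        assert len(plan.boxes) == 3
        for box in plan.boxes:
            aniso_grid.check_box(box)

    def test_full_size_roi_forces_single_placement(self, aniso_grid):
        size = aniso_grid.extent_um
        plan = sample_rois(aniso_grid, size, n_rois=3, seed=4)
        assert len(set(plan.boxes)) == 1
        assert plan.boxes[0] == aniso_grid.full_box()

    def test_oversized_roi_rejected(self, aniso_grid):
        with pytest.raises(ValueError, match="exceeds"):
            sample_rois(aniso_grid, (1000.0, 10.0, 10.0), n_rois=1, seed=0)


class TestAggregation:
    def _result(self, phantom, P):
        geom = measure_geometry(phantom)
        dI = 1000.0
        dIm = P * geom.SA_um2 * dI * 900.0 / geom.Vm_um3
        return PermeabilityResult(
            P_um_per_s=P, Iv1=1000.0, Im1=0.0, Im2=dIm, dt_s=900.0, geometry=geom
        )

    def test_hand_arithmetic(self, phantom):
        results = [self._result(phantom, v) for v in (1.0, 2.0, 3.0)]
        agg = aggregate_rois(results)
        assert agg.mean_P_um_per_s == pytest.approx(2.0)
        assert agg.sd_P_um_per_s == pytest.approx(1.0)

    def test_identical_rois_have_zero_sd(self, phantom):
        agg = aggregate_rois([self._result(phantom, 2.5)] * 3)
        assert agg.mean_P_um_per_s == 2.5
        assert agg.sd_P_um_per_s == 0.0

    def test_single_roi_sd_absent(self, phantom):
        agg = aggregate_rois([self._result(phantom, 2.5)])
        assert agg.sd_P_um_per_s is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rois([])
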