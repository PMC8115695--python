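"""Optical-flow velocities, axis decomposition, phase segmentation, coupling."""
import numpy as np
import pytest

from branchmech.stack import TimeLapseStack
from branchmech.synthetic import (
    _render_spots,
    render_nuclei_motion,
    render_nuclei_stack,
)
from branchmech.ecm_deformation import BranchGeometry
from branchmech.cell_dynamics import (
    VelocityField,
    compute_flow,
    decompose,
    order_parameter,
    segment_phases,
    couple_cell_ecm,
)


def blob_movie(offsets_per_frame, shape=(96, 96), n=30, seed=0, psf=3.0):
    """Frames with the same blobs translated by the given per-frame offsets."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(20, min(shape) - 20, size=(n, 2))
    frames = []
    for dy, dx in offsets_per_frame:
        frames.append(_render_spots((1,) + shape,
                                    [(0, y + dy, x + dx) for y, x in pos],
                                    100.0, psf))
    return TimeLapseStack(np.stack(frames), voxel_size=(1.0, 1.0, 1.0),
                          frame_interval=10.0)


class TestComputeFlow:
    def test_static_movie_zero_field(self):
        stack = blob_movie([(0, 0), (0, 0), (0, 0)])
        flow = compute_flow(stack)
        assert np.abs(flow.speed).max() < 1e-3

    def test_uniform_translation_speed_within_10pct(self):
        # 3 um per 10-min frame -> 0.3 um/min
        stack = blob_movie([(0, 0), (0, 3.0)])
        flow = compute_flow(stack)
        w = stack.intensities[0, 0] > 10
        assert np.median(flow.speed[0][w]) == pytest.approx(0.3, rel=0.10)

    def test_flow_antisymmetry(self):
        stack_fwd = blob_movie([(0, 0), (2.0, -1.0)])
        stack_rev = blob_movie([(2.0, -1.0), (0, 0)])
        fwd = compute_flow(stack_fwd)
        rev = compute_flow(stack_rev)
        w = stack_fwd.intensities[0, 0] > 10
        err = np.hypot(fwd.vy[0] + rev.vy[0], fwd.vx[0] + rev.vx[0])
        scale = np.median(fwd.speed[0][w])
        assert np.median(err[w]) < 0.15 * scale

    def test_blank_frames_warn_and_zero(self):
        frames = np.zeros((2, 1, 32, 32))
        stack = TimeLapseStack(frames)
        with pytest.warns(UserWarning, match="blank"):
            flow = compute_flow(stack)
        assert np.all(flow.speed == 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_flow(TimeLapseStack(np.zeros((1, 1, 16, 16))))


class TestDecompose:
    def _field(self, vx, vy):
        return VelocityField(vy=np.full((1, 8, 8), float(vy)),
                             vx=np.full((1, 8, 8), float(vx)),
                             frame_interval=10.0)

    def test_axis_parallel_motion(self):
        geom = BranchGeometry(tip=(0, 0, 0), axis=(1, 0, 0))
        v_par, v_orth = decompose(self._field(1.0, 0.0), geom)
        np.testing.assert_allclose(v_par, 1.0)
        np.testing.assert_allclose(v_orth, 0.0)

    def test_orthogonal_motion(self):
        geom = BranchGeometry(tip=(0, 0, 0), axis=(1, 0, 0))
        # vy > 0 points down the rows = -y in math coordinates
        v_par, v_orth = decompose(self._field(0.0, 1.0), geom)
        np.testing.assert_allclose(v_par, 0.0)
        np.testing.assert_allclose(v_orth, -1.0)

    def test_exact_reconstruction(self):
        rng = np.random.default_rng(3)
        field = VelocityField(vy=rng.normal(size=(2, 6, 6)),
                              vx=rng.normal(size=(2, 6, 6)), frame_interval=10.0)
        ax = np.array([0.6, 0.8])
        geom = BranchGeometry(tip=(0, 0, 0), axis=(0.6, 0.8, 0.0))
        v_par, v_orth = decompose(field, geom)
        # reconstruct the (x, -y_row) in-plane vector
        vx_rec = v_par * ax[0] + v_orth * (-ax[1])
        vy_math_rec = v_par * ax[1] + v_orth * ax[0]
        np.testing.assert_allclose(vx_rec, field.vx, atol=1e-12)
        np.testing.assert_allclose(vy_math_rec, -field.vy, atol=1e-12)

    def test_axis_without_inplane_component_rejected(self):
        geom = BranchGeometry(tip=(0, 0, 0), axis=(0, 0, 1.0))
        with pytest.raises(ValueError):
            decompose(self._field(1.0, 0.0), geom)

    def test_mask_restricts_output(self):
        geom = BranchGeometry(tip=(0, 0, 0), axis=(1, 0, 0))
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        v_par, _ = decompose(self._field(1.0, 0.0), geom, mask=mask)
        assert np.isfinite(v_par[0][mask]).all()
        assert np.isnan(v_par[0][~mask]).all()


class TestPhases:
    def test_unanimous_outward(self):
        phi, mean_v = order_parameter(np.full(100, 0.8))
        assert phi == 1.0 and mean_v > 0

    def test_balanced_directions_low_phi(self):
        rng = np.random.default_rng(4)
        v = rng.choice([-1.0, 1.0], size=5000)
        phi, _ = order_parameter(v)
        assert phi < 0.05  # binomial null: sd = 1/sqrt(n) ~ 0.014

    def test_schedule_recovered_from_ground_truth_velocities(self):
        motion = render_nuclei_motion(
            [((0, 5), 1.0, 1), ((5, 10), 0.6, 0), ((10, 15), 1.0, -1)],
            jitter=0.0, seed=5, n_cells=60)
        v_par = [motion.velocities[t, :, 0] for t in range(14)]
        phases, _ = segment_phases(v_par, phi_threshold=0.5)
        labels = [p.label for p in phases]
        assert labels == ["collective_outward", "uncoordinated", "collective_inward"]
        switches = [p.start for p in phases[1:]]
        assert all(abs(s - e) <= 1 for s, e in zip(switches, [5, 10]))

    def test_segmentation_from_rendered_movie_flow(self):
        motion = render_nuclei_motion(
            [((0, 4), 0.8, 1), ((4, 8), 0.8, -1)], jitter=0.0, seed=6,
            n_cells=40, region=(40.0, 150.0, 20.0, 70.0))
        stack = render_nuclei_stack(motion, shape=(96, 200), seed=7,
                                    nucleus_sigma=3.0)
        flow = compute_flow(stack)
        geom = BranchGeometry(tip=(200, 45, 0), axis=(1, 0, 0))
        mask = stack.intensities.max(axis=(0, 1)) > 10
        v_par, _ = decompose(flow, geom, mask=mask)
        phases, _ = segment_phases(list(v_par), phi_threshold=0.5,
                                   min_speed=0.1)
        labels = [p.label for p in phases]
        assert labels == ["collective_outward", "collective_inward"]
        assert abs(phases[1].start - 4) <= 1


class TestCoupling:
    def test_exact_anticorrelated_series(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 40)
        s = -2.5 * v
        res = couple_cell_ecm(v, s, max_lag=3)
        assert res.peak_lag == 0
        assert res.peak_correlation == pytest.approx(1.0)

    def test_constructed_delay_recovered(self):
        rng = np.random.default_rng(9)
        v = rng.normal(0, 1, 60)
        s = np.zeros(60)
        s[1:] = -1.7 * v[:-1]  # cells lead the matrix by one frame
        res = couple_cell_ecm(v, s, max_lag=4)
        assert res.peak_lag == 1
        assert res.peak_correlation > 0.95

    def test_independent_noise_consistent_with_null(self):
        rng = np.random.default_rng(10)
        n = 60
        v = rng.normal(0, 1, n)
        s = rng.normal(0, 1, n)
        res = couple_cell_ecm(v, s, max_lag=0)
        null = []
        for _ in range(500):
            null.append(abs(np.corrcoef(rng.permutation(v), s)[0, 1]))
        assert abs(res.peak_correlation) < np.quantile(null, 0.99)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            couple_cell_ecm(np.ones(10), np.arange(10.0), max_lag=2)

    def test_unit_chain_hand_computed(self):
        # 2 um voxels, 10 min frames: a 1.5-voxel displacement per frame is
        # 3 um / 10 min = 0.3 um/min
        fy = np.zeros((1, 4, 4))
        fx = np.full((1, 4, 4), 1.5)
        field = VelocityField(vy=fy * 2.0 / 10.0, vx=fx * 2.0 / 10.0,
                              frame_interval=10.0)
        np.testing.assert_allclose(field.speed, 0.3)
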