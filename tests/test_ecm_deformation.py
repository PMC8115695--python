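"""Branch-frame projection and deformation statistics vs closed forms."""
import numpy as np
import pandas as pd
import pytest

from branchmech.synthetic import FieldParams, temporal_profile
from branchmech.ecm_deformation import (
    BranchGeometry,
    project_samples,
    cumulative_displacement,
    stripe_profile,
    angular_profile,
    frame_mean_series,
    label_phases_ecm,
    relaxation_delta,
)
from conftest import advect_tracks, tracks_to_displacement_table, front_hemisphere_beads


def step_table(rows):
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um",
                                       "dx_um", "dy_um", "dz_um"])


class TestProjectSamples:
    def test_on_axis_step_toward_tip(self, origin_geometry):
        df = step_table([(0, 0, 100.0, 0.0, 0.0, -2.0, 0.0, 0.0)])
        s = project_samples(df, origin_geometry)
        assert s.loc[0, "theta_deg"] == pytest.approx(0.0)
        assert s.loc[0, "r_um"] == pytest.approx(100.0)
        assert s.loc[0, "s_um"] == pytest.approx(2.0)  # toward tip = positive

    def test_perpendicular_step_zero_signed_component(self, origin_geometry):
        df = step_table([(0, 0, 100.0, 0.0, 0.0, 0.0, 1.5, 0.0)])
        s = project_samples(df, origin_geometry)
        assert s.loc[0, "s_um"] == pytest.approx(0.0)

    def test_step_away_from_tip_negative(self, origin_geometry):
        df = step_table([(0, 0, 0.0, 50.0, 0.0, 0.0, 3.0, 0.0)])
        s = project_samples(df, origin_geometry)
        assert s.loc[0, "theta_deg"] == pytest.approx(90.0)
        assert s.loc[0, "s_um"] == pytest.approx(-3.0)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_angular_profile_strictly_decreasing(self, k, origin_geometry):
        params = FieldParams(amplitude=2.0, anisotropy_exponent=k,
                             plastic_fraction=0.5, period=60.0)
        rng = np.random.default_rng(10 + k)
        pos0 = front_hemisphere_beads(rng, 2500)
        tracks = advect_tracks(params, pos0, n_frames=7)
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        prof = angular_profile(samples)
        means = prof["s_mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_angular_profile_flat_for_isotropic_field(self, origin_geometry):
        params = FieldParams(amplitude=2.0, anisotropy_exponent=0,
                             plastic_fraction=0.5, period=60.0)
        rng = np.random.default_rng(20)
        pos0 = front_hemisphere_beads(rng, 2500)
        tracks = advect_tracks(params, pos0, n_frames=7)
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        prof = angular_profile(samples)
        means = prof["s_mean"].to_numpy()
        # all bins equal within a CI band around the pooled mean
        sem = prof["s_std"].to_numpy() / np.sqrt(prof["n"].to_numpy())
        assert np.all(np.abs(means - means.mean()) < 4 * sem)


class TestCumulativeDisplacement:
    def test_constant_step_sums_exactly(self, origin_geometry):
        delta, n_steps, n_beads = 0.25, 6, 4
        rows = []
        for b in range(n_beads):
            for t in range(n_steps):
                rows.append((b, t, 100.0 + 10 * b, 0.0, 0.0, -delta, 0.0, 0.0))
        samples = project_samples(step_table(rows), origin_geometry)
        series = cumulative_displacement(samples, origin_geometry)
        assert series["cumulative_um"].iloc[0] == 0.0
        assert series["cumulative_um"].iloc[-1] == pytest.approx(n_steps * delta)

    def test_zero_field_constant_zero(self, origin_geometry):
        rows = [(0, t, 150.0, 0.0, 0.0, 0.0, 0.0, 0.0) for t in range(5)]
        samples = project_samples(step_table(rows), origin_geometry)
        series = cumulative_displacement(samples, origin_geometry)
        assert np.allclose(series["cumulative_um"], 0.0)

    def test_empty_near_field_raises(self, origin_geometry):
        rows = [(0, 0, 900.0, 0.0, 0.0, -1.0, 0.0, 0.0)]
        samples = project_samples(step_table(rows), origin_geometry)
        with pytest.raises(ValueError, match="near field"):
            cumulative_displacement(samples, origin_geometry)

    def test_plastic_ramp_matches_closed_form(self, origin_geometry):
        # rho=0.5, 3 periods: value at each period start m*P equals
        # m * rho * mean(A cos^k exp(-r/lam)) over the beads
        params = FieldParams(amplitude=2.0, decay_length=150.0,
                             anisotropy_exponent=2.0, period=60.0,
                             plastic_fraction=0.5)
        rng = np.random.default_rng(3)
        pos0 = front_hemisphere_beads(rng, 400)
        tracks = advect_tracks(params, pos0, n_frames=19)  # 3 periods, 10 min
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        series = cumulative_displacement(samples, origin_geometry)
        r = np.linalg.norm(pos0, axis=1)
        cos_t = pos0[:, 0] / r
        per_period = params.plastic_fraction * np.mean(
            params.amplitude * cos_t**2 * np.exp(-r / params.decay_length))
        for m in (1, 2, 3):
            got = series.loc[series["time_min"] == m * 60.0, "cumulative_um"].iloc[0]
            assert got == pytest.approx(m * per_period, rel=0.02)
        # increasing between period starts (the plastic-gain property)
        starts = [series.loc[series["time_min"] == m * 60.0,
                             "cumulative_um"].iloc[0] for m in (0, 1, 2, 3)]
        assert np.all(np.diff(starts) > 0)


class TestStripeProfile:
    def test_single_bead_lands_in_its_stripe(self, origin_geometry):
        df = step_table([(0, 0, 150.0, 0.0, 0.0, -2.0, 0.0, 0.0)])
        samples = project_samples(df, origin_geometry)
        prof = stripe_profile(samples, origin_geometry, r_max=300.0)
        row = prof[(prof["stripe_lo"] == 100.0)]
        assert row["s_mean"].iloc[0] == pytest.approx(2.0)
        assert row["n"].iloc[0] == 1
        others = prof[prof["stripe_lo"] != 100.0]
        assert others["s_mean"].isna().all()
        assert (others["n"] == 0).all()

    def test_exponential_decay_matches_bin_averages(self, origin_geometry):
        params = FieldParams(amplitude=2.0, decay_length=150.0,
                             anisotropy_exponent=0.0, period=60.0,
                             plastic_fraction=1.0)
        rng = np.random.default_rng(4)
        n = 4000
        # beads on the axis cone (theta ~ 0) so only exp(-r/lam) varies
        r = rng.uniform(10.0, 500.0, n)
        pos0 = np.column_stack([r, np.zeros(n), np.zeros(n)])
        tracks = advect_tracks(params, pos0, n_frames=2)
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        prof = stripe_profile(samples, origin_geometry, r_max=500.0)
        g1 = temporal_profile(10.0, 60.0, 1.0)  # field fraction after 1 frame
        for _, row in prof.iterrows():
            sel = (r >= row["stripe_lo"]) & (r < row["stripe_hi"])
            expected = g1 * np.mean(2.0 * np.exp(-r[sel] / 150.0))
            assert row["s_mean"] == pytest.approx(expected, rel=0.05)
        # decay with stripe index
        assert prof["s_mean"].is_monotonic_decreasing

    def test_every_sample_in_exactly_one_stripe(self, origin_geometry):
        rng = np.random.default_rng(5)
        pos0 = front_hemisphere_beads(rng, 300, r_lo=5, r_hi=550)
        params = FieldParams(amplitude=1.0)
        tracks = advect_tracks(params, pos0, n_frames=3)
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        prof = stripe_profile(samples, origin_geometry, r_max=600.0)
        assert prof["n"].sum() == len(samples)

    def test_empty_input_flagged_not_zero(self, origin_geometry):
        samples = project_samples(step_table([]), origin_geometry) if False else \
            pd.DataFrame(columns=["track_id", "frame", "r_um", "theta_deg", "s_um"])
        prof = stripe_profile(samples, origin_geometry, r_max=200.0)
        assert prof["s_mean"].isna().all()
        assert (prof["n"] == 0).all()


class TestPhasesAndRelaxation:
    def test_all_positive_series_contraction(self):
        assert label_phases_ecm([0.5, 1.0, 0.2]) == ["contraction"] * 3

    def test_all_zero_series_neutral(self):
        assert label_phases_ecm([0.0, 0.0]) == ["neutral", "neutral"]

    def test_noise_floor_neutralizes_small_values(self):
        assert label_phases_ecm([0.05, -0.2, 0.3], noise_floor=0.1) == \
            ["neutral", "relaxation", "contraction"]

    def test_periodic_elastic_field_alternates_with_period(self, origin_geometry):
        # rho=0: sign of s_mean(t) follows g'(t); period 60 min = 6 frames
        params = FieldParams(amplitude=2.0, plastic_fraction=0.0, period=60.0,
                             anisotropy_exponent=2.0)
        rng = np.random.default_rng(6)
        pos0 = front_hemisphere_beads(rng, 300)
        tracks = advect_tracks(params, pos0, n_frames=13)
        samples = project_samples(tracks_to_displacement_table(tracks),
                                  origin_geometry)
        fm = frame_mean_series(samples, origin_geometry)
        labels = label_phases_ecm(fm["s_mean"].to_numpy())
        assert labels == (["contraction"] * 3 + ["relaxation"] * 3) * 2

    def test_relaxation_delta_flat_series_zero(self):
        series = pd.DataFrame({"time_min": [0, 10, 20],
                               "cumulative_um": [1.0, 1.0, 1.0]})
        assert relaxation_delta(series, 0) == 0.0

    def test_relaxation_delta_event_at_last_frame_zero(self):
        series = pd.DataFrame({"time_min": [0, 10], "cumulative_um": [0.0, 2.0]})
        assert relaxation_delta(series, 1) == 0.0

    def test_reversed_field_gives_minus_phi_fraction(self, origin_geometry):
        # accumulate with a plastic field, then reverse a fraction phi of the
        # accumulated displacement after the event
        params = FieldParams(amplitude=2.0, plastic_fraction=1.0, period=60.0,
                             anisotropy_exponent=0.0)
        rng = np.random.default_rng(7)
        pos0 = front_hemisphere_beads(rng, 200)
        tracks = advect_tracks(params, pos0, n_frames=7)
        phi = 0.4
        # post-event frame: each bead moves back by phi * (accumulated vector)
        reversal = -phi * (tracks[-1] - tracks[0])
        post = tracks[-1] + reversal
        tracks_ext = np.concatenate([tracks, post[None]], axis=0)
        samples = project_samples(tracks_to_displacement_table(tracks_ext),
                                  origin_geometry)
        series = cumulative_displacement(samples, origin_geometry)
        event_frame = 6
        delta = relaxation_delta(series, event_frame)
        value_at_event = series["cumulative_um"].iloc[event_frame]
        assert delta == pytest.approx(-phi * value_at_event, rel=0.03)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            BranchGeometry(tip=(0, 0, 0), axis=(0, 0, 0))
        with pytest.raises(ValueError):
            BranchGeometry(tip=(0, 0, 0), axis=(1, 0, 0), near_field_radius=-1)
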