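"""Motility statistics: r.m.s. velocities, C_vv, xi fit, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collmot.metrics import (
    CorrelationCurve,
    DegenerateFieldError,
    alignment_index,
    compute_motility_series,
    drift_correct,
    fit_correlation_length,
    mean_drift,
    phase_trajectory,
    rms_velocity,
    velocity_correlation,
    windowed_exponential_curve,
)
from collmot.piv import compute_velocity_fields, temporal_average
from collmot.synthetic import FlowSpec, make_speckle_movie
from conftest import make_field, oracle_cvv_direct


def random_field(seed, ny=5, nx=6):
    rng = np.random.default_rng(seed)
    return make_field(rng.normal(1.0, 2.0, (ny, nx)), rng.normal(-0.5, 2.0, (ny, nx)))


class TestRmsAndDrift:
    def test_constant_magnitude_field(self):
        f = make_field([[3.0, 3.0], [3.0, 3.0]], [[4.0, 4.0], [4.0, 4.0]])
        assert rms_velocity(f) == pytest.approx(5.0)

    def test_two_vector_closed_form(self):
        f = make_field([[3.0, 0.0]], [[0.0, 4.0]])
        assert rms_velocity(f) == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_zero_field(self):
        f = make_field(np.zeros((2, 2)), np.zeros((2, 2)))
        assert rms_velocity(f) == 0.0

    def test_no_valid_vectors_is_nan(self):
        f = make_field(np.ones((2, 2)), np.ones((2, 2)), valid=np.zeros((2, 2)))
        assert np.isnan(rms_velocity(f))

    def test_drift_correct_constant_field_zeroes(self):
        f = make_field(np.full((3, 3), 2.0), np.full((3, 3), -1.0))
        dc = drift_correct(f)
        np.testing.assert_allclose(dc.vx, 0.0, atol=1e-12)
        np.testing.assert_allclose(dc.vy, 0.0, atol=1e-12)

    def test_drift_correct_zero_mean_field_unchanged(self):
        f = make_field([[1.0, -1.0]], [[0.0, 0.0]])
        dc = drift_correct(f)
        np.testing.assert_allclose(dc.vx, f.vx, atol=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_drift_corrected_mean_is_zero(self, seed):
        dc = drift_correct(random_field(seed))
        assert np.linalg.norm(mean_drift(dc)) < 1e-10

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_pythagorean_identity(self, seed):
        """(v_RMS^tot)^2 = (v_RMS^dc)^2 + |<v>|^2 on any field."""
        f = random_field(seed)
        tot = rms_velocity(f)
        dc = rms_velocity(drift_correct(f))
        drift = np.linalg.norm(mean_drift(f))
        assert tot**2 == pytest.approx(dc**2 + drift**2, rel=1e-9)


class TestVelocityCorrelation:
    def test_self_bin_is_one(self):
        c = velocity_correlation(drift_correct(random_field(1)))
        assert c.r_um[0] == 0.0
        assert c.c[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("shape", [(3, 3), (6, 6), (8, 8)])
    def test_matches_pair_enumeration_oracle(self, seed, shape):
        f = drift_correct(random_field(seed, *shape))
        curve = velocity_correlation(f)
        yy, xx = np.meshgrid(f.y_px, f.x_px, indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel()])
        vec = np.column_stack([f.vx.ravel(), f.vy.ravel()])
        r_o, c_o, n_o = oracle_cvv_direct(pos, vec, curve.bin_width_um)
        np.testing.assert_allclose(curve.c, c_o, atol=1e-9)
        np.testing.assert_allclose(curve.r_um, r_o, atol=1e-9)
        np.testing.assert_array_equal(curve.n_pairs, n_o)

    def test_antialigned_pair_gives_minus_one(self):
        f = make_field([[1.0, -1.0]], [[0.0, 0.0]])
        curve = velocity_correlation(f)
        assert curve.c[-1] == pytest.approx(-1.0)

    def test_iid_field_decorrelated_beyond_first_bin(self):
        f = drift_correct(random_field(3, 12, 12))
        curve = velocity_correlation(f)
        bound = 3 / np.sqrt(curve.n_pairs[1:])
        assert np.all(np.abs(curve.c[1:]) <= np.maximum(bound, 0.2))

    def test_uniform_field_after_drift_correction_degenerate(self):
        f = drift_correct(make_field(np.full((3, 3), 2.0), np.zeros((3, 3))))
        with pytest.raises(DegenerateFieldError):
            velocity_correlation(f)

    def test_bin_labels_are_mean_separations(self):
        # on a square grid the first bin holds axial and diagonal pairs,
        # so its label must exceed the nominal grid spacing
        f = drift_correct(random_field(4, 6, 6))
        curve = velocity_correlation(f)
        assert curve.r_um[1] > curve.bin_width_um


def synthetic_curve(xi=50.0, n_bins=10, bw=20.0):
    r = np.arange(n_bins) * bw
    return CorrelationCurve(
        r_um=r, c=np.exp(-r / xi), n_pairs=np.full(n_bins, 100),
        bin_width_um=bw, max_extent_um=r[-1],
    )


class TestFitCorrelationLength:
    def test_exact_exponential_recovered(self):
        fit = fit_correlation_length(synthetic_curve(xi=50.0))
        assert fit.ok and abs(fit.xi_um - 50.0) < 0.5

    def test_flat_curve_pegged(self):
        curve = synthetic_curve()
        curve.c = np.ones_like(curve.c)
        fit = fit_correlation_length(curve)
        assert fit.ok and fit.pegged
        assert fit.xi_um >= curve.max_extent_um

    def test_insufficient_bins_flagged_not_raised(self):
        curve = synthetic_curve(n_bins=3)
        curve.c = np.array([1.0, -0.2, -0.1])
        fit = fit_correlation_length(curve)
        assert not fit.ok and np.isnan(fit.xi_um)

    def test_explicit_fit_range_respected(self):
        fit = fit_correlation_length(synthetic_curve(xi=50.0), fit_range=(20.0, 100.0))
        assert fit.ok
        assert fit.fit_r.min() >= 20.0 and fit.fit_r.max() <= 100.0

    def test_windowed_model_limits(self):
        r = np.linspace(0, 300, 31)
        # a tiny window leaves the exponential nearly untouched
        near = windowed_exponential_curve(r, xi_um=50.0, window_um=2.0)
        np.testing.assert_allclose(near, np.exp(-r / 50.0), atol=0.02)
        # a large window broadens the apparent correlation
        broad = windowed_exponential_curve(r, xi_um=50.0, window_um=120.0)
        assert np.all(broad[1:10] >= np.exp(-r[1:10] / 50.0))


class TestAlignmentIndex:
    def test_uniform_field_fully_aligned(self):
        amap = alignment_index(make_field(np.full((3, 3), 2.0), np.zeros((3, 3))))
        np.testing.assert_allclose(amap.a, 1.0)

    def test_antialigned_node(self):
        # mean vector is (0.5, 0); the last node points against it
        amap = alignment_index(make_field([[1.0, 1.0, 1.0, -1.0]], [[0.0] * 4]))
        assert amap.a[0, 3] == pytest.approx(-1.0)

    def test_orthogonal_node_zero(self):
        # mean vector is (0.5, 0); the last two nodes are perpendicular
        amap = alignment_index(make_field([[1.0, 1.0, 0.0, 0.0]], [[0.0, 0.0, 1.0, -1.0]]))
        assert amap.a[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert amap.a[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_field_all_masked(self):
        amap = alignment_index(make_field([[1.0, -1.0]], [[0.0, 0.0]]))
        assert amap.degenerate and not amap.valid.any()

    def test_zero_magnitude_node_masked(self):
        amap = alignment_index(make_field([[1.0, 0.0]], [[0.0, 0.0]]))
        assert not amap.valid[0, 1] and np.isnan(amap.a[0, 1])


class TestSeriesAndTrajectory:
    def test_empty_series_empty_trajectory(self):
        import pandas as pd

        assert phase_trajectory(pd.DataFrame(columns=["t_min", "vrms_dc", "xi_um"])).shape == (0, 2)

    def test_trajectory_time_ordered(self):
        import pandas as pd

        df = pd.DataFrame(
            {"t_min": [20.0, 0.0, 10.0], "vrms_dc": [3.0, 1.0, 2.0], "xi_um": [30.0, 10.0, 20.0]}
        )
        traj = phase_trajectory(df)
        np.testing.assert_allclose(traj[:, 0], [1.0, 2.0, 3.0])

    def test_decaying_flow_slows_over_chunks(self):
        """Jamming emulation: decaying correlated flow must show a
        decreasing total r.m.s. velocity across chunks."""
        mov = make_speckle_movie(
            FlowSpec(kind="correlated", xi_true_px=40, vrms=2.0,
                     decay_half_life=8.0, seed=21),
            shape=(320, 320),
            n_frames=41,
        )
        fields = compute_velocity_fields(mov)
        chunks = temporal_average(fields, 20, 0.5)
        series = compute_motility_series(chunks, window_um=80 * 0.65)
        assert len(series) == 3
        assert np.all(np.diff(series["vrms_tot"]) < 0)

    def test_steady_flow_gives_tight_cluster(self):
        """A constant-speed movie keeps v_RMS^tot steady (CV < 10%)."""
        mov = make_speckle_movie(
            FlowSpec(kind="uniform", drift=(2.0, 1.0), seed=22),
            shape=(240, 240),
            n_frames=31,
        )
        fields = compute_velocity_fields(mov)
        chunks = temporal_average(fields, 20, 0.5)
        series = compute_motility_series(chunks)
        v = series["vrms_tot"].to_numpy()
        assert v.std() / v.mean() < 0.10
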