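import numpy as np
import pytest

from raftperm import nb_brightness as nb, synthetic_data as sd
from raftperm.nb_brightness import ImageStack


def structured_stack(n_frames=30, drift=(0.0, 0.0), seed=0, epsilon=1.0):
    occ = np.full((48, 48), 0.5)
    occ[15:30, 15:30] = 6.0
    p = sd.NBSimParams(mean_occupancy=occ, epsilon=epsilon, n_frames=n_frames,
                       height=48, width=48, drift_px_per_frame=drift, seed=seed)
    return sd.gen_nb_stack(p)


def brute_force_shifts(frames, max_shift=6):
    """Exhaustive integer-shift search minimizing SSD to the first frame."""
    ref = frames[0].astype(float)
    out = [(0, 0)]
    rng = range(-max_shift, max_shift + 1)
    for t in range(1, len(frames)):
        frame = frames[t].astype(float)
        best, best_ssd = (0, 0), np.inf
        for dy in rng:
            for dx in rng:
                shifted = np.roll(frame, (dy, dx), axis=(0, 1))
                core = (slice(max_shift, -max_shift),) * 2
                ssd = np.sum((shifted[core] - ref[core]) ** 2)
                if ssd < best_ssd:
                    best, best_ssd = (dy, dx), ssd
        out.append(best)
    return np.array(out)


class TestImageStack:
    def test_validation(self):
        with pytest.raises(ValueError):
            ImageStack(frames=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            ImageStack(frames=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ImageStack(frames=-np.ones((3, 4, 4)))
        with pytest.raises(ValueError):
            ImageStack(frames=np.zeros((3, 0, 4)))


class TestRegisterStack:
    def test_zero_drift_identity(self):
        stack, _ = structured_stack(n_frames=12, seed=1)
        registered, shifts = nb.register_stack(stack)
        assert np.array_equal(shifts, np.zeros((12, 2), dtype=int))
        assert np.array_equal(registered.frames, stack.frames)

    def test_recovers_linear_drift(self):
        stack, truth = structured_stack(n_frames=8, drift=(0.0, 1.0), seed=2)
        _, shifts = nb.register_stack(stack)
        assert np.array_equal(shifts[:, 1], -truth["shifts"][:, 1])
        assert np.array_equal(shifts[:, 0], np.zeros(8, dtype=int))

    def test_matches_brute_force_on_drifting_point(self):
        # single bright immobile point, diagonal drift, no noise
        frames = np.zeros((6, 32, 32), dtype=int)
        for t in range(6):
            frames[t, 10 + t, 12 + t] = 50
        stack = ImageStack(frames=frames)
        _, shifts = nb.register_stack(stack)
        expected = brute_force_shifts(frames)
        assert np.array_equal(shifts, expected)
        assert np.array_equal(shifts[:, 0], -np.arange(6))

    def test_idempotent(self):
        stack, _ = structured_stack(n_frames=8, drift=(1.0, 0.0), seed=3)
        registered, _ = nb.register_stack(stack)
        _, second = nb.register_stack(registered)
        assert np.array_equal(second, np.zeros((8, 2), dtype=int))

    def test_all_zero_frames_flagged(self):
        stack = ImageStack(frames=np.zeros((5, 16, 16), dtype=int))
        registered, shifts = nb.register_stack(stack)
        assert np.array_equal(shifts, np.zeros((5, 2), dtype=int))
        assert registered.metadata["registration_flagged_frames"]

    def test_wrapped_pixels_marked_invalid(self):
        stack, _ = structured_stack(n_frames=6, drift=(0.0, 2.0), seed=4)
        registered, shifts = nb.register_stack(stack)
        t = 5
        dx = shifts[t, 1]
        assert dx < 0
        assert not registered.valid[t, :, 48 + dx:].any()
        assert registered.valid[t, :, :48 + dx].all()


class TestPixelMoments:
    def test_constant_stack(self):
        stack = ImageStack(frames=np.full((10, 4, 4), 5))
        mean, var = nb.pixel_moments(stack)
        assert np.allclose(mean, 5.0)
        assert np.allclose(var, 0.0)

    def test_two_frame_population_convention(self):
        frames = np.zeros((2, 1, 1), dtype=int)
        frames[1] = 2
        mean, var = nb.pixel_moments(ImageStack(frames=frames))
        assert mean[0, 0] == pytest.approx(1.0)
        assert var[0, 0] == pytest.approx(1.0)  # denominator T, not T-1

    def test_poisson_moment_identity(self, rng):
        frames = rng.poisson(4.0, size=(25000, 12, 12))
        mean, var = nb.pixel_moments(ImageStack(frames=frames))
        ok = (np.abs(mean - 4.0) < 0.12) & (np.abs(var - 4.0) < 0.12)
        assert ok.mean() >= 0.99

    def test_invalid_pixels_nan(self):
        frames = np.ones((3, 2, 2), dtype=int)
        valid = np.ones_like(frames, dtype=bool)
        valid[:2, 0, 0] = False  # only 1 valid frame at this pixel
        mean, var = nb.pixel_moments(ImageStack(frames=frames, valid=valid))
        assert np.isnan(mean[0, 0]) and np.isnan(var[0, 0])
        assert mean[1, 1] == 1.0


class TestApparentBrightness:
    def test_zero_variance(self):
        mean = np.full((3, 3), 5.0)
        b = nb.apparent_brightness(mean, np.zeros((3, 3)))
        assert np.allclose(b, 0.0)

    def test_shot_noise_identity(self):
        mean = np.full((3, 3), 4.0)
        b = nb.apparent_brightness(mean, mean.copy())
        assert np.allclose(b, 1.0)

    def test_mean_floor_exclusion(self):
        mean = np.array([[0.05, 2.0]])
        var = np.array([[0.05, 4.0]])
        b = nb.apparent_brightness(mean, var)
        assert np.isnan(b[0, 0]) and b[0, 1] == pytest.approx(2.0)

    def test_all_below_floor_errors(self):
        with pytest.raises(ValueError, match="no analyzable"):
            nb.apparent_brightness(np.full((2, 2), 0.01), np.full((2, 2), 0.01))

    def test_simulator_closed_form(self):
        p = sd.NBSimParams(mean_occupancy=2.0, epsilon=0.2, n_frames=3000,
                           height=32, width=32, seed=11)
        stack, _ = sd.gen_nb_stack(p)
        mean, var = nb.pixel_moments(stack)
        b = nb.apparent_brightness(mean, var)
        assert np.nanmedian(b) == pytest.approx(1.2, rel=0.1)

    def test_identity_b_times_mean_is_var(self, rng):
        frames = rng.poisson(3.0, size=(50, 8, 8))
        mean, var = nb.pixel_moments(ImageStack(frames=frames))
        b = nb.apparent_brightness(mean, var)
        ok = np.isfinite(b)
        assert np.allclose(b[ok] * mean[ok], var[ok])


class TestMolecularBrightness:
    def test_unit_brightness_gives_zero_epsilon(self):
        b = np.ones((4, 4))
        eps_map, summary = nb.molecular_brightness(b, reference_epsilon=0.3)
        assert np.allclose(eps_map, 0.0)
        assert summary.center == 0.0
        assert summary.ratio_to_reference == 0.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            nb.molecular_brightness(np.ones((2, 2)), reference_epsilon=0.0)

    def test_negative_center_warns(self):
        with pytest.warns(UserWarning, match="over-subtracted"):
            nb.molecular_brightness(np.full((4, 4), 0.8))

    def test_dimer_vs_monomer_ratio(self):
        summaries = {}
        for eps in (0.2, 0.4):
            p = sd.NBSimParams(mean_occupancy=2.0, epsilon=eps, n_frames=3000,
                               height=32, width=32, seed=21)
            stack, _ = sd.gen_nb_stack(p)
            mean, var = nb.pixel_moments(stack)
            b = nb.apparent_brightness(mean, var)
            _, summaries[eps] = nb.molecular_brightness(b)
        ratio = summaries[0.4].center / summaries[0.2].center
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestQC:
    def test_stationary_accepted(self):
        p = sd.NBSimParams(mean_occupancy=2.0, epsilon=0.2, n_frames=100,
                           seed=31)
        stack, _ = sd.gen_nb_stack(p)
        report = nb.qc_stack(stack)
        assert report.accepted
        assert report.convergence_slope <= -0.5
        assert abs(report.mean_decay_fraction) < 0.05

    def test_bleaching_rejected(self):
        p = sd.NBSimParams(mean_occupancy=2.0, epsilon=0.2, n_frames=100,
                           bleach_fraction=0.2, seed=32)
        stack, _ = sd.gen_nb_stack(p)
        report = nb.qc_stack(stack)
        assert not report.accepted
        assert "mean_decay" in report.reasons
        assert report.mean_decay_fraction > 0.10

    def test_mild_bleach_passes_decay_rule(self):
        p = sd.NBSimParams(mean_occupancy=4.0, epsilon=0.5, n_frames=100,
                           bleach_fraction=0.04, seed=33)
        stack, _ = sd.gen_nb_stack(p)
        report = nb.qc_stack(stack)
        assert "mean_decay" not in report.reasons

    def test_step_change_rejected_by_convergence(self, rng):
        frames = rng.poisson(2.0, size=(100, 48, 48))
        frames[50:] = rng.poisson(3.0, size=(50, 48, 48))
        report = nb.qc_stack(ImageStack(frames=frames))
        assert not report.accepted
        assert "variance_not_converged" in report.reasons

    def test_short_stack(self):
        report = nb.qc_stack(ImageStack(frames=np.ones((10, 8, 8), dtype=int)))
        assert not report.accepted
        assert report.reasons == ["short_stack"]

    def test_constant_stack_trivially_converged(self):
        report = nb.qc_stack(ImageStack(frames=np.full((50, 8, 8), 3)))
        assert report.accepted


class TestPipeline:
    def test_crop_center(self):
        stack = ImageStack(frames=np.arange(4 * 8 * 8).reshape(4, 8, 8))
        cropped = nb.crop_center(stack, 4)
        assert cropped.shape == (4, 4, 4)
        assert cropped.frames[0, 0, 0] == stack.frames[0, 2, 2]

    def test_analyze_stack_report(self):
        p = sd.NBSimParams(mean_occupancy=2.0, epsilon=0.2, n_frames=400,
                           height=48, width=48, seed=41)
        stack, _ = sd.gen_nb_stack(p)
        report = nb.analyze_stack(stack, region=32, register=False,
                                  reference_epsilon=0.2)
        assert report["qc"].accepted
        assert report["maps"].b_map.shape == (32, 32)
        assert report["epsilon_summary"].center == pytest.approx(0.2, abs=0.05)

    def test_analyze_stack_rejects_without_maps(self):
        p = sd.NBSimParams(mean_occupancy=2.0, epsilon=0.2, n_frames=100,
                           bleach_fraction=0.3, seed=42)
        stack, _ = sd.gen_nb_stack(p)
        report = nb.analyze_stack(stack)
        assert not report["qc"].accepted
        assert report["maps"] is None
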