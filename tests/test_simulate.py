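import numpy as np
import pytest

from scanstorm import (ScanConfig, EmitterRecord, step_emitter_states,
                       render_line, finalize_frame, accept_ground_truth,
                       simulate_stack, make_training_crops)
from scanstorm.psf import airy_psf


def small_config(**kw):
    defaults = dict(s_px=10, s_im=9, airy_radius_range=(25, 30), seed=0)
    defaults.update(kw)
    return ScanConfig(**defaults)


def make_emitter(cfg, countdown=0.0, lifetime=1e9, x=None, y=None, photons=1000):
    n = cfg.n_sub
    return EmitterRecord(Lx=n / 2 if x is None else x,
                         Ly=n / 2 if y is None else y,
                         photons=photons, countdown_ms=countdown,
                         lifetime_ms=lifetime)


class TestStateMachine:
    def test_zero_rate_keeps_empty(self, rng):
        cfg = small_config(lambda_on=0.0)
        assert step_emitter_states([], cfg, rng) == []

    def test_countdown_hand_trace(self, rng):
        """countdown 12 ms at dt 6 ms: silent for two lines, ON on line 3."""
        cfg = small_config(lambda_on=0.0)
        e = make_emitter(cfg, countdown=12.0, lifetime=60.0)
        active = [e]
        for line in range(3):
            active = step_emitter_states(active, cfg, rng)
        assert e.countdown_ms <= 0
        history = []
        e2 = make_emitter(cfg, countdown=12.0, lifetime=60.0)
        active = [e2]
        for line in range(4):
            active = step_emitter_states(active, cfg, rng)
            history.append(e2.on_current_line)
        assert history == [False, False, True, True]

    def test_exhausted_lifetime_removed(self, rng):
        cfg = small_config(lambda_on=0.0)
        e = make_emitter(cfg, countdown=0.0, lifetime=6.0)
        active = step_emitter_states([e], cfg, rng)   # ON, lifetime -> 0
        assert e.on_current_line
        active = step_emitter_states(active, cfg, rng)
        assert active == []

    def test_lifetime_and_countdown_poisson_means(self):
        """Empirical means of spawned lifetimes/countdowns match the
        Poisson(90) model within 3 standard errors at n = 10^4.

        New emitters are observed right after their spawning line, where
        one dt has already been applied to the countdown (or, for the rare
        countdown == 0 draw, to the lifetime); the draw is reconstructed
        by adding dt back.
        """
        cfg = small_config(lambda_on=5.0)
        rng = np.random.default_rng(12345)
        lifetimes, countdowns = [], []
        while len(lifetimes) < 10_000:
            for e in step_emitter_states([], cfg, rng):
                if e.on_current_line:           # countdown draw was 0
                    countdowns.append(0.0)
                    lifetimes.append(e.lifetime_ms + cfg.dt_line_ms)
                else:
                    countdowns.append(e.countdown_ms + cfg.dt_line_ms)
                    lifetimes.append(e.lifetime_ms)
        n = len(lifetimes)
        se = 3 * np.sqrt(90.0 / n)
        assert abs(np.mean(lifetimes) - 90.0) < se
        assert abs(np.mean(countdowns) - 90.0) < se

    def test_photon_counts_within_model_range(self):
        cfg = small_config(lambda_on=5.0)
        rng = np.random.default_rng(7)
        active = step_emitter_states([], cfg, rng)
        for _ in range(50):
            active = step_emitter_states(active, cfg, rng)
        base = [e.photons for e in active]
        assert all(800 <= b <= 1500 for b in base)


class TestRendering:
    def test_empty_band_unchanged(self, rng):
        cfg = small_config()
        S = np.zeros((cfg.n_sub, cfg.n_sub))
        render_line(3, [], S, cfg.s_px)
        assert not S.any()

    def test_band_partition_reassembles_full_psf(self, rng):
        """Summing band-clipped renders over all lines equals the full
        PSF times the photon count (photon conservation)."""
        cfg = small_config()
        k = airy_psf(27, 55)
        e = make_emitter(cfg, countdown=0.0)
        e.on_current_line = True
        S = np.zeros((cfg.n_sub, cfg.n_sub))
        for line in range(cfg.s_im):
            render_line(line, [e], S, cfg.s_px, psf=k, photons=750.0)
        # reference: direct placement of the clipped kernel
        ref = np.zeros_like(S)
        c = int(round(e.Ly)) - 27, int(round(e.Lx)) - 27
        ref[c[0]:c[0] + 55, c[1]:c[1] + 55] = 750.0 * k
        assert np.allclose(S, ref, atol=1e-9)
        mass_in_fov = k.sum()
        assert S.sum() == pytest.approx(750.0 * mass_in_fov, rel=1e-9)

    def test_off_switch_truncates_psf(self, rng):
        """An emitter OFF from line l contributes nothing to rows >= l*s_px."""
        cfg = small_config()
        k = airy_psf(27, 55)
        e = make_emitter(cfg, countdown=0.0)
        off_line = 5
        S = np.zeros((cfg.n_sub, cfg.n_sub))
        for line in range(cfg.s_im):
            e.on_current_line = line < off_line
            render_line(line, [e], S, cfg.s_px, psf=k, photons=1000.0)
        assert not S[off_line * cfg.s_px:, :].any()
        assert S[:off_line * cfg.s_px, :].any()


class TestFinalize:
    def test_constant_preserved_and_noise_toggles(self):
        cfg = small_config(shot_noise=False, read_noise=False)
        S = np.full((cfg.n_sub, cfg.n_sub), 7.25)
        noisy, clean = finalize_frame(S, cfg, np.random.default_rng(0))
        assert np.allclose(clean, 7.25)
        assert np.array_equal(noisy, clean)

    def test_noise_statistics(self):
        """Mean offset ~0 and std ~ sigma over many realizations."""
        cfg = small_config(shot_noise=False, read_noise=True)
        S = np.zeros((cfg.n_sub, cfg.n_sub))
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(100):
            noisy, clean = finalize_frame(S, cfg, rng, noise_sigma=180.0)
            diffs.append(noisy - clean)
        d = np.stack(diffs)
        assert abs(d.mean()) < 3 * 180.0 / np.sqrt(d.size)
        assert d.std() == pytest.approx(180.0, rel=0.05)

    def test_shot_noise_scales_with_signal(self):
        cfg = small_config(shot_noise=True, read_noise=False)
        S = np.full((cfg.n_sub, cfg.n_sub), 900.0)
        rng = np.random.default_rng(2)
        noisy, clean = finalize_frame(S, cfg, rng)
        resid = noisy - clean
        assert resid.std() == pytest.approx(30.0, rel=0.15)  # sqrt(900)


class TestAcceptance:
    @pytest.mark.parametrize("rendered,on,expected", [
        (10, 10, True),
        (4, 10, True),    # exactly 40%: boundary accepted
        (3, 10, False),
        (0, 0, False),    # never ON
    ])
    def test_min_on_fraction_rule(self, rendered, on, expected):
        cfg = small_config()
        e = make_emitter(cfg)
        e.lines_rendered, e.lines_on = rendered, on
        assert accept_ground_truth(e, cfg) is expected


class TestStacksAndCrops:
    def test_stack_determinism(self):
        cfg = small_config(seed=5)
        a = simulate_stack(cfg, 3, rng=5)
        b = simulate_stack(cfg, 3, rng=5)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.noiseless, b.noiseless)
        assert [[(t.x_px, t.y_px) for t in f] for f in a.ground_truth] == \
               [[(t.x_px, t.y_px) for t in f] for f in b.ground_truth]

    def test_truth_coordinates_in_bounds(self):
        cfg = small_config(seed=6, lambda_on=0.5)
        stack = simulate_stack(cfg, 4, rng=6)
        for frame_truth in stack.ground_truth:
            for t in frame_truth:
                assert 0 <= t.x_px < cfg.s_im
                assert 0 <= t.y_px < cfg.s_im

    def test_crop_counts_and_determinism(self):
        cfg = small_config(seed=8)
        crops = make_training_crops(12, cfg, rng=8)
        assert all(0 <= len(c.truth) <= 10 for c in crops)
        crops2 = make_training_crops(12, cfg, rng=8)
        for a, b in zip(crops, crops2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_forced_empty_crop_is_pure_noise(self):
        cfg = small_config(seed=9)
        crop = make_training_crops(1, cfg, rng=9, n_range=(0, 0))[0]
        assert crop.truth == []
        assert crop.pixels.shape == (3, 9, 9)

    def test_isolated_crops_have_one_full_emitter(self):
        from scanstorm.simulate import make_isolated_crops

        cfg = small_config(seed=11)
        crops = make_isolated_crops(5, cfg, rng=11)
        for c in crops:
            assert len(c.truth) == 1
            t = c.truth[0]
            assert 0.5 <= t.x_px <= 8.5 and 0.5 <= t.y_px <= 8.5
            # the emitter is ON in all three frames: every frame carries
            # signal, and the brightest pixel sits at the emitter
            for f in range(3):
                assert c.pixels[f].max() > 0
            r, cc = np.unravel_index(np.argmax(c.pixels[1]), (9, 9))
            assert abs(r + 0.5 - t.y_px) <= 1.0
            assert abs(cc + 0.5 - t.x_px) <= 1.0

    def test_noise_sigma_zero_reproduces_noiseless(self):
        cfg = small_config(seed=10, shot_noise=False)
        crop = make_training_crops(1, cfg, rng=10, noise_sigma=0.0)[0]
        assert np.allclose(crop.pixels[1], crop.noiseless)
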