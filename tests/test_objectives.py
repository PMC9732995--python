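import numpy as np
import pytest

from scanstorm.networks import CHANNELS, apply_output_activations
from scanstorm.nn import Tensor
from scanstorm.objectives import (GroundTruthBatch, localisation_mixture,
                                  localisation_loss, count_loss,
                                  background_loss, total_loss)


def single_truth(x=4.5, y=4.5, n=1.0):
    return GroundTruthBatch(x=np.array([[x]]), y=np.array([[y]]),
                            N=np.array([[n]]), mask=np.ones((1, 1)),
                            count=np.ones(1), noiseless=np.zeros((1, 9, 9)))


def perfect_fs(x=4.5, y=4.5, n=1.0, sigma=1.0):
    fs = np.zeros((1, 8, 9, 9))
    r, c = int(y), int(x)
    fs[0, CHANNELS["p"], r, c] = 1.0
    fs[0, CHANNELS["dx"], r, c] = x - c - 0.5
    fs[0, CHANNELS["dy"], r, c] = y - r - 0.5
    fs[0, CHANNELS["N"], r, c] = n
    for k in ("sx", "sy", "sN"):
        fs[0, CHANNELS[k]] = sigma
    return fs


class TestLocalisationMixture:
    def test_exact_match_closed_form(self):
        mix = localisation_mixture(perfect_fs(), single_truth()).data
        assert mix[0, 0] == pytest.approx(1.0 / np.sqrt((2 * np.pi) ** 3),
                                          rel=1e-4)

    def test_density_decreases_with_distance(self):
        vals = [float(localisation_mixture(perfect_fs(),
                                           single_truth(x=4.5 + d)).data[0, 0])
                for d in (0.0, 0.2, 0.4)]
        assert vals[0] > vals[1] > vals[2]

    def test_doubling_sigma_x_halves_density(self):
        gt = single_truth()
        d1 = localisation_mixture(perfect_fs(sigma=1.0), gt).data[0, 0]
        fs = perfect_fs(sigma=1.0)
        fs[0, CHANNELS["sx"]] = 2.0
        d2 = localisation_mixture(fs, gt).data[0, 0]
        assert d2 / d1 == pytest.approx(0.5, rel=1e-4)

    def test_loss_increases_away_from_truth(self):
        losses = [float(localisation_loss(perfect_fs(), single_truth(x=4.5 + d)
                                          ).data) for d in (0.0, 0.3, 0.6)]
        assert losses[0] < losses[1] < losses[2]


class TestCountLoss:
    def test_half_half_closed_form(self):
        fs = np.zeros((1, 8, 9, 9))
        fs[0, CHANNELS["p"], 0, 0] = 0.5
        fs[0, CHANNELS["p"], 0, 1] = 0.5
        val = float(count_loss(fs, single_truth()).data)
        assert val == pytest.approx(-np.log(np.sqrt(np.pi)), abs=1e-5)

    def test_quadratic_term_vanishes_at_correct_count(self):
        fs = np.zeros((1, 8, 9, 9))
        fs[0, CHANNELS["p"], 0, 0] = 0.5
        fs[0, CHANNELS["p"], 0, 1] = 0.5
        printed = float(count_loss(fs, single_truth()).data)
        # analytic: quad = 0, so value equals the pure log term
        assert printed == pytest.approx(-np.log(np.sqrt(2 * np.pi * 0.5)),
                                        abs=1e-5)

    def test_sigma_c_shrinks_toward_confident_p(self):
        def sigma_c(pvals):
            p = np.array(pvals)
            return (p * (1 - p)).sum()

        assert sigma_c([0.9, 0.1]) < sigma_c([0.5, 0.5])
        assert sigma_c([1.0, 0.0]) == 0.0

    def test_nll_form_flips_log_sign(self):
        fs = np.zeros((1, 8, 9, 9))
        fs[0, CHANNELS["p"], 0, 0] = 0.5
        fs[0, CHANNELS["p"], 0, 1] = 0.5
        printed = float(count_loss(fs, single_truth(), form="printed").data)
        nll = float(count_loss(fs, single_truth(), form="nll",
                               var_floor=1e-6).data)
        assert nll == pytest.approx(-printed, abs=1e-6)


class TestBackgroundLoss:
    def test_exact_match_zero(self):
        gt = single_truth()
        fs = np.zeros((1, 8, 9, 9))
        assert float(background_loss(fs, gt).data) == pytest.approx(0.0,
                                                                    abs=1e-5)

    def test_absolute_difference(self):
        gt = single_truth()
        gt.noiseless[:] = 3.0
        fs = np.zeros((1, 8, 9, 9))
        fs[0, CHANNELS["B"]] = 5.0
        assert float(background_loss(fs, gt).data) == pytest.approx(2.0,
                                                                    rel=1e-5)

    def test_symmetric(self):
        gt_a = single_truth()
        gt_a.noiseless[:] = 1.25
        fs_a = np.zeros((1, 8, 9, 9))
        fs_a[0, CHANNELS["B"]] = 4.0
        gt_b = single_truth()
        gt_b.noiseless[:] = 4.0
        fs_b = np.zeros((1, 8, 9, 9))
        fs_b[0, CHANNELS["B"]] = 1.25
        assert float(background_loss(fs_a, gt_a).data) == pytest.approx(
            float(background_loss(fs_b, gt_b).data), rel=1e-9)


class TestTotalLoss:
    def test_sum_of_components(self):
        fs = perfect_fs()
        gt = single_truth()
        total, comps = total_loss(fs, gt, include_components=True)
        assert float(total.data) == pytest.approx(
            comps["loc"] + comps["count"] + comps["bg"], rel=1e-9)

    def test_empty_crop_contributes_no_localisation_term(self):
        gt = GroundTruthBatch(x=np.zeros((1, 1)), y=np.zeros((1, 1)),
                              N=np.zeros((1, 1)), mask=np.zeros((1, 1)),
                              count=np.zeros(1), noiseless=np.zeros((1, 9, 9)))
        fs = np.zeros((1, 8, 9, 9))
        assert float(localisation_loss(fs, gt).data) == 0.0

    def test_gradients_match_finite_differences(self, rng):
        """Analytic gradients of all three components agree with central
        finite differences on a random small input."""
        raw_data = rng.normal(0, 0.5, (1, 8, 9, 9))
        gt = GroundTruthBatch(
            x=np.array([[4.2, 2.8]]), y=np.array([[4.7, 6.1]]),
            N=np.array([[1.0, 1.3]]), mask=np.ones((1, 2)),
            count=np.array([2.0]),
            noiseless=rng.normal(0.1, 0.05, (1, 9, 9)))

        for comp in (localisation_loss,
                     lambda f, g: count_loss(f, g, form="nll"),
                     background_loss):
            raw = Tensor(raw_data.copy(), requires_grad=True)
            loss = comp(apply_output_activations(raw), gt)
            loss.backward()
            g_analytic = raw.grad.copy()
            # spot-check 10 random coordinates
            for _ in range(10):
                idx = tuple(rng.integers(0, s) for s in raw_data.shape)
                eps = 1e-6
                pert = raw_data.copy()
                pert[idx] += eps
                fp = float(comp(apply_output_activations(pert), gt).data)
                pert[idx] -= 2 * eps
                fm = float(comp(apply_output_activations(pert), gt).data)
                num = (fp - fm) / (2 * eps)
                assert g_analytic[idx] == pytest.approx(num, rel=1e-4,
                                                        abs=1e-8)

    def test_perfect_prediction_beats_perturbations(self, rng):
        gt = single_truth(x=4.3, y=4.8, n=1.1)
        fs0 = perfect_fs(x=4.3, y=4.8, n=1.1, sigma=0.05)
        base = float(total_loss(fs0, gt).data)
        for _ in range(100):
            fs = fs0 + rng.normal(0, 0.15, fs0.shape)
            fs[:, CHANNELS["p"]] = np.clip(fs[:, CHANNELS["p"]], 0, 1)
            for k in ("sx", "sy", "sN"):
                fs[:, CHANNELS[k]] = np.clip(fs[:, CHANNELS[k]], 0.05, 3)
            fs[:, CHANNELS["N"]] = np.clip(fs[:, CHANNELS["N"]], 0, None)
            fs[:, CHANNELS["B"]] = np.clip(fs[:, CHANNELS["B"]], 0, None)
            assert float(total_loss(fs, gt).data) > base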