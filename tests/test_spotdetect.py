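import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.signal import convolve2d

from vesiclefill import synthgen
from vesiclefill.errors import InvalidArgumentError
from vesiclefill.spotdetect import (DetectionParams, accept_experiment,
                                    atrous_transform, detection_mask,
                                    difference_image, extract_traces,
                                    mask_component_table)

B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class TestAtrousTransform:
    def test_constant_image_has_zero_details(self):
        planes = atrous_transform(np.full((32, 32), 3.7), k=4)
        for w in planes[:-1]:
            assert np.allclose(w, 0.0, atol=1e-12)
        assert np.allclose(planes[-1], 3.7)

    def test_reconstruction_identity(self, rng):
        img = rng.normal(0, 1, (48, 40))
        planes = atrous_transform(img, k=4)
        assert np.max(np.abs(sum(planes) - img)) < 1e-9 * np.ptp(img)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (16, 16),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_reconstruction_identity_property(self, img):
        planes = atrous_transform(img, k=3)
        scale = max(np.ptp(img), 1.0)
        assert np.max(np.abs(sum(planes) - img)) < 1e-9 * scale

    def test_impulse_planes_match_direct_convolution_oracle(self):
        # detail planes of a centred unit impulse, k = 2, away from borders
        n = 65
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        planes = atrous_transform(img, k=2)
        k2d = np.outer(B3, B3)
        smooth1 = convolve2d(img, k2d, mode="same", boundary="symm")
        k_dilated = np.zeros((9, 9))
        k_dilated[::2, ::2] = k2d
        smooth2 = convolve2d(smooth1, k_dilated, mode="same",
                             boundary="symm")
        assert np.allclose(planes[0], img - smooth1, atol=1e-12)
        assert np.allclose(planes[1], smooth1 - smooth2, atol=1e-12)
        assert np.allclose(planes[2], smooth2, atol=1e-12)

    def test_non_2d_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            atrous_transform(np.zeros(10), k=2)


class TestDifferenceImage:
    def test_static_stack_gives_zero(self, protocol):
        stack = np.full((protocol.n_frames, 16, 16), 50.0)
        assert np.allclose(difference_image(stack, protocol), 0.0)

    def test_peak_equals_amplitude_times_psf_peak(self, protocol,
                                                  kinetics_default):
        trs, truth = synthgen.simulate_truth_traces(
            protocol, kinetics_default, 1, noise_sd=0.0, seed=0)
        stack, truth = synthgen.render_image_stack(
            trs, truth, field_size=(64, 64), noise_sd=0.0,
            positions=[(32.0, 32.0)], seed=0)
        diff = difference_image(stack, protocol)
        e0, e1 = protocol.stim_end_window()
        expected_peak = trs[0].f[e0:e1].mean() - trs[0].f[:5].mean()
        assert diff.max() == pytest.approx(expected_peak, rel=1e-9)

    def test_negative_going_channel_flag(self, protocol):
        stack = np.full((protocol.n_frames, 8, 8), 100.0)
        e0, e1 = protocol.stim_end_window()
        stack[e0:e1, 4, 4] = 60.0  # CypHer-like dimming
        diff = difference_image(stack, protocol, negative_going=True)
        assert diff[4, 4] > 0


class TestDetectionMask:
    def test_pure_noise_false_positive_area(self):
        # Monte-Carlo over 20 seeds: FP mask area below 0.5% of pixels
        areas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = rng.normal(0, 1, (128, 128))
            mask = detection_mask(atrous_transform(img, 4))
            areas.append(mask.mask.mean())
        assert np.mean(areas) < 0.005

    def test_single_spot_detected_within_one_pixel(self, protocol,
                                                   kinetics_default):
        trs, truth = synthgen.simulate_truth_traces(
            protocol, kinetics_default, 1, noise_sd=0.0, seed=0)
        stack, truth = synthgen.render_image_stack(
            trs, truth, field_size=(64, 64), noise_sd=5.0,
            positions=[(30.0, 35.0)], seed=1)
        diff = difference_image(stack, protocol)
        mask = detection_mask(atrous_transform(diff, 4))
        assert mask.n_components == 1
        r, c = mask.centroids[0]
        assert abs(r - 30.0) < 1.0 and abs(c - 35.0) < 1.0

    def test_zero_image_gives_empty_mask(self):
        mask = detection_mask(atrous_transform(np.zeros((32, 32)), 4))
        assert mask.n_components == 0
        assert not mask.mask.any()

    def test_translation_equivariance(self, protocol, kinetics_default):
        trs, truth = synthgen.simulate_truth_traces(
            protocol, kinetics_default, 1, noise_sd=0.0, seed=0)
        stack, _ = synthgen.render_image_stack(
            trs, truth, field_size=(64, 64), noise_sd=0.0,
            positions=[(28.0, 28.0)], seed=0)
        diff = difference_image(stack, protocol)
        m1 = detection_mask(atrous_transform(diff, 4))
        m2 = detection_mask(atrous_transform(np.roll(diff, (5, 3),
                                                     axis=(0, 1)), 4))
        assert m2.n_components == 1
        assert m2.centroids[0][0] == pytest.approx(m1.centroids[0][0] + 5,
                                                   abs=0.1)
        assert m2.centroids[0][1] == pytest.approx(m1.centroids[0][1] + 3,
                                                   abs=0.1)


class TestExtractTraces:
    def test_known_component_means_recovered(self):
        stack = np.zeros((10, 16, 16))
        stack[:, 5:7, 5:7] = np.arange(10)[:, None, None]
        mask = detection_mask_from_box((16, 16), (5, 7), (5, 7))
        trs = extract_traces(stack, mask)
        assert np.allclose(trs[0].f, np.arange(10))

    def test_uniform_offset_cancelled_by_ring(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 1, (10, 24, 24))
        mask = detection_mask_from_box((24, 24), (10, 13), (10, 13))
        t1 = extract_traces(base, mask)
        t2 = extract_traces(base + 17.5, mask)
        assert np.allclose(t1[0].f, t2[0].f, atol=1e-9)

    def test_two_disjoint_components_match_truth(self, protocol,
                                                 kinetics_default):
        kin = {"a": synthgen.KineticParams(tau_s=4.9, amplitude=60.0)}
        trs, truth = synthgen.simulate_truth_traces(protocol, kin, 2,
                                                    noise_sd=0.0, seed=0)
        stack, _ = synthgen.render_image_stack(
            trs, truth, field_size=(80, 80), noise_sd=0.0,
            positions=[(20.0, 20.0), (60.0, 60.0)], seed=0)
        diff = difference_image(stack, protocol)
        mask = detection_mask(atrous_transform(diff, 4))
        assert mask.n_components == 2
        got = extract_traces(stack, mask,
                             frame_rate_hz=protocol.frame_rate_hz)
        # spot means are attenuated versions of the point traces; the
        # correlation with truth should be essentially exact
        order = np.argsort([c[0] for c in mask.centroids])
        for comp, tr in zip(np.array(got)[order], trs):
            centred = tr.f - tr.f.mean()
            got_c = comp.f - comp.f.mean()
            rho = np.dot(centred, got_c) / np.sqrt(
                np.dot(centred, centred) * np.dot(got_c, got_c))
            assert rho > 0.9999

    def test_border_component_flagged(self):
        stack = np.zeros((6, 16, 16))
        stack[:, 0:3, 4:8] = 10.0
        mask = detection_mask_from_box((16, 16), (0, 3), (4, 8))
        trs = extract_traces(stack, mask)
        assert trs[0].border_flagged


class TestAcceptance:
    @pytest.mark.parametrize("n, expected", [(51, True), (50, False),
                                             (0, False)])
    def test_strictly_more_than_min_boutons(self, n, expected):
        mask = synthetic_mask_with_components(n)
        assert accept_experiment(mask) is expected


class TestRecallOnSyntheticStacks:
    def test_recall_and_false_positives_at_default_snr(self, protocol):
        kin = {"g": synthgen.KineticParams(tau_s=4.9, amplitude=50.0)}
        trs, truth = synthgen.simulate_truth_traces(protocol, kin, 60,
                                                    noise_sd=0.02, seed=11)
        stack, truth = synthgen.render_image_stack(
            trs, truth, field_size=(256, 256), noise_sd=2.0, seed=11)
        diff = difference_image(stack, protocol)
        mask = detection_mask(atrous_transform(diff, 4))
        true_pos = 0
        for r, c in truth.bouton_positions:
            if any((r - cr) ** 2 + (c - cc) ** 2 < 3.0 ** 2
                   for cr, cc in mask.centroids):
                true_pos += 1
        recall = true_pos / len(truth.bouton_positions)
        false_pos = mask.n_components - true_pos
        assert recall >= 0.95
        assert false_pos <= 0.05 * len(truth.bouton_positions)
        assert len(mask_component_table(mask)) == mask.n_components


# -- helpers ---------------------------------------------------------------

def detection_mask_from_box(shape, rows, cols):
    from vesiclefill.spotdetect import BoutonMask
    m = np.zeros(shape, dtype=bool)
    m[rows[0]:rows[1], cols[0]:cols[1]] = True
    labels = m.astype(int)
    centroid = ((rows[0] + rows[1] - 1) / 2, (cols[0] + cols[1] - 1) / 2)
    return BoutonMask(mask=m, labels=labels, centroids=[centroid],
                      areas=[int(m.sum())])


def synthetic_mask_with_components(n):
    from vesiclefill.spotdetect import BoutonMask
    size = 220
    m = np.zeros((size, size), dtype=bool)
    labels = np.zeros((size, size), dtype=int)
    cents, areas = [], []
    for i in range(n):
        r, c = 5 + 10 * (i // 20), 5 + 10 * (i % 20)
        m[r:r + 3, c:c + 3] = True
        labels[r:r + 3, c:c + 3] = i + 1
        cents.append((r + 1.0, c + 1.0))
        areas.append(9)
    return BoutonMask(mask=m, labels=labels, centroids=cents, areas=areas)
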