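import numpy as np
import pytest

from duvmargin import gradcampp as gpp


# ---------------------------------------------------------------------------
# Fixture networks
# ---------------------------------------------------------------------------


@pytest.fixture
def linear_model():
    """Y = sum of all activations."""
    return gpp.CamModel(feature_layers=[], head_layers=[gpp.GlobalSum()], score="linear")


@pytest.fixture
def square_model():
    """Y = (sum of all activations)^2."""
    return gpp.CamModel(
        feature_layers=[], head_layers=[gpp.GlobalSum(), gpp.Square()], score="linear"
    )


def make_smooth_model(score="linear", seed=5):
    """Tiny smooth CNN: conv+tanh features, channel-mix+tanh head, 2 classes."""
    rng = np.random.default_rng(seed)
    conv = gpp.Conv2d(rng.normal(scale=0.4, size=(2, 3, 3, 3)), rng.normal(scale=0.1, size=2))
    mix = gpp.ChannelMix(rng.normal(scale=0.5, size=(2, 2)), rng.normal(scale=0.1, size=2))
    head_linear = gpp.Linear(rng.normal(scale=0.7, size=(2, 2)))
    return gpp.CamModel(
        feature_layers=[conv, gpp.Tanh()],
        head_layers=[mix, gpp.Tanh(), gpp.SpatialMean(), head_linear],
        score=score,
    )


def fd_derivatives(f, acts, h1=1e-4, h2=1e-3, h3=5e-3):
    """Central finite-difference oracle for elementwise 1st/2nd/3rd derivatives."""
    flat = acts.reshape(-1)
    first = np.zeros_like(flat)
    second = np.zeros_like(flat)
    third = np.zeros_like(flat)
    for i in range(flat.size):
        def probe(delta, _i=i):
            pert = flat.copy()
            pert[_i] += delta
            return f(pert.reshape(acts.shape))

        first[i] = (probe(h1) - probe(-h1)) / (2 * h1)
        second[i] = (probe(h2) - 2 * probe(0.0) + probe(-h2)) / h2**2
        third[i] = (probe(2 * h3) - 2 * probe(h3) + 2 * probe(-h3) - probe(-2 * h3)) / (
            2 * h3**3
        )
    return first.reshape(acts.shape), second.reshape(acts.shape), third.reshape(acts.shape)


# ---------------------------------------------------------------------------
# higher_order_grads
# ---------------------------------------------------------------------------


class TestHigherOrderGrads:
    def test_linear_model(self, linear_model, rng):
        acts = rng.normal(size=(2, 3, 3))
        for method in ("taylor", "closed_form"):
            derivs = gpp.higher_order_grads(linear_model, acts, 0, method=method)
            assert np.allclose(derivs.first, 1.0)
            assert np.allclose(derivs.second, 0.0)
            assert np.allclose(derivs.third, 0.0)
            assert derivs.method == method

    def test_square_model_hand_calculus(self, square_model):
        acts = np.ones((1, 2, 2))
        derivs = gpp.higher_order_grads(square_model, acts, 0, method="taylor")
        assert np.allclose(derivs.first, 8.0)  # 2 * sum(A)
        assert np.allclose(derivs.second, 2.0)
        assert np.allclose(derivs.third, 0.0)

    @pytest.mark.parametrize("score", ["linear", "exp"])
    def test_smooth_cnn_matches_finite_differences(self, score, rng):
        model = make_smooth_model(score=score)
        image = rng.uniform(0.0, 1.0, size=(3, 4, 4))
        acts = model.activations(image)
        derivs = gpp.higher_order_grads(model, acts, class_c=1, method="taylor")
        fd1, fd2, fd3 = fd_derivatives(lambda a: model.class_score(a, 1), acts)
        assert np.allclose(derivs.first, fd1, rtol=1e-3, atol=1e-6)
        assert np.allclose(derivs.second, fd2, rtol=1e-3, atol=1e-5)
        assert np.allclose(derivs.third, fd3, rtol=1e-3, atol=1e-4)

    def test_closed_form_matches_taylor_on_piecewise_linear_head(self, rng):
        model = gpp.build_color_cam_model(input_size=16, pool=2)
        image = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        acts = model.activations(gpp.prepare_model_input(model, image))
        closed = gpp.higher_order_grads(model, acts, gpp.MALIGNANT_CLASS, method="closed_form")
        taylor = gpp.higher_order_grads(model, acts, gpp.MALIGNANT_CLASS, method="taylor")
        assert np.allclose(closed.first, taylor.first, rtol=1e-10)
        assert np.allclose(closed.second, taylor.second, rtol=1e-10)
        assert np.allclose(closed.third, taylor.third, rtol=1e-10)

    def test_auto_method_selection(self, linear_model, rng):
        acts = rng.normal(size=(1, 2, 2))
        assert gpp.higher_order_grads(linear_model, acts, 0).method == "closed_form"
        smooth = make_smooth_model()
        smooth_acts = smooth.activations(rng.uniform(size=(3, 4, 4)))
        assert gpp.higher_order_grads(smooth, smooth_acts, 0).method == "taylor"

    def test_closed_form_rejects_smooth_head(self, rng):
        model = make_smooth_model()
        acts = model.activations(rng.uniform(size=(3, 4, 4)))
        with pytest.raises(ValueError, match="piecewise-linear"):
            gpp.higher_order_grads(model, acts, 0, method="closed_form")

    def test_invalid_class_index(self, linear_model, rng):
        with pytest.raises(ValueError, match="class index"):
            gpp.higher_order_grads(linear_model, rng.normal(size=(1, 2, 2)), 5)


# ---------------------------------------------------------------------------
# alpha coefficients and channel weights
# ---------------------------------------------------------------------------


def stack(first, second, third):
    return gpp.DerivativeStack(
        first=np.asarray(first, dtype=float),
        second=np.asarray(second, dtype=float),
        third=np.asarray(third, dtype=float),
        method="taylor",
    )


class TestAlpha:
    def test_zero_third_derivative_gives_half(self):
        derivs = stack(np.ones((1, 2, 2)), np.ones((1, 2, 2)), np.zeros((1, 2, 2)))
        alpha = gpp.alpha_coefficients(derivs, np.ones((1, 2, 2)))
        assert np.allclose(alpha, 0.5)

    def test_zero_over_zero_guard(self):
        zeros = np.zeros((1, 2, 2))
        alpha = gpp.alpha_coefficients(stack(zeros, zeros, zeros), np.ones((1, 2, 2)))
        assert np.allclose(alpha, 0.0)

    def test_hand_evaluation(self):
        # sum(A) = 2, d2 = d3 = 1 -> alpha = 1 / (2 + 2) = 0.25
        acts = np.array([[[1.0, 1.0]]])
        derivs = stack(np.ones((1, 1, 2)), np.ones((1, 1, 2)), np.ones((1, 1, 2)))
        assert np.allclose(gpp.alpha_coefficients(derivs, acts), 0.25)

    def test_shape_mismatch(self):
        derivs = stack(np.ones((1, 2, 2)), np.ones((1, 2, 2)), np.ones((1, 2, 2)))
        with pytest.raises(ValueError):
            gpp.alpha_coefficients(derivs, np.ones((2, 2, 2)))


class TestChannelWeights:
    def test_all_negative_gradients_rectified_to_zero(self, rng):
        alpha = rng.uniform(size=(2, 3, 3))
        grads = -rng.uniform(0.1, 1.0, size=(2, 3, 3))
        assert np.allclose(gpp.channel_weights(alpha, grads), 0.0)

    def test_uniform_alpha_reduces_to_gradcam(self, rng):
        grads = rng.uniform(0.1, 1.0, size=(3, 4, 4))  # all positive
        z = 16
        weights = gpp.channel_weights(np.full_like(grads, 1 / z), grads)
        assert np.allclose(weights, gpp.gradcam_channel_weights(grads), rtol=1e-12)

    def test_gradcam_reduction_exact_without_rectifier(self, rng):
        grads = rng.normal(size=(4, 5, 5))  # mixed signs
        z = 25
        weights = gpp.channel_weights(np.full_like(grads, 1 / z), grads, rectify=False)
        assert np.allclose(weights, gpp.gradcam_channel_weights(grads), rtol=1e-12)

    def test_hand_sum(self):
        alpha = np.array([[[0.25, 0.25]]])
        grads = np.array([[[2.0, -1.0]]])
        assert np.allclose(gpp.channel_weights(alpha, grads), 0.5)


# ---------------------------------------------------------------------------
# regional importance maps
# ---------------------------------------------------------------------------


def brute_force_map(model, image, class_c):
    """Step-by-step composition with loops and finite-difference derivatives."""
    acts = model.activations(gpp.prepare_model_input(model, image))
    fd1, fd2, fd3 = fd_derivatives(lambda a: model.class_score(a, class_c), acts)
    k_channels, h, w = acts.shape
    weights = np.zeros(k_channels)
    for k in range(k_channels):
        sum_a = acts[k].sum()
        for i in range(h):
            for j in range(w):
                denom = 2.0 * fd2[k, i, j] + sum_a * fd3[k, i, j]
                alpha = fd2[k, i, j] / denom if abs(denom) > 1e-9 else 0.0
                weights[k] += alpha * max(fd1[k, i, j], 0.0)
    raw = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            raw[i, j] = max(sum(weights[k] * acts[k, i, j] for k in range(k_channels)), 0.0)
    if raw.max() - raw.min() < 1e-12:
        return np.zeros((h, w))
    return (raw - raw.min()) / (raw.max() - raw.min())


class TestRegionalImportance:
    def test_all_zero_weights_flagged(self):
        mix = gpp.ChannelMix(np.full((1, 3), 1 / 3))
        model = gpp.CamModel(
            feature_layers=[mix, gpp.ReLU()],
            head_layers=[gpp.SpatialMean(), gpp.Linear(np.array([[-1.0]]))],
            score="exp",
        )
        image = np.random.default_rng(0).integers(0, 255, (8, 8, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="flat"):
            imap = gpp.regional_importance(model, image, class_c=0)
        assert imap.all_zero
        assert np.all(imap.values == 0.0)

    def test_single_positive_channel_is_normalized_activation(self, rng):
        mix = gpp.ChannelMix(np.full((1, 3), 1 / 3))
        model = gpp.CamModel(
            feature_layers=[mix, gpp.ReLU()],
            head_layers=[gpp.SpatialMean(), gpp.Linear(np.array([[2.0]]))],
            score="exp",
        )
        image = rng.integers(10, 255, (8, 8, 3), dtype=np.uint8)
        acts = model.activations(gpp.prepare_model_input(model, image))[0]
        imap = gpp.regional_importance(model, image, class_c=0, out_shape=acts.shape)
        expected = (acts - acts.min()) / (acts.max() - acts.min())
        assert np.allclose(imap.values, expected, atol=1e-9)

    def test_matches_brute_force_composition(self, rng):
        model = make_smooth_model(score="exp", seed=9)
        image = rng.integers(0, 255, (4, 4, 3), dtype=np.uint8)
        imap = gpp.regional_importance(model, image, class_c=1, out_shape=(4, 4))
        oracle = brute_force_map(model, image, class_c=1)
        assert np.allclose(imap.values, oracle, atol=1e-3)

    def test_values_in_unit_interval(self, rng, malignant_slide):
        model = gpp.build_color_cam_model(input_size=64, pool=4)
        imap = gpp.regional_importance(model, malignant_slide.slide.pixels)
        assert imap.values.min() >= 0.0
        assert imap.values.max() <= 1.0
        assert imap.values.shape == malignant_slide.slide.pixels.shape[:2]

    def test_scale_covariance(self, rng):
        acts = np.abs(rng.normal(size=(3, 5, 5)))
        weights = rng.normal(size=3)
        base = gpp.cam_from_weights(weights, acts)
        scaled = gpp.cam_from_weights(weights / 7.5, acts * 7.5)
        norm = lambda m: m / m.max() if m.max() > 0 else m
        assert np.allclose(norm(base), norm(scaled))

    def test_malignant_class_highlights_focus(self, malignant_slide):
        model = gpp.build_color_cam_model(input_size=128, pool=4)
        imap = gpp.regional_importance(
            model, malignant_slide.slide.pixels, class_c=gpp.MALIGNANT_CLASS
        )
        mask = malignant_slide.truth.mask
        inside = imap.values[mask == 2].mean()
        outside = imap.values[mask == 1].mean()
        assert inside > outside + 0.3

    def test_save_roundtrip(self, tmp_path, rng):
        values = rng.uniform(size=(16, 16))
        values = (values - values.min()) / (values.max() - values.min())
        imap = gpp.ImportanceMap(values=values, class_c=1, method="taylor")
        path = gpp.save_importance_map(imap, tmp_path / "map.png")
        from PIL import Image

        loaded = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
        assert np.allclose(loaded, values, atol=1.0 / 65535)
        assert (tmp_path / "map.json").exists()


def test_importance_map_rejects_out_of_range():
    with pytest.raises(ValueError):
        gpp.ImportanceMap(values=np.array([[1.5]]), class_c=0)
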