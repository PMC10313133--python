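"""Grad-CAM++ regional importance maps on small differentiable CNNs.

The class score ``Y_c`` is differentiated with respect to the activation maps
``A^k`` of a chosen layer.  Pixel-wise coefficients

    alpha^k_l = d2 / (2 * d2 + (sum_b A^k_b) * d3)         (0/0 guarded to 0)

combine with rectified first gradients into channel weights

    w_k = sum_l alpha^k_l * ReLU(dY/dA^k_l)

and the importance map is ``ReLU(sum_k w_k A^k)``, upsampled to the slide and
min-max normalized to [0, 1].

Higher-order derivatives come from one of two routes, recorded in the output:

* ``taylor`` — truncated univariate Taylor propagation through the head, one
  perturbation direction per activation element.  Exact (to float precision)
  for smooth layers; works for any head built from the layers below.
* ``closed_form`` — for a piecewise-linear head with an exponential score
  ``Y = exp(S)``, the n-th derivative reduces to ``Y * g^n`` with
  ``g = dS/dA`` from a single backward pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Layer",
    "ChannelMix",
    "Conv2d",
    "Linear",
    "ReLU",
    "Tanh",
    "Square",
    "Exp",
    "SpatialMean",
    "GlobalSum",
    "AvgPool",
    "CamModel",
    "ActivationStack",
    "DerivativeStack",
    "ImportanceMap",
    "higher_order_grads",
    "alpha_coefficients",
    "channel_weights",
    "gradcam_channel_weights",
    "cam_from_weights",
    "regional_importance",
    "build_color_cam_model",
    "save_importance_map",
    "MALIGNANT_CLASS",
    "BENIGN_CLASS",
]

_DENOM_EPS = 1e-12


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """A network layer supporting forward, backward (vjp) and Taylor modes.

    ``linear_part`` applies the bias-free linear action and must accept
    arbitrary leading (batch) axes in front of the core shape; elementwise
    layers override ``taylor`` instead.
    """

    #: True when the layer is linear or piecewise linear (ReLU, pooling, ...).
    piecewise_linear = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no linear part")

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} is not backward-differentiable")

    def taylor(self, coeffs: np.ndarray) -> np.ndarray:
        """Propagate degree-3 Taylor coefficients, shape (4, *lead, *core)."""
        out0 = self.forward(coeffs[0])
        rest = [self.linear_part(c) for c in coeffs[1:]]
        return np.stack([out0, *rest])


class ChannelMix(Layer):
    """1x1 convolution: per-pixel linear mix of channels, (K_in,H,W)->(K_out,H,W)."""

    piecewise_linear = True

    def __init__(self, weight: np.ndarray, bias: np.ndarray | None = None) -> None:
        self.weight = np.asarray(weight, dtype=np.float64)
        self.bias = (
            np.zeros(self.weight.shape[0]) if bias is None else np.asarray(bias, dtype=np.float64)
        )

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        return np.einsum("ok,...khw->...ohw", self.weight, x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.linear_part(x) + self.bias[:, None, None]

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        return np.einsum("ok,...ohw->...khw", self.weight, g)


class Conv2d(Layer):
    """Same-padding 2-D convolution with odd kernels, (K_in,H,W)->(K_out,H,W)."""

    piecewise_linear = True

    def __init__(self, weight: np.ndarray, bias: np.ndarray | None = None) -> None:
        self.weight = np.asarray(weight, dtype=np.float64)  # (K_out, K_in, kh, kw)
        if self.weight.shape[2] % 2 == 0 or self.weight.shape[3] % 2 == 0:
            raise ValueError("Conv2d requires odd kernel sizes for same padding")
        self.bias = (
            np.zeros(self.weight.shape[0]) if bias is None else np.asarray(bias, dtype=np.float64)
        )

    def _conv_core(self, x: np.ndarray) -> np.ndarray:
        from scipy.signal import correlate2d

        k_out = self.weight.shape[0]
        out = np.zeros((k_out,) + x.shape[1:])
        for o in range(k_out):
            for k in range(x.shape[0]):
                out[o] += correlate2d(x[k], self.weight[o, k], mode="same")
        return out

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        lead = x.shape[:-3]
        flat = x.reshape((-1,) + x.shape[-3:])
        out = np.stack([self._conv_core(sample) for sample in flat])
        return out.reshape(lead + out.shape[1:])

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.linear_part(x) + self.bias[:, None, None]

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        from scipy.signal import convolve2d

        k_in = self.weight.shape[1]
        out = np.zeros((k_in,) + g.shape[1:])
        for k in range(k_in):
            for o in range(g.shape[0]):
                out[k] += convolve2d(g[o], self.weight[o, k], mode="same")
        return out


class Linear(Layer):
    """Dense layer on channel vectors, (C_in,) -> (C_out,)."""

    piecewise_linear = True

    def __init__(self, weight: np.ndarray, bias: np.ndarray | None = None) -> None:
        self.weight = np.asarray(weight, dtype=np.float64)
        self.bias = (
            np.zeros(self.weight.shape[0]) if bias is None else np.asarray(bias, dtype=np.float64)
        )

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        return np.einsum("ck,...k->...c", self.weight, x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.linear_part(x) + self.bias

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        return np.einsum("ck,...c->...k", self.weight, g)


class SpatialMean(Layer):
    """Global average pooling, (K,H,W) -> (K,)."""

    piecewise_linear = True

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(-2, -1))

    forward = linear_part

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        h, w = x.shape[-2:]
        return np.broadcast_to(g[..., None, None], x.shape) / (h * w)


class GlobalSum(Layer):
    """Sum over all elements, (K,H,W) -> (1,)."""

    piecewise_linear = True

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        return x.sum(axis=(-3, -2, -1))[..., None]

    forward = linear_part

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        return np.broadcast_to(g[..., None, None], x.shape).copy()


class AvgPool(Layer):
    """Non-overlapping block averaging by an integer factor."""

    piecewise_linear = True

    def __init__(self, factor: int) -> None:
        self.factor = int(factor)

    def linear_part(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        *lead, k, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {f}")
        return x.reshape(*lead, k, h // f, f, w // f, f).mean(axis=(-3, -1))

    forward = linear_part

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        f = self.factor
        return np.repeat(np.repeat(g, f, axis=-2), f, axis=-1) / (f * f)


class Elementwise(Layer):
    """Elementwise nonlinearity with derivatives to third order.

    Taylor propagation follows Faa di Bruno truncated at degree 3:
    ``c1' = f' a1``, ``c2' = f' a2 + f'' a1^2 / 2``,
    ``c3' = f' a3 + f'' a1 a2 + f''' a1^3 / 6``.
    """

    def derivs(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.derivs(x)[0]

    def vjp(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        return g * self.derivs(x)[1]

    def taylor(self, coeffs: np.ndarray) -> np.ndarray:
        a0, a1, a2, a3 = coeffs
        f0, f1, f2, f3 = self.derivs(a0)
        return np.stack(
            [
                f0,
                f1 * a1,
                f1 * a2 + 0.5 * f2 * a1**2,
                f1 * a3 + f2 * a1 * a2 + f3 * a1**3 / 6.0,
            ]
        )


class ReLU(Elementwise):
    piecewise_linear = True

    def derivs(self, x):
        mask = (x > 0).astype(np.float64)
        return np.maximum(x, 0.0), mask, np.zeros_like(x), np.zeros_like(x)


class Tanh(Elementwise):
    def derivs(self, x):
        t = np.tanh(x)
        sech2 = 1.0 - t**2
        return t, sech2, -2.0 * t * sech2, sech2 * (6.0 * t**2 - 2.0)


class Square(Elementwise):
    def derivs(self, x):
        return x**2, 2.0 * x, np.full_like(x, 2.0), np.zeros_like(x)


class Exp(Elementwise):
    def derivs(self, x):
        e = np.exp(x)
        return e, e, e, e


def _exp_series(s: np.ndarray) -> np.ndarray:
    """Compose exp with a degree-3 Taylor series (leading axis = degree)."""
    s0, s1, s2, s3 = s
    e = np.exp(s0)
    return np.stack([e, e * s1, e * (s2 + 0.5 * s1**2), e * (s3 + s1 * s2 + s1**3 / 6.0)])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class CamModel:
    """A CNN split at the CAM target layer.

    ``feature_layers`` map the input image (3,H,W in [0,1]) to the activation
    stack ``A`` at the target layer; ``head_layers`` map ``A`` to the vector
    of pre-softmax class scores ``S``.  ``score="exp"`` differentiates
    ``Y = exp(S_c)`` (the usual choice that makes higher-order terms
    informative for piecewise-linear heads); ``score="linear"`` uses ``S_c``.
    """

    feature_layers: list
    head_layers: list
    score: str = "linear"
    input_size: int | None = None
    layer_tag: str = "final"

    def __post_init__(self) -> None:
        if self.score not in ("linear", "exp"):
            raise ValueError(f"score must be 'linear' or 'exp', got {self.score!r}")

    @property
    def head_is_piecewise_linear(self) -> bool:
        return all(layer.piecewise_linear for layer in self.head_layers)

    def activations(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64)
        for layer in self.feature_layers:
            x = layer.forward(x)
        return x

    def head(self, acts: np.ndarray) -> np.ndarray:
        x = np.asarray(acts, dtype=np.float64)
        for layer in self.head_layers:
            x = layer.forward(x)
        return x

    def class_score(self, acts: np.ndarray, class_c: int) -> float:
        s = float(self.head(acts)[class_c])
        return float(np.exp(s)) if self.score == "exp" else s


@dataclass
class ActivationStack:
    """Per-channel activation maps at the CAM target layer."""

    maps: np.ndarray  # (K, H, W)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("activation stack must be (K, H, W)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("activation stack contains non-finite values")


@dataclass
class DerivativeStack:
    """First, second and third derivatives of Y_c w.r.t. each activation."""

    first: np.ndarray
    second: np.ndarray
    third: np.ndarray
    method: str  # "taylor" | "closed_form"

    def __post_init__(self) -> None:
        if not (self.first.shape == self.second.shape == self.third.shape):
            raise ValueError("derivative orders must share one shape")


@dataclass
class ImportanceMap:
    """Normalized per-pixel relevance in [0, 1] over a slide."""

    values: np.ndarray
    class_c: int
    layer_tag: str = "final"
    method: str = "taylor"
    all_zero: bool = False
    raw_min: float = 0.0
    raw_max: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("importance values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------


def _head_forward_cached(model: CamModel, acts: np.ndarray) -> list[np.ndarray]:
    xs = [np.asarray(acts, dtype=np.float64)]
    for layer in model.head_layers:
        xs.append(layer.forward(xs[-1]))
    return xs

def _head_backward(model: CamModel, acts: np.ndarray, class_c: int) -> tuple[np.ndarray, np.ndarray]:
    """One-hot backward pass through the head: returns (dS_c/dA, scores S)."""
    xs = _head_forward_cached(model, acts)
    scores = xs[-1]
    g = np.zeros_like(scores)
    g[class_c] = 1.0
    for layer, x in zip(reversed(model.head_layers), reversed(xs[:-1])):
        try:
            g = layer.vjp(x, g)
        except NotImplementedError as exc:
            raise ValueError(
                f"layer {type(layer).__name__} in the head is not backward-differentiable"
            ) from exc
    return g, scores


def _taylor_head(model: CamModel, coeffs: np.ndarray) -> np.ndarray:
    for layer in model.head_layers:
        try:
            coeffs = layer.taylor(coeffs)
        except NotImplementedError as exc:
            raise ValueError(
                f"layer {type(layer).__name__} in the head does not support Taylor mode"
            ) from exc
    return coeffs


def higher_order_grads(
    model: CamModel,
    acts: np.ndarray,
    class_c: int,
    method: str = "auto",
    chunk: int = 1024,
) -> DerivativeStack:
    """Derivatives of the class score w.r.t. each target-layer activation.

    ``method="closed_form"`` requires a piecewise-linear head (then the
    exponential-score derivatives are powers of the single backward gradient);
    ``method="taylor"`` perturbs each activation element along a Taylor series
    and is exact for the smooth layers shipped here.  ``"auto"`` picks the
    closed form whenever it applies.
    """
    acts = np.asarray(acts, dtype=np.float64)
    scores = model.head(acts)
    if not 0 <= class_c < scores.shape[-1]:
        raise ValueError(f"class index {class_c} out of range for {scores.shape[-1]} classes")

    if method == "auto":
        method = "closed_form" if model.head_is_piecewise_linear else "taylor"
    if method == "closed_form":
        if not model.head_is_piecewise_linear:
            raise ValueError("closed_form derivatives require a piecewise-linear head")
        g, scores = _head_backward(model, acts, class_c)
        if model.score == "exp":
            y = np.exp(scores[class_c])
            first, second, third = y * g, y * g**2, y * g**3
        else:
            first, second, third = g, np.zeros_like(g), np.zeros_like(g)
        return DerivativeStack(first=first, second=second, third=third, method="closed_form")
    if method != "taylor":
        raise ValueError(f"unknown method {method!r}")

    n = acts.size
    first = np.zeros(n)
    second = np.zeros(n)
    third = np.zeros(n)
    flat = acts.reshape(-1)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        b = len(idx)
        coeffs = np.zeros((4, b) + acts.shape)
        coeffs[0] = acts  # broadcast base point
        directions = np.zeros((b, n))
        directions[np.arange(b), idx] = 1.0
        coeffs[1] = directions.reshape((b,) + acts.shape)
        out = _taylor_head(model, coeffs)  # (4, b, C)
        series = out[:, :, class_c]
        if model.score == "exp":
            series = _exp_series(series)
        first[idx] = series[1]
        second[idx] = 2.0 * series[2]
        third[idx] = 6.0 * series[3]
        del coeffs
    shape = acts.shape
    return DerivativeStack(
        first=first.reshape(shape),
        second=second.reshape(shape),
        third=third.reshape(shape),
        method="taylor",
    )


# ---------------------------------------------------------------------------
# Grad-CAM++ combination
# ---------------------------------------------------------------------------


def alpha_coefficients(derivs: DerivativeStack, acts: np.ndarray) -> np.ndarray:
    """Pixel-wise coefficients alpha = d2 / (2 d2 + (sum_b A_b) d3), per channel.

    The channel-wise activation sum multiplies the third derivative at each
    pixel; a vanishing denominator (including the 0/0 case) yields alpha = 0.
    """
    acts = np.asarray(acts, dtype=np.float64)
    if acts.shape != derivs.second.shape:
        raise ValueError("activations and derivatives must share one shape")
    sum_a = acts.sum(axis=(-2, -1), keepdims=True)
    denom = 2.0 * derivs.second + sum_a * derivs.third
    return np.where(np.abs(denom) > _DENOM_EPS, derivs.second / np.where(denom == 0, 1, denom), 0.0)


def channel_weights(alpha: np.ndarray, first_grads: np.ndarray, rectify: bool = True) -> np.ndarray:
    """Per-channel weights w_k = sum_l alpha_l * ReLU(dY/dA_l).

    ``rectify=False`` drops the rectifier (used by the plain Grad-CAM
    reduction check); default keeps it.
    """
    grads = np.maximum(first_grads, 0.0) if rectify else np.asarray(first_grads, dtype=np.float64)
    if alpha.shape != grads.shape:
        raise ValueError("alpha and gradients must share one shape")
    return np.sum(alpha * grads, axis=(-2, -1))


def gradcam_channel_weights(first_grads: np.ndarray) -> np.ndarray:
    """Plain Grad-CAM weights: global-average-pooled first gradients."""
    return np.mean(first_grads, axis=(-2, -1))


def cam_from_weights(weights: np.ndarray, acts: np.ndarray) -> np.ndarray:
    """Rectified weighted sum of activation maps: ReLU(sum_k w_k A^k)."""
    return np.maximum(np.einsum("k,khw->hw", weights, acts), 0.0)


def _upsample(values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    if values.shape == tuple(out_shape):
        return values
    image = Image.fromarray(values.astype(np.float32), mode="F")
    return np.asarray(image.resize((out_shape[1], out_shape[0]), Image.BILINEAR), dtype=np.float64)


def prepare_model_input(model: CamModel, slide_pixels: np.ndarray) -> np.ndarray:
    """Resize an RGB slide to the model input size and scale to [0,1] CHW."""
    pixels = np.asarray(slide_pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"slide must be HxWx3 RGB, got shape {pixels.shape}")
    if model.input_size is not None and (
        pixels.shape[0] != model.input_size or pixels.shape[1] != model.input_size
    ):
        image = Image.fromarray(pixels.astype(np.uint8), mode="RGB")
        pixels = np.asarray(image.resize((model.input_size, model.input_size), Image.BILINEAR))
    return pixels.astype(np.float64).transpose(2, 0, 1) / 255.0


def regional_importance(
    model: CamModel,
    slide_pixels: np.ndarray,
    class_c: int | None = None,
    method: str = "auto",
    out_shape: tuple[int, int] | None = None,
) -> ImportanceMap:
    """Slide-level importance map: ReLU(sum_k w_k A^k), upsampled + normalized.

    When ``class_c`` is None the model's top-scoring class is explained.  The
    raw map is bilinearly upsampled to ``out_shape`` (default: the slide's own
    dimensions) and min-max normalized to [0, 1]; a flat map comes back
    all-zero with ``all_zero=True`` and a warning instead of dividing by zero.
    """
    x = prepare_model_input(model, slide_pixels)
    acts = model.activations(x)
    if class_c is None:
        class_c = int(np.argmax(model.head(acts)))
    derivs = higher_order_grads(model, acts, class_c, method=method)
    alpha = alpha_coefficients(derivs, acts)
    weights = channel_weights(alpha, derivs.first)
    raw = cam_from_weights(weights, acts)

    out_shape = out_shape or (slide_pixels.shape[0], slide_pixels.shape[1])
    upsampled = _upsample(raw, out_shape)
    upsampled = np.maximum(upsampled, 0.0)  # bilinear can undershoot at edges
    lo, hi = float(upsampled.min()), float(upsampled.max())
    if hi - lo <= _DENOM_EPS:
        warnings.warn("importance map is flat; returning all-zero map", stacklevel=2)
        return ImportanceMap(
            values=np.zeros(out_shape),
            class_c=class_c,
            layer_tag=model.layer_tag,
            method=derivs.method,
            all_zero=True,
            raw_min=lo,
            raw_max=hi,
        )
    return ImportanceMap(
        values=(upsampled - lo) / (hi - lo),
        class_c=class_c,
        layer_tag=model.layer_tag,
        method=derivs.method,
        all_zero=False,
        raw_min=lo,
        raw_max=hi,
    )


# ---------------------------------------------------------------------------
# Default slide-explanation model
# ---------------------------------------------------------------------------

BENIGN_CLASS = 0
MALIGNANT_CLASS = 1


def build_color_cam_model(input_size: int = 256, pool: int = 4) -> CamModel:
    """Fixed-weight color-opponent CNN for phantom slide explanation.

    Three ReLU detector channels on unit-scaled RGB — green excess (benign),
    red excess (pink) and red+green minus blue (yellow) — pooled and combined
    into two class scores (benign, malignant).  The head is piecewise linear,
    so the exponential-score closed form applies.
    """
    if input_size % pool:
        raise ValueError("input_size must be divisible by pool")
    mix = ChannelMix(
        weight=np.array(
            [
                [-1.0, 1.0, 0.0],  # benign: G - R
                [1.0, -1.0, 0.0],  # pink:   R - G
                [1.0, 1.0, -2.0],  # yellow: R + G - 2B - 0.8
            ]
        ),
        bias=np.array([0.0, 0.0, -0.8]),
    )
    head_linear = Linear(weight=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]]))
    return CamModel(
        feature_layers=[AvgPool(pool), mix, ReLU()],
        head_layers=[SpatialMean(), head_linear],
        score="exp",
        input_size=input_size,
        layer_tag="color-opponent",
    )


def save_importance_map(imap: ImportanceMap, path: str | Path) -> Path:
    """Write a map as 16-bit grayscale PNG plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scaled = np.round(imap.values * 65535.0).astype(np.uint16)
    Image.fromarray(scaled).save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "class": int(imap.class_c),
                "layer": imap.layer_tag,
                "method": imap.method,
                "all_zero": bool(imap.all_zero),
                "raw_min": imap.raw_min,
                "raw_max": imap.raw_max,
            },
            indent=2,
        )
    )
    return path
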