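import numpy as np
import pytest

from duvmargin import phantom, tiling


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def benign_slide():
    """Small benign phantom slide (800 x 800, one green ellipse)."""
    spec = phantom.PhantomSpec(
        height=800,
        width=800,
        regions=(
            phantom.Region(center=(400, 400), radii=(320, 320), tissue_class="benign"),
        ),
        seed=7,
    )
    return phantom.generate_slide(spec, slide_id="ben", patient_id="PB", label=-1)


@pytest.fixture
def malignant_slide():
    """Small malignant phantom slide: benign ellipse with a pink focus."""
    spec = phantom.PhantomSpec(
        height=800,
        width=800,
        regions=(
            phantom.Region(center=(400, 400), radii=(360, 360), tissue_class="benign"),
            phantom.Region(center=(200, 200), radii=(180, 180), tissue_class="malignant"),
        ),
        seed=11,
    )
    return phantom.generate_slide(spec, slide_id="mal", patient_id="PM", label=1)


def make_slide(pixels, label=-1, slide_id="s", patient_id="p"):
    return tiling.SlideRecord(
        slide_id=slide_id, patient_id=patient_id, pixels=pixels, label=label
    )


@pytest.fixture
def separable_features(rng):
    """Linearly separable 2-D features, 100 per class, labels in {+1, -1}."""
    pos = rng.normal(loc=(3.0, 3.0), scale=0.5, size=(100, 2))
    neg = rng.normal(loc=(-3.0, -3.0), scale=0.5, size=(100, 2))
    features = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(100, dtype=int), -np.ones(100, dtype=int)])
    return features, labels
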