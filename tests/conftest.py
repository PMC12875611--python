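import numpy as np
import pytest

from limbsym import (
    DEFAULT_PALETTE,
    LabelImage,
    SectionSpec,
    StainModel,
    generate_label_section,
    render_staining,
)


@pytest.fixture(scope="session")
def palette():
    return DEFAULT_PALETTE


@pytest.fixture(scope="session")
def symmetric_section():
    """A 256 px mirror-symmetric ground-truth section (asymmetry 0)."""
    return generate_label_section(
        SectionSpec(height_px=256, width_px=256, asymmetry=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def clean_render(symmetric_section):
    """Noise-free palette-exact render of the symmetric section."""
    return render_staining(
        symmetric_section,
        StainModel(noise_sd=0.0, multiplier_range=(1.0, 1.0)),
        seed=0,
        multiplier=1.0,
    )


@pytest.fixture()
def stripes():
    """Five vertical constant-color stripes: every column's feature profile is
    translation-invariant along rows, so sparse scribbles separate exactly."""
    labels = np.zeros((40, 100), np.uint8)
    for i, c in enumerate((1, 2, 3, 4, 5)):
        labels[:, i * 20 : (i + 1) * 20] = c
    return LabelImage(labels, DEFAULT_PALETTE, 4.0)
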