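import numpy as np
import pytest

from mbdeform import synthetic as syn


@pytest.fixture(scope="session")
def small_pcfg() -> syn.PhantomConfig:
    """A desk-sized phantom: 1.5 mm isotropic, brain semi-axes ~45 mm."""
    return syn.PhantomConfig(
        grid_shape=(72, 72, 66),
        spacing_mm=(1.5, 1.5, 1.5),
        brain_semi_axes_mm=(45.0, 48.0, 42.0),
        tissue_intensity_levels=(70.0, 110.0, 85.0),
    )


@pytest.fixture(scope="session")
def small_subject(small_pcfg):
    """Deformed subject with ground truth on the small phantom."""
    atlas, brain = syn.generate_atlas(small_pcfg)
    dcfg = syn.DeformationSimConfig(
        tumor_center_mm=(0.0, 4.0, -6.0),
        tumor_radius_mm=8.0,
        amplitude_A0_mm=3.0,
        heterogeneity_h=0.5,
        angular_harmonic=2,
    )
    subject, tumor, field = syn.generate_subject(atlas, brain, dcfg, small_pcfg)
    return {
        "pcfg": small_pcfg,
        "dcfg": dcfg,
        "atlas": atlas,
        "brain": brain,
        "subject": subject,
        "tumor": tumor,
        "field": field,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
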