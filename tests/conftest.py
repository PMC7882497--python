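import numpy as np
import pytest

from hydromorph import imaging, phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default head phantom shared across tests (generation is the
    expensive step)."""
    spec = phantom.PhantomSpec(frontal_sas_thickness_mm=5.0, ihf_width_mm=3.0)
    intensity, labels, truth = phantom.make_head_phantom(spec)
    return spec, intensity, labels, truth


@pytest.fixture(scope="session")
def default_masks(default_phantom):
    """CSF / total-head masks derived from the default phantom's labels."""
    _, _, labels, _ = default_phantom
    csf = imaging.VoxelVolume(
        np.isin(labels.values, phantom.CSF_LIKE_LABELS).astype(np.uint8),
        labels.spacing_mm,
    )
    total = imaging.VoxelVolume(
        ((labels.values > 0) & ~np.isin(labels.values, (6, 7, 8, 9))).astype(np.uint8),
        labels.spacing_mm,
    )
    return csf, total
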