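import numpy as np
import pytest

from hemoshear.core import HemodynamicRecord
from hemoshear.synthetic import ImageSpec, generate_endothelium_image

#: printed group-mean hemodynamic inputs (sex, phase) -> (D mm, Vmax mm/s)
GROUP_MEANS = {
    ("male", "diastole"): (0.387, 157.0),
    ("male", "systole"): (0.484, 999.0),
    ("female", "diastole"): (0.376, 167.0),
    ("female", "systole"): (0.466, 1015.0),
}
ETA_B = {"male": 4.1, "female": 3.9}
ETA_P = {"male": 1.26, "female": 1.27}
HEMATOCRIT = 0.43


def mean_record(sex: str, phase: str) -> HemodynamicRecord:
    d, v = GROUP_MEANS[(sex, phase)]
    return HemodynamicRecord(
        animal_id=f"{sex}-{phase}",
        sex=sex,
        phase=phase,
        diameter_mm=d,
        vmax_mm_s=v,
        hematocrit=HEMATOCRIT,
    )


@pytest.fixture(scope="session")
def fast_image_spec() -> ImageSpec:
    """A 240 µm field at 234 nm pixels: large enough to pack 50 cells with
    unambiguous pairing, small enough for fast tests."""
    return ImageSpec(
        image_size_px=1024,
        pixel_size_um=0.234,
        n_cells=50,
        class_fractions=(0.2, 0.2, 0.6),
    )


@pytest.fixture(scope="session")
def synthetic_field(fast_image_spec):
    """One generated (image, ground truth) pair shared across tests."""
    return generate_endothelium_image(fast_image_spec, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
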