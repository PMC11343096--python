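import numpy as np
import pytest
from PIL import Image

from ommatidia.detection import detect_ommatidia
from ommatidia.synthetic import LatticeSpec, generate_centers, render


@pytest.fixture(scope="session")
def default_lattice():
    """Clean default lattice: (spec, truth centers, rendered image)."""
    spec = LatticeSpec(seed=0)
    return spec, generate_centers(spec), render(spec)


@pytest.fixture(scope="session")
def default_detections(default_lattice):
    _, _, image = default_lattice
    return detect_ommatidia(image)


@pytest.fixture
def write_png(tmp_path):
    """Write a uint8/uint16 array as PNG and return its path."""
    def _write(arr, name="img.png"):
        path = tmp_path / name
        arr = np.asarray(arr)
        mode = "I;16" if arr.dtype == np.uint16 else None
        Image.fromarray(arr, mode=mode).save(path)
        return path
    return _write


def detections_to_array(detections):
    return np.array([[d.cx, d.cy] for d in detections], dtype=float)
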