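import numpy as np
import pytest

from epiquant import CellRegion, LayerSegmentation


@pytest.fixture
def rect_layer():
    """Flat rectangular layer: 100 rows x 120 cols, basal boundary at row 0."""
    h, w = 100, 120
    mask = np.ones((h, w), dtype=bool)
    basal = np.array([[0.0, 0.0], [w - 1.0, 0.0]])
    apical = np.array([[0.0, h - 1.0], [w - 1.0, h - 1.0]])
    return LayerSegmentation(mask=mask, basal_boundary=basal, apical_boundary=apical)


@pytest.fixture
def disk_cell():
    """Disk cell of radius 30 in a 81x81 frame."""
    n, c, r = 81, 40, 30
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.hypot(yy - c, xx - c) <= r
    return CellRegion(mask=mask, label="disk"), (c, r)
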