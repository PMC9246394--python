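import numpy as np
import pytest

from lnspatial.core import CellMap, CellRecord, FrameMeta, Mode


@pytest.fixture
def hr_frame() -> FrameMeta:
    return FrameMeta(1024, 1024, 0.1058, Mode.HR_ROI)


@pytest.fixture
def hmp_frame() -> FrameMeta:
    return FrameMeta(512, 512, 0.221, Mode.HMP_SECTION)


def disc_mask(x: float, y: float, r: int) -> np.ndarray:
    """Pixel coordinates of a disc, clipped to nonnegative coordinates."""
    xs = np.arange(int(x) - r, int(x) + r + 1)
    ys = np.arange(int(y) - r, int(y) + r + 1)
    gx, gy = np.meshgrid(xs, ys)
    keep = (gx - x) ** 2 + (gy - y) ** 2 <= r**2
    pts = np.column_stack([gx[keep], gy[keep]])
    return pts[(pts[:, 0] >= 0) & (pts[:, 1] >= 0)]


def make_map(frame: FrameMeta, spec: list[tuple], **kwargs) -> CellMap:
    """Build a CellMap from (x, y, base_class[, markers[, conf[, mask_r]]]) tuples."""
    cells = []
    for i, entry in enumerate(spec):
        x, y, cls = entry[0], entry[1], entry[2]
        markers = frozenset(entry[3]) if len(entry) > 3 else frozenset()
        conf = entry[4] if len(entry) > 4 else 1.0
        mask = disc_mask(x, y, entry[5]) if len(entry) > 5 else None
        cells.append(
            CellRecord(cell_id=i, x=x, y=y, base_class=cls, markers=markers, confidence=conf, mask=mask)
        )
    return CellMap(frame=frame, cells=cells, **kwargs)
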