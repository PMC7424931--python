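import math

import numpy as np
import pytest

from conemosaic.io import ConePoints, ROIMeta


@pytest.fixture
def roi():
    """A 100×100 µm ROI with typical optics metadata."""
    return ROIMeta(
        subject_id="S01",
        roi_id="S01_R01",
        width_um=100.0,
        height_um=100.0,
        scale_um_per_px=0.45,
        axial_length_mm=24.0,
        eccentricity_um=500.0,
    )


def make_points(roi, coords, annotator="A"):
    return ConePoints(roi=roi, annotator=annotator, coords=np.asarray(coords, float))


@pytest.fixture
def make_cone_points(roi):
    def _make(coords, annotator="A", roi_=None):
        return make_points(roi_ or roi, coords, annotator)

    return _make


def square_lattice(spacing, x0, x1, y0, y1):
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    return np.array([(x, y) for y in ys for x in xs])


def hex_lattice(spacing, width, height, margin=0.0):
    """Hexagonal lattice covering [−margin, width+margin] × same in y."""
    row_h = spacing * math.sqrt(3.0) / 2.0
    pts = []
    y = -margin
    r = 0
    while y <= height + margin:
        shift = spacing / 2.0 if r % 2 else 0.0
        x = -margin + shift
        while x <= width + margin:
            pts.append((x, y))
            x += spacing
        y += row_h
        r += 1
    return np.array(pts)


def random_mosaic(rng, n, width, height, min_sep=0.0):
    """n points uniform in the box, optionally with a minimum separation
    (dart throwing)."""
    pts = []
    attempts = 0
    while len(pts) < n and attempts < 200 * n:
        cand = rng.uniform([0, 0], [width, height])
        attempts += 1
        if min_sep and pts:
            d = np.min(np.hypot(*(np.asarray(pts) - cand).T))
            if d < min_sep:
                continue
        pts.append(cand)
    return np.asarray(pts)
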