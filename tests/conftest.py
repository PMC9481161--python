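import numpy as np
import pytest

from polarquant.tracking import Track


def make_rod_scene(length=30, width=8, origin=(10, 10), shape=(50, 60)):
    """A single horizontal rod (rectangle with semicircular caps) label image."""
    labels = np.zeros(shape, dtype=np.uint16)
    r = width / 2.0
    r0, c0 = origin
    yy, xx = np.mgrid[0:width, 0:length] + 0.5
    xc = np.clip(xx, r, length - r)
    mask = np.hypot(yy - width / 2.0, xx - xc) <= r + 1e-9
    labels[r0:r0 + width, c0:c0 + length][mask] = 1
    return labels, mask


def checkerboard_fluor(labels, low=90.0, high=110.0, background=0.0):
    """Fluorescence with a two-level checkerboard inside cells: the cell mean
    is ~(low+high)/2 and the pixel standard deviation ~(high-low)/2, giving
    controlled cytoplasmic statistics without randomness."""
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    fluor = np.full(labels.shape, background, dtype=float)
    inside = labels > 0
    fluor[inside] = np.where((rr + cc)[inside] % 2 == 0, low, high)
    return fluor


def make_track(xs, track_id=0, y=0.0, half_axis=15.0, f_a=None, f_b=None,
               interval_s=30.0):
    """Track of a cell moving along the column axis at positions ``xs``;
    pole a sits at x - half_axis, pole b at x + half_axis."""
    xs = np.asarray(xs, dtype=float)
    n = len(xs)
    centroids = np.column_stack([np.full(n, y), xs])
    pole_a = centroids + [0.0, -half_axis]
    pole_b = centroids + [0.0, half_axis]
    return Track(track_id=track_id, frames=np.arange(n), centroids=centroids,
                 pole_a=pole_a, pole_b=pole_b,
                 f_pole_a=np.zeros(n) if f_a is None else np.asarray(f_a, float),
                 f_pole_b=np.zeros(n) if f_b is None else np.asarray(f_b, float),
                 frame_interval_s=interval_s)


@pytest.fixture
def rod_scene():
    return make_rod_scene()
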