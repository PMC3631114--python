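import math

import numpy as np
import pytest

import bonepore as bp


@pytest.fixture
def disk_image():
    """A single digitized disk (r = 30 px) on a clean bright background."""
    spec = bp.SyntheticImageSpec(
        width_px=128, height_px=128, n_objects=1,
        axis_length_range_px=(30, 30), axis_ratio_range=(1, 1), seed=0,
    )
    return bp.generate_pore_image(spec)


def match_objects(truth, objects, max_dist_px=5.0):
    """Pair ground-truth objects with measured ones by nearest centroid."""
    pairs = []
    for t in truth:
        best = min(
            objects,
            key=lambda o: (o.centroid[0] - t.centroid_px[0]) ** 2
            + (o.centroid[1] - t.centroid_px[1]) ** 2,
            default=None,
        )
        if best is not None and math.hypot(
            best.centroid[0] - t.centroid_px[0], best.centroid[1] - t.centroid_px[1]
        ) <= max_dist_px:
            pairs.append((t, best))
    return pairs


@pytest.fixture
def recovery_image_spec():
    """Study-scale recovery conditions: a 512 px field of >= 30 well-resolved
    pores under 2% salt-and-pepper noise and a 20% illumination gradient."""
    def _make(seed):
        return bp.SyntheticImageSpec(
            width_px=512, height_px=512, n_objects=30,
            axis_length_range_px=(18, 32), axis_ratio_range=(1, 1.4),
            roughness_amplitude=0.0, illumination_gradient_amplitude=0.2,
            noise_fraction=0.02, seed=seed,
        )
    return _make
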