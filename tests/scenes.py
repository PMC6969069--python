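"""Hand-built noiseless scenes used as geometric oracles across tests."""

import numpy as np
import pandas as pd

from cinquant.imaging import CELL_COLUMNS, ImagingConfig
from cinquant.synthgen import SceneObject, render_scene

PS = 0.5  # um/pixel; integer-pixel centroids for exact border distances
CONFIG = ImagingConfig(pixel_size=PS)
IMAGE_PX = 300  # 150 x 150 um


def nucleus_with_spot(
    nucleus_d=30.0,
    spot_d=None,
    spot_intensity=20000.0,
    nucleus_intensity=30000.0,
    gap=1.5,
    image_px=IMAGE_PX,
    seed=0,
):
    """One centred nucleus, optionally one adjacent spot inside its cell body."""
    c = (image_px - 1) * PS / 2.0
    objs = [SceneObject(c, c, nucleus_d, nucleus_intensity)]
    if spot_d is not None:
        objs.append(
            SceneObject(
                c + nucleus_d / 2.0 + gap + spot_d / 2.0,
                c,
                spot_d,
                spot_intensity,
                kind="micronucleus",
                owner_id=1,
            )
        )
    return render_scene(
        objs,
        (image_px, image_px),
        PS,
        background=(3000.0, 0.0),
        blur_sigma_px=0.0,
        seed=seed,
    )


def nucleus_at_edge_distance(dist_um, nucleus_d=15.0, image_px=IMAGE_PX):
    """Single nucleus whose centroid sits on an exact pixel at ``dist_um``
    from the left image edge (vertically centred)."""
    assert (dist_um / PS) == int(dist_um / PS)
    cy = (image_px - 1) * PS / 2.0
    objs = [SceneObject(dist_um, cy, nucleus_d, 30000.0)]
    return render_scene(
        objs, (image_px, image_px), PS, background=(3000.0, 0.0), blur_sigma_px=0.0
    )


def fake_cells(n_retained, n_excluded=0):
    """A cell table with the given number of retained / excluded nuclei."""
    n = n_retained + n_excluded
    df = pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "area_um2": np.full(n, 150.0),
            "eq_diameter_um": np.full(n, 13.8),
            "mean_intensity": np.full(n, 30000.0),
            "cx_um": np.full(n, 100.0),
            "cy_um": np.full(n, 100.0),
            "border_excluded": np.zeros(n, bool),
            "intensity_excluded": np.arange(n) >= n_retained,
            "size_excluded": np.zeros(n, bool),
        },
        columns=CELL_COLUMNS,
    )
    return df
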