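import numpy as np
import pytest

import deciquant as dq


@pytest.fixture(scope="session")
def small_phantom():
    """Confluent-cluster phantom small enough for per-test pipelines."""
    return dq.generate_phantom(
        canvas_size=(512, 512),
        n_clusters=2,
        cells_per_cluster=6,
        n_singles=4,
        cluster_radius=50.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def discrete_phantom():
    """Discrete-cluster phantom: cells never touch, counting has exact truth."""
    return dq.generate_phantom(
        canvas_size=(512, 512),
        n_clusters=2,
        cells_per_cluster=6,
        n_singles=4,
        cluster_radius=50.0,
        cluster_style="discrete",
        seed=7,
    )


def blank_phantom(canvas=(64, 96), markers=("CK7",)):
    """A phantom with no tissue at all (white slide)."""
    h, w = canvas
    return dq.SlidePhantom(
        canvas_size=(h, w),
        pixel_size=0.5,
        trophoblast_cells=np.empty((0, 4)),
        stroma_field=np.zeros((h, w)),
        exclusion_regions=[],
        marker_strengths={m: (0.8, 0.1) for m in markers},
        section_offsets={m: (0, 0) for m in markers},
        seed=0,
    )


def scan_from_array(image, pixel_size=0.5, marker="NRF2"):
    from deciquant.stitching import SlideScan

    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=2)
    return SlideScan(image=image.astype(np.uint8), pixel_size=pixel_size, marker=marker)
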