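import numpy as np
import pytest

from atriumkit.plane_geometry import PlaneGeometry, SegmentationMask


def axis_aligned_geometry(spacing=1.0, origin=(0.0, 0.0, 0.0)):
    """Plane in the z=const patient plane: columns along x, rows along y."""
    return PlaneGeometry(
        origin_mm=origin,
        row_cosine=(1.0, 0.0, 0.0),
        col_cosine=(0.0, 1.0, 0.0),
        spacing_mm=(spacing, spacing),
    )


def mask_from_array(arr, spacing=1.0):
    return SegmentationMask(np.asarray(arr, np.uint8), axis_aligned_geometry(spacing))


@pytest.fixture
def geom():
    return axis_aligned_geometry()


@pytest.fixture(scope="session")
def sphere_phantom():
    """Static 30-mm sphere sliced by the default view plan (shared)."""
    from atriumkit.synthetic_data import PhantomSpec, make_phantom

    spec = PhantomSpec(shape="sphere", semi_axes_mm=(30.0, 30.0, 30.0), n_frames=1)
    views, truth = make_phantom(spec)
    return spec, views, truth


@pytest.fixture(scope="session")
def lead_snp_fixture():
    from atriumkit.loci_overlap import load_lead_snp_fixture

    return load_lead_snp_fixture()
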