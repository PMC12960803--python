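import numpy as np
import pandas as pd
import pytest

from lcfusion.raster import CategoricalRaster, GridSpec
from lcfusion.sampling import ValidationSample


def make_grid(nrows, ncols, cell=10.0, origin=(0.0, None), crs="test"):
    origin_y = origin[1] if origin[1] is not None else nrows * cell
    return GridSpec(
        origin_x=origin[0], origin_y=origin_y, dx=cell, dy=cell,
        nrows=nrows, ncols=ncols, crs=crs,
    )


def make_map(values, cell=10.0, nodata=0, domain=None, crs="test"):
    values = np.asarray(values, dtype=np.int32)
    if domain is None:
        domain = frozenset(int(v) for v in np.unique(values) if v != nodata)
    return CategoricalRaster(
        values=values,
        grid=make_grid(*values.shape, cell=cell, crs=crs),
        nodata=nodata,
        class_domain=domain,
    )


def sample_from_arrays(x, y, stratum, final_label, domain=()):
    df = pd.DataFrame({"x": x, "y": y, "stratum": stratum, "final_label": final_label})
    return ValidationSample(points=df, class_domain=frozenset(domain))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
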