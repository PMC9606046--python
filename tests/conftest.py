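"""Shared fixtures: scanner geometry, kernels, phantoms."""

import numpy as np
import pytest

from petmu.phantom import (PhantomSpec, Shape, body_phantom_spec,
                           build_phantom, default_tissue_table)
from petmu.scanner import ScannerModel, TofKernel

VOXEL_MM = 1.65


@pytest.fixture(scope="session")
def scanner64():
    return ScannerModel.for_grid((64, 64), VOXEL_MM)


@pytest.fixture(scope="session")
def kernel64(scanner64):
    return TofKernel.for_scanner(scanner64)


@pytest.fixture(scope="session")
def table():
    return default_tissue_table()


@pytest.fixture(scope="session")
def disk_phantom(table):
    """Two-compartment phantom: soft-tissue ellipse with a bone insert."""
    spec = PhantomSpec((64, 64), [
        Shape("ellipse", (31.5, 31.5), (24, 28), "soft_tissue"),
        Shape("ellipse", (40.0, 31.5), (6, 6), "bone"),
    ], voxel_size_mm=VOXEL_MM)
    return build_phantom(spec, table)


@pytest.fixture(scope="session")
def body_phantom(table):
    return build_phantom(body_phantom_spec((64, 64), seed=3), table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def uniform_disk(value=0.1, radius_vox=25.0, shape=(64, 64)):
    yy, xx = np.meshgrid(*(np.arange(n) - (n - 1) / 2 for n in shape),
                         indexing="ij")
    return np.where(yy ** 2 + xx ** 2 <= radius_vox ** 2, value, 0.0)
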