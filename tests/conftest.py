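import numpy as np
import pytest

from parconc import Parcellation, SyntheticFamilySpec, VoxelGrid, make_family


def line_parcellation(name: str, labels_1d, area_prefix: str) -> Parcellation:
    """A 1-voxel-thick line volume: the simplest hand-checkable fixture."""
    arr = np.asarray(labels_1d, dtype=np.int32).reshape(-1, 1, 1)
    grid = VoxelGrid(shape=arr.shape, affine=np.eye(4))
    names = {int(l): f"{area_prefix}{l}" for l in np.unique(arr) if l > 0}
    return Parcellation(name=name, grid=grid, labels=arr, area_names=names)


@pytest.fixture
def line_pair():
    """Six collinear voxels: A = [1,1,1,2,2,2], B = [1,1,2,2,3,3].

    Hand enumeration: joint counts n11=2, n12=1, n22=1, n23=2; voxel pairs
    co-located in both = 1+0+0+1 = 2; co-located in A = 2*C(3,2) = 6; in
    B = 3*C(2,2... C(2,2)=1 each) = 3.  Hence W_A->B = 2/6 = 1/3 and
    W_B->A = 2/3, cross-checked by the brute-force route in the tests.
    """
    A = line_parcellation("A", [1, 1, 1, 2, 2, 2], "a")
    B = line_parcellation("B", [1, 1, 2, 2, 3, 3], "b")
    return A, B


@pytest.fixture(scope="session")
def demo_family():
    """Default demo family: 16^3 ellipsoid, 6 base areas, 2 splitters,
    2 lumpers, boundary noise 0.05."""
    return make_family(SyntheticFamilySpec(seed=20260923))


@pytest.fixture(scope="session")
def clean_family():
    """Same family layout with boundary noise 0 (exact nesting holds)."""
    return make_family(SyntheticFamilySpec(seed=20260923, boundary_noise=0.0))
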