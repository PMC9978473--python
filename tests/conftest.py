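import numpy as np
import pytest

import levelpost as lp

SPACING = (1.14, 1.14, 3.0)


@pytest.fixture(scope="session")
def taxonomy():
    return lp.load_taxonomy()


@pytest.fixture(scope="session")
def phantom_gt(taxonomy):
    return lp.generate_ground_truth(lp.PhantomSpec(seed=0), taxonomy)


def make_label_volume(arr, spacing=SPACING):
    """Small label volume helper with the default CT-like spacing."""
    return lp.LabelVolume(np.asarray(arr, dtype=np.int16), spacing)


def boundary_voxels_bruteforce(mask):
    """Independent boundary extraction: mask voxels with a 6-neighbour
    outside the mask (array border counts as outside)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)
    for i, j, k in idx:
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1] and 0 <= nk < mask.shape[2]):
                out[i, j, k] = True
                break
            if not mask[ni, nj, nk]:
                out[i, j, k] = True
                break
    return out


def pairwise_surface_distances(surf_a, surf_b, spacing):
    """All nearest-neighbour distances from surface A voxel centers to
    surface B voxel centers, by exhaustive pairwise computation."""
    pa = np.argwhere(surf_a) * np.asarray(spacing)
    pb = np.argwhere(surf_b) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)
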