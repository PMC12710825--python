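import numpy as np
import pytest

import remo


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world: 20 modules x 4 CREs, 8 cell types, 50 cells."""
    return remo.generate_world(
        n_celltypes=8, n_modules=20, cres_per_module=4, n_cells=50,
        mean_frags_per_cell=300.0, noise_sd=0.05, seed=3,
    )


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions: 200 modules x 4 CREs, 10 cell types, noise 0.05."""
    return remo.generate_world(seed=7)


def brute_force_matrix(fragments, regions, barcodes, mode, grouped=False):
    """Quadratic every-fragment-vs-every-region counting oracle."""
    if grouped:
        features = sorted({iv.group for iv in regions})
        feat_of = {i: features.index(iv.group) for i, iv in enumerate(regions)}
    else:
        features = list(range(len(regions)))
        feat_of = {i: i for i in range(len(regions))}
    out = np.zeros((len(features), len(barcodes)), dtype=np.int64)
    bc = {b: i for i, b in enumerate(barcodes)}
    for rec in fragments:
        if rec.barcode not in bc:
            continue
        j = bc[rec.barcode]
        for ri, iv in enumerate(regions):
            if iv.chrom != rec.chrom:
                continue
            in_left = iv.start <= rec.start < iv.end
            in_right = iv.start <= rec.end - 1 < iv.end
            if mode == "insertion":
                out[feat_of[ri], j] += rec.count * (int(in_left) + int(in_right))
            elif in_left or in_right:
                out[feat_of[ri], j] += rec.count
    return out
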