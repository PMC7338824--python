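import numpy as np
import pandas as pd
import pytest

from radioprot import OmicsMatrix, PhantomSpec, SegmentedVolume, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_site_volume():
    """8x8x3 volume with two rectangular sites of distinct plain textures."""
    intens = np.zeros((8, 8, 3))
    mask = np.zeros((8, 8, 3), dtype=np.int32)
    mask[1:4, 1:7, :] = 1
    mask[5:8, 1:7, :] = 2
    rng = np.random.default_rng(3)
    intens[mask == 1] = 10 + 5 * rng.standard_normal((mask == 1).sum())
    intens[mask == 2] = 80 + 40 * rng.standard_normal((mask == 2).sum())
    return SegmentedVolume(intensities=intens, spacing=(1.0, 1.0, 5.0), mask=mask,
                           patient_id="fixture2")


@pytest.fixture
def small_phantom():
    return generate_phantom(PhantomSpec(n_sites=2, voxels_per_site=(60, 100),
                                        shape=(32, 32, 4), heterogeneity=0.8, seed=5))


@pytest.fixture
def omics_pair(rng):
    genes = [f"G{i}" for i in range(8)]
    patients = [f"P{i}" for i in range(12)]
    t = rng.standard_normal((8, 12))
    tx = OmicsMatrix(pd.DataFrame(t, index=genes, columns=patients), kind="transcript")
    prot = OmicsMatrix(pd.DataFrame(t + 0.1 * rng.standard_normal((8, 12)),
                                    index=genes, columns=patients), kind="protein")
    return tx, prot
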