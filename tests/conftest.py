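import numpy as np
import pytest

from centroscreen import synthetic as syn

PX = 0.108


@pytest.fixture(scope="session")
def px():
    return PX


@pytest.fixture(scope="session")
def disk_mask():
    """Plain disk nucleus (R_eq = 6 um) plus its ground truth."""
    params = syn.NucleusShapeParams(equivalent_radius_um=6.0)
    return syn.generate_nucleus_mask(params, PX, seed=101)


@pytest.fixture(scope="session")
def irregular_masks():
    """Ten nuclei of varied size, eccentricity and boundary roughness."""
    rng = np.random.default_rng(42)
    masks = []
    for i in range(10):
        params = syn.NucleusShapeParams(
            equivalent_radius_um=float(rng.uniform(4.5, 7.5)),
            eccentricity=float(rng.uniform(0.0, 0.6)),
            boundary_roughness=float(rng.uniform(0.0, 0.08)),
        )
        masks.append(syn.generate_nucleus_mask(params, PX, seed=7000 + i))
    return masks
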