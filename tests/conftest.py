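import numpy as np
import pytest

from histex import (
    ExpressionMatrix,
    PreprocessConfig,
    SimConfig,
    SlideImage,
    SpatialDataset,
    SpotGrid,
    preprocess_pair,
    simulate_pair,
)


@pytest.fixture(scope="session")
def small_pair():
    """One seeded synthetic two-section dataset, shared across tests."""
    return simulate_pair(SimConfig(seed=11, n_rows=8, n_cols=8, n_genes=20,
                                   spot_spacing_px=16))


@pytest.fixture(scope="session")
def small_processed(small_pair):
    """Preprocessed (patches, targets) train/test pairs from small_pair."""
    ds0, ds1, _, _ = small_pair
    pconfig = PreprocessConfig(patch_size=32, n_hvg=10, target_sum=1e4)
    return preprocess_pair(ds0, ds1, pconfig)


def make_dataset(n_spots=5, n_genes=4, seed=0, image_side=64):
    """Small hand-rolled SpatialDataset for I/O tests."""
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 256, size=(image_side, image_side, 3), dtype=np.uint8)
    coords = rng.uniform(5, image_side - 5, size=(n_spots, 2))
    spot_ids = [f"BC{i:03d}" for i in range(n_spots)]
    gene_ids = [f"g{j}" for j in range(n_genes)]
    counts = rng.poisson(5.0, size=(n_spots, n_genes)).astype(float)
    counts[:, 0] += 1  # guarantee nonzero totals
    return SpatialDataset(
        image=SlideImage(pixels=pixels),
        spots=SpotGrid(spot_ids=spot_ids, pixel_xy=coords,
                       array_rc=np.zeros((n_spots, 2), dtype=int),
                       in_tissue=np.ones(n_spots, dtype=bool)),
        expression=ExpressionMatrix(values=counts, spot_ids=spot_ids,
                                    gene_ids=gene_ids, layer="counts"),
        section_id="fixture",
    )
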