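import numpy as np
import pytest

import translatome_kit as tk


@pytest.fixture(scope="session")
def noiseless_config():
    """The exactly invertible world: no noise, identity distortions,
    fraction recovery constant across fractions and replicates."""
    return tk.SyntheticConfig(
        n_genes=200,
        seed=101,
        noise_cv=0.0,
        loss_sd=0.0,
        distortion_r_range=(1.0, 1.0),
        distortion_b_range=(0.0, 0.0),
        below_cutoff_frac=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_world(noiseless_config):
    truth = tk.generate_gene_truth(noiseless_config)
    series = tk.synthesize_arrays(truth, noiseless_config)
    return noiseless_config, truth, series


@pytest.fixture(scope="session")
def default_calibration():
    return tk.default_calibration(3)


def toy_series(intensities, empty_mean=100.0, empty_sd=20.0):
    """ArraySeries from a raw (genes, 8, reps) tensor with flat metadata."""
    intensities = np.asarray(intensities, dtype=float)
    g, _, k = intensities.shape
    return tk.ArraySeries(
        intensities=intensities,
        gene_ids=[f"g{i}" for i in range(g)],
        empty_stats=np.tile([empty_mean, empty_sd], (8, 1)),
        rna_quantity=np.full((8, k), 100.0),
    )
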