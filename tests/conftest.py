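import numpy as np
import pytest

from batchlens.io_formats import BatchDesign, ExpressionMatrix
from batchlens.synthetic_data import FactorSpec, SpeciesSpec, SyntheticConfig, generate


def make_matrix(rng, n_probes, sample_ids, mean=8.0, noise_sd=0.35):
    """Homogeneous (no batch structure) log2 matrix."""
    values = mean + rng.normal(0.0, noise_sd, size=(n_probes, len(sample_ids)))
    return ExpressionMatrix([f"p{i:05d}" for i in range(n_probes)], list(sample_ids), values)


def equal_batches(n_batches, batch_size, prefix="b"):
    """BatchDesign with equal batches over consecutively numbered samples."""
    assignment = {}
    for k in range(n_batches):
        for i in range(batch_size):
            assignment[f"s{k * batch_size + i:03d}"] = f"{prefix}{k}"
    return BatchDesign("Experiment", assignment)


@pytest.fixture(scope="session")
def two_species_dataset():
    """Moderate two-species dataset shared by cross-species tests."""
    config = SyntheticConfig(
        seed=101,
        species_a=SpeciesSpec("PPR", n_genes=1500,
                              factors=(FactorSpec("Experiment", (8,) * 5),)),
        species_b=SpeciesSpec("DRE", n_genes=1200,
                              factors=(FactorSpec("Experiment", (8,) * 5),)),
    )
    return generate(config)
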