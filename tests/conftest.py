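import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coseed import Compendium, Dataset, ModuleSpec, SimParams, simulate_compendium

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(dataset_id: str, data: dict[str, list[float]]) -> Dataset:
    """Build a dataset from {gene: values}; samples named s0..s(n-1)."""
    n = len(next(iter(data.values())))
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=[f"{dataset_id}_s{i}" for i in range(n)])
    return Dataset(dataset_id=dataset_id, expr=df.astype(float))


@pytest.fixture
def tiny_compendium() -> Compendium:
    """Three small hand-built datasets over genes gA..gE."""
    rng = np.random.default_rng(42)
    genes = ["gA", "gB", "gC", "gD", "gE"]
    datasets = []
    for d in range(3):
        base = rng.standard_normal(8)
        data = {
            "gA": base + 0.01 * rng.standard_normal(8),
            "gB": base + 0.01 * rng.standard_normal(8),
            "gC": -base + 0.01 * rng.standard_normal(8),
            "gD": rng.standard_normal(8),
            "gE": rng.standard_normal(8),
        }
        datasets.append(make_dataset(f"d{d}", {g: list(data[g]) for g in genes}))
    return Compendium(datasets=datasets)


@pytest.fixture
def noise_free_module():
    """One 10-gene planted module at vanishing noise: within-module r -> 1."""
    params = SimParams(
        n_datasets=3,
        samples_per_dataset=30,
        n_genes=30,
        module_specs=(ModuleSpec("m1", 10, 1.0, 0.0),),
        noise_sd=1e-9,
        seed_overlap_fraction=0.5,
        dropout_fraction=0.0,
        rng_seed=11,
    )
    return simulate_compendium(params)
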