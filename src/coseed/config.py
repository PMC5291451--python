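"""Pipeline configuration: analysis parameters plus input/output paths.

Defaults follow the reference analysis: correlation threshold 0.5, a
23,000-gene genome for by-chance expectations, 1,000 permutation walks,
above-chance alpha 1e-4, EASE alpha 0.05 and partner thresholds 1/2/5/10.
The full configuration is hashed and echoed into every output header for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # analysis parameters
    r_threshold: float = 0.5
    min_shared_datasets: int = 3
    min_presence_fraction: float = 0.25
    genome_size: int = 23000
    B_permutations: int = 1000
    alpha_chance: float = 1e-4
    alpha_ease: float = 0.05
    partner_thresholds: list[int] = field(default_factory=lambda: [1, 2, 5, 10])
    rng_seed: int = 0
    # simulation (used unless skip_simulate)
    skip_simulate: bool = False
    sim_n_datasets: int = 10
    sim_samples_per_dataset: int = 30
    sim_n_genes: int = 2000
    sim_module_size: int = 100
    sim_loading_mean: float = 1.0
    sim_loading_sd: float = 0.1
    sim_noise_sd: float = 0.2
    sim_seed_overlap_fraction: float = 0.5
    sim_dropout_fraction: float = 0.1
    sim_ppi_p_within: float = 0.5
    sim_ppi_p_between: float = 0.01
    sim_responsive_fraction_module: float = 0.8
    sim_responsive_fraction_background: float = 0.05
    sim_term_module_fraction: float = 0.8
    sim_term_background_fraction: float = 0.02
    # inputs (ignored when simulating: the simulator writes them)
    compendium_dir: str = "compendium"
    seeds_gmt: str = "gene_sets.gmt"
    seeds_set_name: str = "seeds"
    ppi_tsv: str = "ppi.tsv"
    responsive_set_name: str = "responsive"
    module_list: str = "disease_module.txt"
    pathway_gmt: str = "pathways.gmt"
    required_terms: list[str] = field(default_factory=lambda: ["term1"])
    # outputs
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
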