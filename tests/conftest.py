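"""Shared fixtures: seeded synthetic datasets with planted ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stagewire.synthetic import (
    CONDITIONS,
    PlantedModule,
    SimulationConfig,
    generate_stage_dataset,
)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    return np.log2(counts / counts.sum(axis=0) * 1e6 + 1)


def planted_config(
    seed: int,
    n_per_condition: int = 60,
    rewired_stage: str = "I",
    n_modules: int = 4,
    module_size: int = 50,
    n_genes: int = 300,
    rho_base: float = 0.85,
    rho_rewired: float = 0.0,
) -> SimulationConfig:
    """Blocks co-expressed at ``rho_base`` everywhere except ``rewired_stage``."""
    modules = []
    for k in range(n_modules):
        genes = tuple(f"M{k + 1}_{i:03d}" for i in range(module_size))
        rho = {c: rho_base for c in CONDITIONS}
        rho[rewired_stage] = rho_rewired
        modules.append(PlantedModule(genes, rho))
    return SimulationConfig(
        n_genes=n_genes,
        n_samples_per_condition={c: n_per_condition for c in CONDITIONS},
        modules=modules,
        survival=None,
        seed=seed,
    )


def planted_partition(config: SimulationConfig, genes) -> pd.Series:
    """Ground-truth labels (module index, 0 = background) over ``genes``."""
    truth = pd.Series(0, index=genes)
    for k, mod in enumerate(config.modules, start=1):
        present = [g for g in mod.gene_ids if g in truth.index]
        truth[present] = k
    return truth


@pytest.fixture(scope="session")
def rewired_dataset():
    """One seeded dataset with four blocks all re-wired in stage I."""
    cfg = planted_config(seed=0)
    counts, design, truth = generate_stage_dataset(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "design": design,
        "truth": truth,
        "expr": log_cpm(counts),
    }
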