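"""Shared fixtures: small deterministic cohorts and reference scenes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigdriver.simulate import PlantedHotspot, SimulationConfig, simulate_cohort

# desk-scale study conditions used across tests: 300 tumors, 300 kb genome,
# moderate per-tumor loads, 4 sparse synthetic signatures, 3 entities
DESK_SCALE = dict(
    n_tumors=300,
    genome_length=300_000,
    n_signatures=4,
    load_log_mu=float(np.log(300.0)),
    load_log_sigma=0.5,
    load_max=3000,
)


def desk_config(seed: int, **overrides) -> SimulationConfig:
    params = dict(DESK_SCALE)
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def planted_cohort():
    """One cohort with a +3 residual-SD hotspot on SIG-2 (30/300 carriers)."""
    cfg = desk_config(
        seed=11,
        hotspots=(PlantedHotspot(signature="SIG-2", effect_size=3.0, carrier_fraction=0.1),),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def profiles_300():
    """Covariate table for region-level association tests."""
    rng = np.random.default_rng(42)
    n = 300
    return pd.DataFrame(
        {
            "tumor_id": [f"t{i:03d}" for i in range(n)],
            "entity": rng.choice(["ENT-A", "ENT-B", "ENT-C"], n),
            "sex": rng.choice(["female", "male"], n),
            "total_load": rng.integers(50, 3000, n),
        }
    )


@pytest.fixture()
def tiny_genome():
    """A fixed 41 bp single-contig reference for context classification."""
    #            0         1         2         3         4
    #            0123456789012345678901234567890123456789
    return {"chr1": "ACGTACATGACATGGTACGTTGCATGCAAGCTTGACGTACA"}
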