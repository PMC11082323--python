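import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ssgblup.genio import qc_snps
from ssgblup.model import ModelSpec, build_design
from ssgblup.relmat import build_relationships
from ssgblup.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A desk-scale two-breed dataset shared across test modules."""
    cfg = SimConfig(n_animals_per_breed=60, n_generations=3, n_snps=400,
                    n_chromosomes=2, h2=(0.30, 0.25), genetic_correlation=0.5,
                    seed=7)
    ped, gm, snp_map, pt, truth = simulate_dataset(cfg)
    gm_qc, map_qc, _ = qc_snps(gm, snp_map)
    return {"config": cfg, "pedigree": ped, "genotypes_raw": gm, "snp_map_raw": snp_map,
            "genotypes": gm_qc, "snp_map": map_qc, "phenotypes": pt, "truth": truth}


@pytest.fixture(scope="session")
def small_relationships(small_dataset):
    gm = small_dataset["genotypes"]
    return build_relationships(small_dataset["pedigree"], gm.dosages,
                               list(gm.animal_ids), blend_weight=0.05)


@pytest.fixture(scope="session")
def small_design(small_dataset, small_relationships):
    spec = ModelSpec(traits=("trait_brown", "trait_holstein"))
    return build_design(small_dataset["phenotypes"], spec, small_relationships.ids)
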