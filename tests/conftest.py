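import numpy as np
import pandas as pd
import pytest

import picrisk as pk

#: Synthetic stand-in for the dated 8-taxon host-plant tree: the topology and
#: the two Fagaceae ages (Quercus pair at 17 my, the Fagus/Quercus split at
#: 34 my) follow the published description; the remaining node ages are
#: invented but plausible (the real supplementary tree is not distributed).
HOST_TREE_NEWICK = (
    "(Hamamelis_virginiana:110,(Acer_rubrum:105,(Prunus_serotina:95,"
    "(((Quercus_rubra:17,Quercus_alba:17):17,Fagus_grandifolia:34):46,"
    "(Betula_lenta:65,Carya_spp:65):15):15):10):5);"
)


@pytest.fixture
def host_tree() -> pk.Phylogeny:
    return pk.parse_tree(HOST_TREE_NEWICK, tree_id="host")


@pytest.fixture
def cherry_plus_outgroup() -> pk.Phylogeny:
    return pk.parse_tree("((A:1,B:1):1,C:1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231994)


@pytest.fixture(scope="session")
def synthetic_study():
    """One deterministic synthetic study: tree pair, species table, truth."""
    cfg = pk.SimulationConfig(seed=42)
    rng = np.random.default_rng(cfg.seed)
    tree1 = pk.simulate_tree(cfg.n_species, cfg.tree_model, rng,
                             cfg.branch_lengths)
    tree1.tree_id = "tree1"
    tree2 = pk.alternative_topology(tree1, rng, cfg.branch_lengths)
    traits = pk.simulate_bm_traits(tree1, cfg.trait_cov, rng, cfg.trait_names)
    samples = pk.simulate_experiment(traits, cfg, rng)
    from picrisk.simulate import build_species_table
    table = build_species_table(traits, samples, rng)
    return {"config": cfg, "tree1": tree1, "tree2": tree2, "traits": traits,
            "samples": samples, "table": table}


def branch_samples_fixture() -> pd.DataFrame:
    """Tiny hand-checkable branch-sample table (two branches per arm)."""
    return pd.DataFrame([
        {"branch_id": "b1", "site": "s1", "block": 1, "year": 2011,
         "tree_species": "oak", "ant_treatment": "control",
         "bird_treatment": "access", "area_m2": 1.0, "spA": 2, "spB": 0},
        {"branch_id": "b2", "site": "s1", "block": 1, "year": 2012,
         "tree_species": "oak", "ant_treatment": "control",
         "bird_treatment": "access", "area_m2": 1.0, "spA": 2, "spB": 0},
        {"branch_id": "b3", "site": "s1", "block": 1, "year": 2011,
         "tree_species": "oak", "ant_treatment": "excluded",
         "bird_treatment": "access", "area_m2": 1.0, "spA": 1, "spB": 0},
        {"branch_id": "b4", "site": "s1", "block": 1, "year": 2012,
         "tree_species": "oak", "ant_treatment": "excluded",
         "bird_treatment": "access", "area_m2": 1.0, "spA": 1, "spB": 0},
    ])


@pytest.fixture
def branch_samples() -> pd.DataFrame:
    return branch_samples_fixture()
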