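import numpy as np
import pytest

from ngnn.featurize import SolventRegistry, build_sample
from ngnn.model import NGNNConfig, NGNNParameters


@pytest.fixture(scope="session")
def registry():
    return SolventRegistry.default()


@pytest.fixture(scope="session")
def ethanol_in_water(registry):
    return build_sample("CCO", "H2O", -0.77, registry=registry, sample_id="etoh")


@pytest.fixture(scope="session")
def benzene_in_water(registry):
    return build_sample("c1ccccc1", "H2O", 1.0, registry=registry, sample_id="bz")


def small_config(**overrides) -> NGNNConfig:
    """A low-width configuration for fast exact tests."""
    defaults = dict(
        d_inherent_embed=4,
        d_env_embed=4,
        d_solvent_embed=4,
        d_edge_embed=4,
        k_intra=2,
        k_inter=2,
        head_layers=(8, 1),
        set2set_steps=2,
    )
    defaults.update(overrides)
    return NGNNConfig(**defaults)


def zeroed_params(config: NGNNConfig, n_custom_flags: int = 0) -> NGNNParameters:
    params = NGNNParameters.initialize(config, n_custom_flags, seed=0)
    for t in params.tensors.values():
        t.data[:] = 0.0
    return params


def permute_sample(sample, rng: np.random.Generator):
    """Relabel the solute's atoms by a random permutation (tests bypass the
    parser's canonical ordering on purpose)."""
    import dataclasses

    g = sample.solute
    perm = rng.permutation(g.n_atoms)  # perm[old] = new index
    edges = perm[g.directed_edges] if len(g.directed_edges) else g.directed_edges
    inv = np.argsort(perm)
    solute = dataclasses.replace(
        g,
        symbols=tuple(g.symbols[i] for i in inv),
        inherent=g.inherent[inv],
        environment=g.environment[inv],
        directed_edges=edges,
        bond_features=g.bond_features,
    )
    return dataclasses.replace(sample, solute=solute), perm
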