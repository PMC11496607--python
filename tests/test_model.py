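"""Architecture tests: micro-cases, dense-oracle equivalence, invariances,
gradient flow."""

import subprocess
import sys

import numpy as np
import pytest

from conftest import permute_sample, small_config, zeroed_params
from ngnn._autodiff import Tensor
from ngnn.featurize import build_sample
from ngnn.model import (
    GraphBatch,
    ModelError,
    NGNNConfig,
    NGNNParameters,
    NodeStates,
    dissolve_edges,
    dissolve_nodes,
    embed_nodes,
    forward,
    inter_pass_e,
    inter_pass_q,
    intra_pass,
    load_checkpoint,
    parameter_shapes,
    predict,
    readout,
    save_checkpoint,
)

ORACLE_MOLECULES = ["C", "CC", "CCO", "CC(C)C", "C1CC1", "c1ccccc1", "CC#N", "ClCCl", "C1CCCC1"]


# --------------------------------------------------------------------------
# the dense O(n^2) reference: explicit loops over ordered atom pairs
# --------------------------------------------------------------------------
def leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def dense_gate(edge_inputs, params, stage):
    """Edge MLP recomputed with plain NumPy."""
    h = leaky(edge_inputs @ params[f"edge_mlp_{stage}_W0"].data + params[f"edge_mlp_{stage}_b0"].data)
    return h @ params[f"edge_mlp_{stage}_W1"].data + params[f"edge_mlp_{stage}_b1"].data


def dense_reference_pass(h0, graph, params, stage, gate_rows, k_rounds):
    """Loop over all ordered pairs with an explicit adjacency mask."""
    n = graph.n_atoms
    adj = np.zeros((n, n), dtype=bool)
    gate = {}
    for (i, j), row in zip(graph.directed_edges.tolist(), gate_rows):
        adj[i, j] = True
        gate[(i, j)] = row
    deg = adj.sum(axis=1)
    h = h0.copy()
    for r in range(k_rounds):
        theta = params.theta(stage, r).data
        new = np.zeros_like(h)
        for i in range(n):
            new[i] = theta.T @ h[i]
            if deg[i]:
                acc = np.zeros(h.shape[1])
                for j in range(n):
                    if adj[i, j]:
                        acc += h[j] * gate[(i, j)]
                new[i] += acc / deg[i]
        h = new
    return h


@pytest.mark.parametrize("stage", ["intra", "q", "e"])
def test_message_passing_matches_dense_oracle(stage, registry):
    """Each passing stage equals the explicit ordered-pair reference on all
    small molecules over 20 random parameter draws."""
    config = small_config()
    samples = [build_sample(s, "DMSO", 0.0, registry=registry) for s in ORACLE_MOLECULES]
    for draw in range(20):
        params = NGNNParameters.initialize(config, 0, seed=1000 + draw)
        for sample in samples:
            batch = GraphBatch.from_samples([sample])
            h0 = embed_nodes(batch, params)
            if stage == "intra":
                states, k = h0, config.k_intra
                result = intra_pass(h0, params).values.data
            elif stage == "q":
                states = dissolve_nodes(intra_pass(h0, params), batch, params)
                k = config.k_inter
                result = inter_pass_q(states, params).values.data
            else:
                states = intra_pass(h0, params)
                k = config.k_inter
                result = inter_pass_e(states, dissolve_edges(batch, params), params).values.data

            if batch.n_edges:
                act = params.config.activation_fn()
                ea = act(Tensor(batch.edge_raw) @ params["W4"]).data
                if stage == "e":
                    pol = act(Tensor(batch.solvent_pol) @ params["W5"]).data
                    edge_in = np.hstack([ea, pol[batch.edge_graph_id]])
                else:
                    edge_in = ea
                gate_rows = dense_gate(edge_in, params, stage)
            else:
                gate_rows = np.zeros((0, 1))
            expected = dense_reference_pass(
                states.values.data, sample.solute, params, stage, gate_rows, k
            )
            assert np.allclose(result, expected, rtol=1e-6, atol=1e-10), (draw, sample.sample_id)


# --------------------------------------------------------------------------
# micro-cases, stage by stage
# --------------------------------------------------------------------------
def test_embed_nodes_zero_maps_give_zero_states(ethanol_in_water):
    config = small_config(activation="relu")
    params = zeroed_params(config)
    h = embed_nodes(ethanol_in_water, params)
    assert h.values.shape == (3, config.node_dim)
    assert np.all(h.values.data == 0.0)


def test_embed_nodes_identity_map_reproduces_inherent_block(registry):
    sample = build_sample("C", "H2O", 0.0, registry=registry)
    config = small_config(d_inherent_embed=6, activation="identity")
    params = zeroed_params(config)
    params["W1"].data[:] = np.eye(6)
    h = embed_nodes(sample, params).values.data
    assert np.array_equal(h[0, :6], sample.solute.inherent[0])
    assert np.all(h[0, 6:] == 0.0)


def test_embed_nodes_rejects_marking_mismatch(registry):
    marked = build_sample("CCl", "H2O", 0.0, marking_rules=["hydrophobic_halogen"],
                          registry=registry)
    params = NGNNParameters.initialize(small_config(), n_custom_flags=0, seed=0)
    with pytest.raises(ModelError, match="marking"):
        embed_nodes(marked, params)


def test_intra_pass_isolated_atom_is_theta_power(registry):
    sample = build_sample("C", "H2O", 0.0, registry=registry)
    config = small_config(activation="identity", k_intra=3)
    params = NGNNParameters.initialize(config, 0, seed=5)
    h0 = embed_nodes(sample, params)
    out = intra_pass(h0, params).values.data
    expected = h0.values.data.copy()
    for r in range(3):
        expected = expected @ params.theta("intra", r).data
    assert np.allclose(out, expected, rtol=1e-12)


def test_intra_pass_two_atoms_unit_gate_mutual_addition(registry):
    sample = build_sample("CC", "H2O", 0.0, registry=registry)
    config = small_config(activation="identity", k_intra=1)
    params = zeroed_params(config)
    d = config.node_dim
    params["theta_intra_0"].data[:] = np.eye(d)
    params["edge_mlp_intra_b1"].data[:] = 1.0  # gate identically one
    rng = np.random.default_rng(2)
    h0 = NodeStates(Tensor(rng.normal(size=(2, d))), GraphBatch.from_samples([sample]), "intact")
    out = intra_pass(h0, params).values.data
    h = h0.values.data
    assert np.allclose(out[0], h[0] + h[1])
    assert np.allclose(out[1], h[1] + h[0])


def test_dissolve_nodes_broadcasts_one_solvent_tail(benzene_in_water):
    config = small_config()
    params = NGNNParameters.initialize(config, 0, seed=3)
    h = intra_pass(embed_nodes(benzene_in_water, params), params)
    hq = dissolve_nodes(h, benzene_in_water, params).values.data
    assert hq.shape == (6, config.q_dim)
    act = config.activation_fn()
    tail = act(Tensor(benzene_in_water.solvent_descriptors[None, :]) @ params["W3"]).data[0]
    for i in range(6):
        assert np.allclose(hq[i, config.node_dim :], tail, rtol=1e-12)

    params_zero = zeroed_params(config)
    params_zero["W1"].data[:] = 1.0
    hq0 = dissolve_nodes(
        intra_pass(embed_nodes(benzene_in_water, params_zero), params_zero),
        benzene_in_water,
        params_zero,
    ).values.data
    assert np.all(hq0[:, config.node_dim :] == 0.0)


def test_dissolve_edges_composition(registry):
    sample = build_sample("CCO", "DMSO", 0.0, registry=registry)
    config = small_config()
    params = NGNNParameters.initialize(config, 0, seed=4)
    e_c = dissolve_edges(sample, params).values.data
    assert e_c.shape == (4, 2 * config.d_edge_embed)
    act = config.activation_fn()
    batch = GraphBatch.from_samples([sample])
    ea = act(Tensor(batch.edge_raw) @ params["W4"]).data
    pol = act(Tensor(sample.solvent_polarity[None, :]) @ params["W5"]).data[0]
    for row in range(4):
        assert np.allclose(e_c[row], np.concatenate([ea[row], pol]), rtol=1e-12)
    # polarity half identical across edges; zero W5 zeroes it
    params["W5"].data[:] = 0.0
    e_c = dissolve_edges(sample, params).values.data
    assert np.all(e_c[:, config.d_edge_embed :] == 0.0)


def test_inter_pass_q_zero_rounds_is_identity(benzene_in_water):
    params = NGNNParameters.initialize(small_config(), 0, seed=6)
    h = dissolve_nodes(
        intra_pass(embed_nodes(benzene_in_water, params), params), benzene_in_water, params
    )
    out = inter_pass_q(h, params, k_rounds=0)
    assert np.array_equal(out.values.data, h.values.data)


def test_inter_pass_e_zero_gate_is_theta_only(registry):
    sample = build_sample("CC", "H2O", 0.0, registry=registry)
    config = small_config(activation="identity", k_inter=1)
    params = NGNNParameters.initialize(config, 0, seed=7)
    for name in ("edge_mlp_e_W0", "edge_mlp_e_b0", "edge_mlp_e_W1", "edge_mlp_e_b1"):
        params[name].data[:] = 0.0
    h = intra_pass(embed_nodes(sample, params), params)
    out = inter_pass_e(h, dissolve_edges(sample, params), params).values.data
    assert np.allclose(out, h.values.data @ params.theta("e", 0).data, rtol=1e-12)


def test_readout_sum_pool_and_dimension(registry):
    sample = build_sample("CCO", "H2O", 0.0, registry=registry)
    config = small_config(readout="sum")
    params = NGNNParameters.initialize(config, 0, seed=8)
    batch = GraphBatch.from_samples([sample])
    ones_q = NodeStates(Tensor(np.ones((3, 4))), batch, "dissolved_q")
    ones_e = NodeStates(Tensor(np.ones((3, 4))), batch, "dissolved_e")
    emb = readout(ones_q, ones_e, params)
    assert np.array_equal(emb.h_g.data, np.full((1, 8), 3.0))
    assert emb.h_g.shape[1] == emb.h_g1.shape[1] + emb.h_g2.shape[1]


def test_predict_linear_head_is_dot_product(registry):
    sample = build_sample("CCO", "H2O", 0.0, registry=registry)
    config = small_config(head_layers=(1,))
    params = NGNNParameters.initialize(config, 0, seed=9)
    from ngnn.model import forward_tensor

    batch = GraphBatch.from_samples([sample])
    h0 = embed_nodes(batch, params)
    hq = inter_pass_q(dissolve_nodes(intra_pass(h0, params), batch, params), params)
    he = inter_pass_e(intra_pass(h0, params), dissolve_edges(batch, params), params)
    emb = readout(hq, he, params)
    y = predict(emb, params).data
    w, b = params["head_W0"].data, params["head_b0"].data
    assert y[0, 0] == pytest.approx(float(emb.h_g.data[0] @ w[:, 0] + b[0]), rel=1e-12)


def test_forward_zero_weights_yield_head_bias(ethanol_in_water):
    config = small_config()
    params = zeroed_params(config)
    params["head_b1"].data[:] = 2.5
    assert forward(ethanol_in_water, params) == pytest.approx(2.5)


# --------------------------------------------------------------------------
# invariants
# --------------------------------------------------------------------------
@pytest.mark.parametrize("readout_kind", ["set2set", "sum"])
def test_forward_invariant_to_atom_relabeling(registry, readout_kind):
    rng = np.random.default_rng(123)
    config = small_config(readout=readout_kind)
    params = NGNNParameters.initialize(config, 0, seed=10)
    for smiles in ("CCO", "c1ccncc1", "CC(C)CO", "ClC(Cl)Cl"):
        sample = build_sample(smiles, "MeCN", 0.0, registry=registry)
        y = forward(sample, params)
        for _ in range(3):
            shuffled, _ = permute_sample(sample, rng)
            y_perm = forward(shuffled, params)
            assert y_perm == pytest.approx(y, rel=1e-9)


def test_dimensional_bookkeeping_random_configs(registry):
    sample = build_sample("CCO", "H2O", 0.0, registry=registry)
    rng = np.random.default_rng(99)
    for _ in range(10):
        config = NGNNConfig(
            d_inherent_embed=int(rng.integers(1, 9)),
            d_env_embed=int(rng.integers(1, 9)),
            d_solvent_embed=int(rng.integers(1, 9)),
            d_edge_embed=int(rng.integers(1, 9)),
            k_intra=int(rng.integers(1, 4)),
            k_inter=int(rng.integers(1, 4)),
            readout=("sum", "set2set")[int(rng.integers(2))],
            head_layers=(int(rng.integers(2, 17)), 1),
        )
        params = NGNNParameters.initialize(config, 0, seed=11)
        batch = GraphBatch.from_samples([sample])
        h0 = embed_nodes(batch, params)
        assert h0.values.shape[1] == config.d_inherent_embed + config.d_env_embed
        hq = inter_pass_q(dissolve_nodes(intra_pass(h0, params), batch, params), params)
        he = inter_pass_e(intra_pass(h0, params), dissolve_edges(batch, params), params)
        emb = readout(hq, he, params)
        d1, d2 = config.branch_readout_dims
        assert emb.h_g1.shape[1] == d1
        assert emb.h_g2.shape[1] == d2
        assert emb.h_g.shape[1] == config.embedding_dim


def test_solvent_sensitivity(registry):
    """Same solute, different solvents, nonzero W3/W5: predictions must differ."""
    params = NGNNParameters.initialize(small_config(), 0, seed=12)
    a = build_sample("CCO", "H2O", 0.0, registry=registry)
    b = build_sample("CCO", "hexane", 0.0, registry=registry)
    assert forward(a, params) != forward(b, params)


def test_batched_equals_one_by_one(registry):
    params = NGNNParameters.initialize(small_config(), 0, seed=13)
    samples = [
        build_sample(s, solv, 0.0, registry=registry)
        for s, solv in [("C", "H2O"), ("CCO", "DMSO"), ("c1ccccc1", "toluene"), ("CC#N", "THF")]
    ]
    batched = forward(samples, params)
    singles = np.array([forward(s, params) for s in samples])
    assert np.allclose(batched, singles, rtol=1e-9)


def test_forward_deterministic_across_processes(registry, tmp_path):
    sample = build_sample("CCO", "H2O", 0.0, registry=registry)
    params = NGNNParameters.initialize(small_config(), 0, seed=14)
    y_here = forward(sample, params)
    script = (
        "import ngnn\n"
        "from ngnn.model import NGNNParameters\n"
        "import sys\n"
        "sys.path.insert(0, r'%s')\n"
        "from conftest import small_config\n"
        "s = ngnn.build_sample('CCO', 'H2O', 0.0)\n"
        "p = NGNNParameters.initialize(small_config(), 0, seed=14)\n"
        "print(repr(ngnn.forward(s, p)))\n" % (__file__.rsplit("/", 1)[0])
    )
    out = subprocess.run([sys.executable, "-c", script], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    assert float(out.stdout.strip()) == y_here  # bit-identical


# --------------------------------------------------------------------------
# gradient flow
# --------------------------------------------------------------------------
def test_backprop_matches_finite_differences_for_every_bank(registry):
    from ngnn.model import forward_tensor
    from ngnn._autodiff import sum_all

    sample = build_sample("CCO", "H2O", 0.0, registry=registry)  # 3 atoms
    batch = GraphBatch.from_samples([sample])
    config = small_config()
    params = NGNNParameters.initialize(config, 0, seed=15)

    params.zero_grad()
    y = forward_tensor(batch, params)
    sum_all(y).backward()
    grads = {k: (t.grad.copy() if t.grad is not None else np.zeros_like(t.data))
             for k, t in params.tensors.items()}

    eps = 1e-6
    rng = np.random.default_rng(0)
    checked_banks = set()
    for bank, names in params.banks().items():
        for name in names:
            t = params.tensors[name]
            flat = t.data.ravel()
            coords = rng.choice(flat.size, size=min(3, flat.size), replace=False)
            for c in coords:
                orig = flat[c]
                flat[c] = orig + eps
                hi = float(forward_tensor(batch, params).data.sum())
                flat[c] = orig - eps
                lo = float(forward_tensor(batch, params).data.sum())
                flat[c] = orig
                fd = (hi - lo) / (2 * eps)
                bp = grads[name].ravel()[c]
                assert abs(fd - bp) <= 1e-4 * max(1.0, abs(fd), abs(bp)), (name, c, fd, bp)
        checked_banks.add(bank)
    assert {"W1", "W2", "W3", "W4", "W5", "theta_intra", "theta_q", "theta_e",
            "edge_mlp_intra", "edge_mlp_q", "edge_mlp_e", "readout", "head"} <= checked_banks


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------
def test_checkpoint_roundtrip_bit_exact(tmp_path, registry):
    sample = build_sample("CCO", "DMF", 0.0, registry=registry)
    params = NGNNParameters.initialize(small_config(), 0, seed=16)
    y = forward(sample, params)
    path = tmp_path / "ckpt.json"
    save_checkpoint(params, path)
    restored, _ = load_checkpoint(path)
    for name, t in params.tensors.items():
        assert np.array_equal(t.data, restored.tensors[name].data)
    assert forward(sample, restored) == y


def test_parameter_count_is_config_function():
    c = small_config()
    shapes1 = parameter_shapes(c, 0)
    shapes2 = parameter_shapes(c, 0)
    assert shapes1 == shapes2
    with_flag = parameter_shapes(c, 1)
    assert with_flag["W2"][0] == shapes1["W2"][0] + 1
    assert {k: v for k, v in with_flag.items() if k != "W2"} == {
        k: v for k, v in shapes1.items() if k != "W2"
    }
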