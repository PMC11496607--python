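"""The natural-growth message-passing network for dissolved molecules.

The architecture grows information across scales in eight stages:

1. node embedding     h_i   = concat(sigma(W1 h_ia), sigma(W2 h_ib))
2. intramolecular     h_i^k = Theta h_i^{k-1} + (1/N_i) sum_j h_j^{k-1} * MLP(sigma(W4 e_ija))
3. atom dissolution   h_i^q = concat(h_i', sigma(W3 h_ic))          (solvent broadcast)
4. edge solvation     e_ijc = concat(sigma(W4 e_ija), sigma(W5 e_ijb))
5. intermolecular (q) same update as 2 on the widened states, gate from sigma(W4 e_ija)
6. intermolecular (e) same update on the un-widened states, gate MLP(e_ijc)
7. readout            h_G   = concat(Set(h^q), Set(h))              (permutation-invariant)
8. head               y     = MLP(h_G)

`*` is the elementwise product (the edge MLP maps to the node-state width),
1/N_i is the mean over the receiving atom's neighbors (isolated atoms receive
no message), and Theta is a bias-free learnable square map, one copy per round
and per stage unless weight sharing is switched on. W1..W5 are bias-free;
the edge MLPs and the head carry biases.

Everything is float64 and fully deterministic given the run seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .featurize import (
    BOND_LENGTH,
    ENV_BASE_LENGTH,
    INHERENT_LENGTH,
    N_POLARITY_PARAMS,
    N_SOLVENT_DESCRIPTORS,
    DissolvedSample,
)

__all__ = [
    "ModelError",
    "NGNNConfig",
    "NGNNParameters",
    "GraphBatch",
    "NodeStates",
    "EdgeStates",
    "GraphEmbedding",
    "embed_nodes",
    "intra_pass",
    "dissolve_nodes",
    "dissolve_edges",
    "inter_pass_q",
    "inter_pass_e",
    "readout",
    "predict",
    "forward",
    "forward_tensor",
    "save_checkpoint",
    "load_checkpoint",
]


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class NGNNConfig:
    """Architecture hyperparameters; defaults are the package's documented choices."""

    d_inherent_embed: int = 64
    d_env_embed: int = 64
    d_solvent_embed: int = 64
    d_edge_embed: int = 64
    k_intra: int = 3
    k_inter: int = 2
    activation: str = "leaky_relu"
    readout: str = "set2set"  # or "sum"
    set2set_steps: int = 3
    head_layers: tuple[int, ...] = (128, 64, 1)
    share_theta: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("d_inherent_embed", "d_env_embed", "d_solvent_embed", "d_edge_embed"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be >= 1")
        if self.k_intra < 1 or self.k_inter < 1:
            raise ModelError("k_intra and k_inter must be >= 1")
        if self.activation not in ad.ACTIVATIONS:
            raise ModelError(f"unknown activation {self.activation!r}")
        if self.readout not in ("set2set", "sum"):
            raise ModelError(f"unknown readout {self.readout!r}")
        if not self.head_layers or self.head_layers[-1] != 1:
            raise ModelError("head_layers must end in width 1")
        object.__setattr__(self, "head_layers", tuple(self.head_layers))

    # derived dimensions ----------------------------------------------------
    @property
    def node_dim(self) -> int:
        return self.d_inherent_embed + self.d_env_embed

    @property
    def q_dim(self) -> int:
        return self.node_dim + self.d_solvent_embed

    @property
    def branch_readout_dims(self) -> tuple[int, int]:
        mult = 2 if self.readout == "set2set" else 1
        return mult * self.q_dim, mult * self.node_dim

    @property
    def embedding_dim(self) -> int:
        return sum(self.branch_readout_dims)

    def activation_fn(self):
        return ad.ACTIVATIONS[self.activation]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def parameter_shapes(config: NGNNConfig, n_custom_flags: int = 0) -> dict[str, tuple]:
    """Shape of every learnable tensor; a pure function of the configuration."""
    d_node, d_q, de = config.node_dim, config.q_dim, config.d_edge_embed
    shapes: dict[str, tuple] = {
        "W1": (INHERENT_LENGTH, config.d_inherent_embed),
        "W2": (ENV_BASE_LENGTH + n_custom_flags, config.d_env_embed),
        "W3": (N_SOLVENT_DESCRIPTORS, config.d_solvent_embed),
        "W4": (BOND_LENGTH, de),
        "W5": (N_POLARITY_PARAMS, de),
    }

    def add_stage(stage: str, dim: int, gate_in: int, k_rounds: int):
        rounds = 1 if config.share_theta else k_rounds
        for r in range(rounds):
            shapes[f"theta_{stage}_{r}"] = (dim, dim)
        shapes[f"edge_mlp_{stage}_W0"] = (gate_in, gate_in)
        shapes[f"edge_mlp_{stage}_b0"] = (gate_in,)
        shapes[f"edge_mlp_{stage}_W1"] = (gate_in, dim)
        shapes[f"edge_mlp_{stage}_b1"] = (dim,)

    add_stage("intra", d_node, de, config.k_intra)
    add_stage("q", d_q, de, config.k_inter)
    add_stage("e", d_node, 2 * de, config.k_inter)

    if config.readout == "set2set":
        for branch, d in (("q", d_q), ("e", d_node)):
            shapes[f"s2s_{branch}_Wx"] = (2 * d, 4 * d)
            shapes[f"s2s_{branch}_Wh"] = (d, 4 * d)
            shapes[f"s2s_{branch}_b"] = (4 * d,)

    widths = (config.embedding_dim,) + config.head_layers
    for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
        shapes[f"head_W{i}"] = (fan_in, fan_out)
        shapes[f"head_b{i}"] = (fan_out,)
    return shapes


class NGNNParameters:
    """All learnable maps, keyed by name; reproducibly initialized from a seed."""

    def __init__(self, config: NGNNConfig, n_custom_flags: int, tensors: dict[str, Tensor]):
        self.config = config
        self.n_custom_flags = n_custom_flags
        self.tensors = tensors

    @classmethod
    def initialize(
        cls, config: NGNNConfig, n_custom_flags: int = 0, seed: int | None = None
    ) -> "NGNNParameters":
        """Glorot-uniform weights, zero biases, in a fixed deterministic order."""
        rng = np.random.default_rng(config.seed if seed is None else seed)
        tensors = {}
        for name, shape in parameter_shapes(config, n_custom_flags).items():
            if len(shape) == 1:
                data = np.zeros(shape)
            else:
                limit = np.sqrt(6.0 / (shape[0] + shape[1]))
                data = rng.uniform(-limit, limit, size=shape)
            tensors[name] = Tensor(data, requires_grad=True)
        return cls(config, n_custom_flags, tensors)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def theta(self, stage: str, round_index: int) -> Tensor:
        if self.config.share_theta:
            round_index = 0
        return self.tensors[f"theta_{stage}_{round_index}"]

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.tensors.values())

    def zero_grad(self):
        for t in self.tensors.values():
            t.zero_grad()

    def banks(self) -> dict[str, list[str]]:
        """Group tensor names into the architecture's parameter banks."""
        groups: dict[str, list[str]] = {}
        for name in self.tensors:
            if name in ("W1", "W2", "W3", "W4", "W5"):
                key = name
            elif name.startswith("theta_") or name.startswith("edge_mlp_"):
                key = "_".join(name.split("_")[:-1] if name.startswith("theta_") else name.split("_")[:3])
            elif name.startswith("s2s_"):
                key = "readout"
            else:
                key = "head"
            groups.setdefault(key, []).append(name)
        return groups

    def copy(self) -> "NGNNParameters":
        return NGNNParameters(
            self.config,
            self.n_custom_flags,
            {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.tensors.items()},
        )


# --------------------------------------------------------------------------
# batching: disjoint union of solute graphs
# --------------------------------------------------------------------------
@dataclass
class GraphBatch:
    """Disjoint union of dissolved samples, ready for vectorized passing."""

    n_nodes: int
    n_graphs: int
    graph_id: np.ndarray  # (n,) node -> graph
    receiver: np.ndarray  # (E,) node index i of each directed edge i<-j
    sender: np.ndarray  # (E,) node index j
    edge_graph_id: np.ndarray  # (E,)
    inv_deg: np.ndarray  # (n, 1) 1/N_i, 0 for isolated atoms
    node_inherent: np.ndarray  # (n, 6)
    node_env: np.ndarray  # (n, 23 + k)
    edge_raw: np.ndarray  # (E, 7)
    solvent_desc: np.ndarray  # (G, 66)
    solvent_pol: np.ndarray  # (G, 5)
    targets: np.ndarray  # (G,)
    sample_ids: tuple[str, ...]

    @property
    def n_edges(self) -> int:
        return len(self.receiver)

    @classmethod
    def from_samples(cls, samples: Sequence[DissolvedSample]) -> "GraphBatch":
        if not samples:
            raise ModelError("empty batch")
        widths = {s.solute.environment.shape[1] for s in samples}
        if len(widths) > 1:
            raise ModelError(f"inconsistent environment widths in batch: {sorted(widths)}")
        graph_id, recv, send, eg_id = [], [], [], []
        offset = 0
        for g, s in enumerate(samples):
            n = s.solute.n_atoms
            graph_id.extend([g] * n)
            edges = s.solute.directed_edges
            recv.extend((edges[:, 0] + offset).tolist())
            send.extend((edges[:, 1] + offset).tolist())
            eg_id.extend([g] * len(edges))
            offset += n
        recv = np.asarray(recv, dtype=np.intp)
        deg = np.zeros(offset)
        np.add.at(deg, recv, 1.0)
        inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return cls(
            n_nodes=offset,
            n_graphs=len(samples),
            graph_id=np.asarray(graph_id, dtype=np.intp),
            receiver=recv,
            sender=np.asarray(send, dtype=np.intp),
            edge_graph_id=np.asarray(eg_id, dtype=np.intp),
            inv_deg=inv_deg[:, None],
            node_inherent=np.vstack([s.solute.inherent for s in samples]),
            node_env=np.vstack([s.solute.environment for s in samples]),
            edge_raw=(
                np.vstack([s.solute.bond_features for s in samples])
                if any(len(s.solute.bond_features) for s in samples)
                else np.empty((0, BOND_LENGTH))
            ),
            solvent_desc=np.vstack([s.solvent_descriptors for s in samples]),
            solvent_pol=np.vstack([s.solvent_polarity for s in samples]),
            targets=np.array([s.target for s in samples]),
            sample_ids=tuple(s.sample_id for s in samples),
        )


def _as_batch(x) -> GraphBatch:
    if isinstance(x, GraphBatch):
        return x
    if isinstance(x, DissolvedSample):
        return GraphBatch.from_samples([x])
    return GraphBatch.from_samples(list(x))


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------
@dataclass
class NodeStates:
    values: Tensor  # (n_nodes, d)
    batch: GraphBatch
    track: str  # "intact" | "dissolved_q" | "dissolved_e"
    round_index: int = 0


@dataclass
class EdgeStates:
    values: Tensor  # (n_edges, d)
    batch: GraphBatch
    track: str  # "raw" | "dissolved"


@dataclass
class GraphEmbedding:
    h_g1: Tensor
    h_g2: Tensor
    h_g: Tensor


def _check_finite(t: Tensor, context: str):
    if not np.all(np.isfinite(t.data)):
        raise ModelError(f"non-finite values in {context}")


# --------------------------------------------------------------------------
# the eight stages
# --------------------------------------------------------------------------
def embed_nodes(sample, params: NGNNParameters) -> NodeStates:
    """Map the incompatible raw blocks into one node state per atom.

    Inherent constants (natural coding) and environmental one-hots live on
    different scales, so each block gets its own linear map before the
    concatenation."""
    batch = _as_batch(sample)
    act = params.config.activation_fn()
    if batch.node_env.shape[1] != params["W2"].shape[0]:
        raise ModelError(
            f"environment width {batch.node_env.shape[1]} does not match W2 input "
            f"{params['W2'].shape[0]} (marking-rule mismatch between data and model)"
        )
    h = ad.concat(
        [
            act(ad.matmul(Tensor(batch.node_inherent), params["W1"])),
            act(ad.matmul(Tensor(batch.node_env), params["W2"])),
        ],
        axis=1,
    )
    return NodeStates(h, batch, track="intact")


def _bond_gate(batch: GraphBatch, params: NGNNParameters, stage: str) -> Tensor:
    """MLP(sigma(W4 e_ija)) for the given stage's edge MLP."""
    act = params.config.activation_fn()
    ea = act(ad.matmul(Tensor(batch.edge_raw), params["W4"]))
    return _edge_mlp(ea, params, stage)


def _edge_mlp(edge_embed: Tensor, params: NGNNParameters, stage: str) -> Tensor:
    act = params.config.activation_fn()
    hidden = act(
        ad.matmul(edge_embed, params[f"edge_mlp_{stage}_W0"]) + params[f"edge_mlp_{stage}_b0"]
    )
    return ad.matmul(hidden, params[f"edge_mlp_{stage}_W1"]) + params[f"edge_mlp_{stage}_b1"]


def _propagate(
    states: NodeStates,
    params: NGNNParameters,
    stage: str,
    gate: Tensor | None,
    k_rounds: int,
) -> NodeStates:
    """k rounds of h_i <- Theta h_i + mean_j h_j * gate_ij (gate fixed across rounds)."""
    batch = states.batch
    h = states.values
    for r in range(k_rounds):
        out = ad.matmul(h, params.theta(stage, r))
        if batch.n_edges:
            msg = ad.gather_rows(h, batch.sender) * gate
            agg = ad.segment_sum(msg, batch.receiver, batch.n_nodes) * Tensor(batch.inv_deg)
            out = out + agg
        h = out
        if not np.all(np.isfinite(h.data)):
            raise ModelError(f"non-finite node states in {stage} passing, round {r}")
    return NodeStates(h, batch, track=states.track, round_index=states.round_index + k_rounds)


def intra_pass(
    states: NodeStates, params: NGNNParameters, k_rounds: int | None = None
) -> NodeStates:
    """Intramolecular message passing on the intact graph, gated by bond features."""
    k = params.config.k_intra if k_rounds is None else k_rounds
    gate = _bond_gate(states.batch, params, "intra") if states.batch.n_edges else None
    return _propagate(states, params, "intra", gate, k)


def dissolve_nodes(states: NodeStates, sample, params: NGNNParameters) -> NodeStates:
    """Widen every atom with the solvent-descriptor embedding (same tail per graph)."""
    batch = states.batch
    act = params.config.activation_fn()
    tail = act(ad.matmul(Tensor(batch.solvent_desc), params["W3"]))  # (G, d3)
    widened = ad.concat([states.values, ad.gather_rows(tail, batch.graph_id)], axis=1)
    return NodeStates(widened, batch, track="dissolved_q")


def dissolve_edges(sample, params: NGNNParameters) -> EdgeStates:
    """Solvated edge features: bond embedding next to the polarity embedding.

    The polarity half (Et30 and the Catalan scales through W5) is identical for
    every edge of one sample."""
    batch = _as_batch(sample)
    act = params.config.activation_fn()
    ea = act(ad.matmul(Tensor(batch.edge_raw), params["W4"]))
    pol = act(ad.matmul(Tensor(batch.solvent_pol), params["W5"]))  # (G, de)
    e_c = ad.concat([ea, ad.gather_rows(pol, batch.edge_graph_id)], axis=1)
    _check_finite(e_c, "dissolved edge features")
    return EdgeStates(e_c, batch, track="dissolved")


def inter_pass_q(
    states_q: NodeStates, params: NGNNParameters, k_rounds: int | None = None
) -> NodeStates:
    """Intermolecular passing on the widened (quasi-dissolved-atom) states."""
    k = params.config.k_inter if k_rounds is None else k_rounds
    gate = _bond_gate(states_q.batch, params, "q") if states_q.batch.n_edges else None
    return _propagate(states_q, params, "q", gate, k)


def inter_pass_e(
    states: NodeStates,
    edge_states: EdgeStates,
    params: NGNNParameters,
    k_rounds: int | None = None,
) -> NodeStates:
    """Intermolecular passing gated by the solvated edge features directly."""
    k = params.config.k_inter if k_rounds is None else k_rounds
    gate = _edge_mlp(edge_states.values, params, "e") if states.batch.n_edges else None
    return _propagate(states, params, "e", gate, k)


def _set2set(
    h: Tensor, batch: GraphBatch, params: NGNNParameters, branch: str, dim: int
) -> Tensor:
    """Set-to-set readout: an LSTM queries the node set by attention m times."""
    steps = params.config.set2set_steps
    n_graphs = batch.n_graphs
    wx, wh, b = params[f"s2s_{branch}_Wx"], params[f"s2s_{branch}_Wh"], params[f"s2s_{branch}_b"]
    q = Tensor(np.zeros((n_graphs, dim)))
    c = Tensor(np.zeros((n_graphs, dim)))
    q_star = Tensor(np.zeros((n_graphs, 2 * dim)))
    for _ in range(steps):
        gates = ad.matmul(q_star, wx) + ad.matmul(q, wh) + b
        i_g = ad.sigmoid(_cols(gates, 0, dim))
        f_g = ad.sigmoid(_cols(gates, dim, 2 * dim))
        o_g = ad.sigmoid(_cols(gates, 2 * dim, 3 * dim))
        g_g = ad.tanh(_cols(gates, 3 * dim, 4 * dim))
        c = f_g * c + i_g * g_g
        q = o_g * ad.tanh(c)
        logits = ad.rowsum(h * ad.gather_rows(q, batch.graph_id))  # (n, 1)
        shift = np.full((n_graphs, 1), -np.inf)
        np.maximum.at(shift, batch.graph_id, logits.data)
        weights = ad.exp(logits - Tensor(shift[batch.graph_id]))
        denom = ad.segment_sum(weights, batch.graph_id, n_graphs)
        alpha = weights / ad.gather_rows(denom, batch.graph_id)
        r = ad.segment_sum(h * alpha, batch.graph_id, n_graphs)
        q_star = ad.concat([q, r], axis=1)
    return q_star


def _cols(t: Tensor, lo: int, hi: int) -> Tensor:
    out = ad.Tensor(t.data[:, lo:hi])
    out._parents = (t,)

    def back(g):
        full = np.zeros_like(t.data)
        full[:, lo:hi] = g
        t._accumulate(full)

    out._backward = back
    return out


def readout(
    states_q_final: NodeStates, states_e_final: NodeStates, params: NGNNParameters
) -> GraphEmbedding:
    """Aggregate each dissolved graph's node set into one vector per branch."""
    if states_q_final.batch.n_nodes != states_e_final.batch.n_nodes:
        raise ModelError("branch state sets disagree on the number of atoms")
    cfg = params.config
    batch = states_q_final.batch
    if cfg.readout == "sum":
        h_g1 = ad.segment_sum(states_q_final.values, batch.graph_id, batch.n_graphs)
        h_g2 = ad.segment_sum(states_e_final.values, batch.graph_id, batch.n_graphs)
    else:
        h_g1 = _set2set(states_q_final.values, batch, params, "q", cfg.q_dim)
        h_g2 = _set2set(states_e_final.values, states_e_final.batch, params, "e", cfg.node_dim)
    return GraphEmbedding(h_g1, h_g2, ad.concat([h_g1, h_g2], axis=1))


def predict(embedding: GraphEmbedding, params: NGNNParameters) -> Tensor:
    """Scalar property per graph from the concatenated embedding."""
    act = params.config.activation_fn()
    h = embedding.h_g
    n_layers = len(params.config.head_layers)
    for i in range(n_layers):
        h = ad.matmul(h, params[f"head_W{i}"]) + params[f"head_b{i}"]
        if i < n_layers - 1:
            h = act(h)
    _check_finite(h, "prediction head output")
    return h


# --------------------------------------------------------------------------
# full forward pass
# --------------------------------------------------------------------------
_STAGES = (
    "embed_nodes",
    "intra_pass",
    "dissolve_nodes",
    "inter_pass_q",
    "dissolve_edges",
    "inter_pass_e",
    "readout",
    "predict",
)


def forward_tensor(batch: GraphBatch, params: NGNNParameters) -> Tensor:
    """Differentiable forward pass; returns per-graph predictions (G, 1)."""
    stage = "embed_nodes"
    try:
        h0 = embed_nodes(batch, params)
        stage = "intra_pass"
        h_intra = intra_pass(h0, params)
        stage = "dissolve_nodes"
        h_q = dissolve_nodes(h_intra, batch, params)
        stage = "inter_pass_q"
        h_q = inter_pass_q(h_q, params)
        stage = "dissolve_edges"
        e_c = dissolve_edges(batch, params)
        stage = "inter_pass_e"
        h_e = inter_pass_e(h_intra, e_c, params)
        stage = "readout"
        emb = readout(h_q, h_e, params)
        stage = "predict"
        return predict(emb, params)
    except ModelError as err:
        raise ModelError(f"forward failed in stage {stage}: {err}") from None


def forward(sample, params: NGNNParameters) -> float | np.ndarray:
    """Predict the property for one sample (float) or a batch (array)."""
    single = isinstance(sample, DissolvedSample)
    batch = _as_batch(sample)
    y = forward_tensor(batch, params).data[:, 0]
    return float(y[0]) if single and batch.n_graphs == 1 else y.copy()


# --------------------------------------------------------------------------
# checkpointing (text JSON; float64 round-trips exactly via repr)
# --------------------------------------------------------------------------
def save_checkpoint(params: NGNNParameters, path, extra: dict | None = None):
    from .featurize import DESCRIPTOR_REGISTRY_VERSION

    payload = {
        "config": params.config.to_dict(),
        "n_custom_flags": params.n_custom_flags,
        "registry_version": DESCRIPTOR_REGISTRY_VERSION,
        "tensors": {k: v.data.tolist() for k, v in params.tensors.items()},
        "extra": extra or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[NGNNParameters, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    config = NGNNConfig(**payload["config"])
    tensors = {
        k: Tensor(np.array(v, dtype=np.float64), requires_grad=True)
        for k, v in payload["tensors"].items()
    }
    expected = parameter_shapes(config, payload["n_custom_flags"])
    for name, shape in expected.items():
        if name not in tensors or tensors[name].shape != shape:
            raise ModelError(f"checkpoint tensor {name!r} missing or mis-shaped")
    return NGNNParameters(config, payload["n_custom_flags"], tensors), payload.get("extra", {})
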