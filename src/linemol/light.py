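"""Line-graph transformer encoder with path- and distance-biased attention.

The encoder operates on a molecular line graph (optionally augmented with a
knowledge node).  Each node's initial embedding is

    h = concat(W_v x_i + W_v x_j,  W_e x_e)

i.e. the sum of the two endpoint-atom projections concatenated with the bond
projection; the knowledge node is embedded by projecting its 712-dimensional
descriptor/fingerprint vector.  Structure enters through two additive
attention biases shared by all layers and heads:

* path bias   a^p_{ij} = W_a ( mean_n W_n h_{p_n} ) over the stored shortest
  path between nodes i and j, with a per-position projection bank W_1..W_P;
* distance bias a^d_{ij} = W_2 GELU(W_1 d_{ij}) from the (clipped) hop count.

Pairs involving the knowledge node, and unreachable pairs, bypass both
formulas and receive dedicated learned scalars — the knowledge node is wired
to every node, so routing it through the shortest-path machinery would
collapse all distances to <= 2 hops and erase the structural signal.

Each transformer layer is multi-head attention

    A = softmax(Q K^T / sqrt(D_h) + A^p + A^d)

followed by a post-norm residual feed-forward block

    H_hat = LN(H_prev + H_attn);  out = LN(W_2 GELU(W_1 H_hat) + H_hat).

Readout is a mean pool over nodes (knowledge node included by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .molgraph import AugmentedGraph, LineGraph, UNREACHABLE, DEFAULT_SCHEME
from .nn import Tensor, concat, dropout, trunc_normal

__all__ = [
    "LiGhTConfig",
    "LiGhTModel",
    "AttentionBias",
    "PredictionHead",
    "embed_nodes",
    "path_bias",
    "distance_bias",
    "attention_bias",
    "attention_layer",
    "ffn_block",
    "forward",
    "predict_head",
    "count_parameters",
]


@dataclass
class LiGhTConfig:
    """Hyperparameters of the encoder.

    Defaults follow the reference configuration (12 layers, 768 hidden units,
    12 attention heads); desk-scale work uses much smaller values.
    """

    n_layers: int = 12
    hidden: int = 768
    n_heads: int = 12
    d_path: int | None = None       # path-embedding dim D_p; defaults to hidden
    d_dist: int | None = None       # distance-embedding dim D_d; defaults to hidden
    max_path_nodes: int = 5
    distance_clip: int = 20
    knowledge_dim: int = 712
    atom_dim: int = DEFAULT_SCHEME.atom_dim
    bond_dim: int = DEFAULT_SCHEME.bond_dim
    dropout: float = 0.1
    include_k_in_pool: bool = True
    recompute_bias_per_layer: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.d_path is None:
            self.d_path = self.hidden
        if self.d_dist is None:
            self.d_dist = self.hidden
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden must be divisible by n_heads")
        if self.hidden % 2 != 0:
            raise ValueError("hidden must be even (embedding concatenates two halves)")
        for name in ("n_layers", "hidden", "n_heads", "d_path", "d_dist",
                     "max_path_nodes", "knowledge_dim", "atom_dim", "bond_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.hidden // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LiGhTConfig":
        return cls(**d)


@dataclass
class AttentionBias:
    """Per-graph additive attention biases, shared across layers and heads."""

    a_path: Tensor   # [N, N]
    a_dist: Tensor   # [N, N]
    pad_mask: np.ndarray | None = None  # True where a position is padding

    def total(self) -> Tensor:
        b = self.a_path + self.a_dist
        if self.pad_mask is not None:
            neutral = np.where(self.pad_mask[None, :] | self.pad_mask[:, None],
                               -1e30, 0.0)
            b = b + Tensor(neutral)
        return b


class LiGhTModel:
    """Parameter bundle: embeddings, L transformer layers, bias banks."""

    def __init__(self, config: LiGhTConfig, params: dict[str, Tensor]):
        self.config = config
        self.params = params
        self.training = False
        self.rng: np.random.Generator | None = None

    @classmethod
    def init(cls, config: LiGhTConfig, seed: int | None = None) -> "LiGhTModel":
        rng = np.random.default_rng(config.seed if seed is None else seed)
        D, Dp, Dd = config.hidden, config.d_path, config.d_dist
        std = 0.02

        def w(*shape):
            return Tensor(trunc_normal(shape, std, rng), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "embed.Wv": w(D // 2, config.atom_dim),
            "embed.We": w(D // 2, config.bond_dim),
            "embed.bv": zeros(D // 2),
            "embed.be": zeros(D // 2),
            "embed.mask_token": w(D),
            "know.Wk": w(D, config.knowledge_dim),
            "know.Wmask": w(D, config.knowledge_dim),
            "know.bk": zeros(D),
        }
        for n in range(1, config.max_path_nodes + 1):
            p[f"path.W{n}"] = w(Dp, D)
        p["path.Wa"] = w(1, Dp)
        p["path.k_scalar"] = zeros(1)
        p["path.unreach_scalar"] = zeros(1)
        p["dist.W1"] = w(Dd, 1)
        p["dist.W2"] = w(1, Dd)
        p["dist.k_scalar"] = zeros(1)
        p["dist.unreach_scalar"] = zeros(1)
        for l in range(config.n_layers):
            p[f"layer{l}.Wq"] = w(D, D)
            p[f"layer{l}.Wk"] = w(D, D)
            p[f"layer{l}.Wv"] = w(D, D)
            p[f"layer{l}.bq"] = zeros(D)
            p[f"layer{l}.bk"] = zeros(D)
            p[f"layer{l}.bv"] = zeros(D)
            p[f"layer{l}.ln1.gamma"] = ones(D)
            p[f"layer{l}.ln1.beta"] = zeros(D)
            p[f"layer{l}.W1"] = w(4 * D, D)
            p[f"layer{l}.b1"] = zeros(4 * D)
            p[f"layer{l}.W2"] = w(D, 4 * D)
            p[f"layer{l}.b2"] = zeros(D)
            p[f"layer{l}.ln2.gamma"] = ones(D)
            p[f"layer{l}.ln2.beta"] = zeros(D)
        return cls(config, p)

    def train(self, rng: np.random.Generator | None = None):
        self.training = True
        self.rng = rng

    def eval(self):
        self.training = False
        self.rng = None

    def layer_param_names(self, l: int) -> list[str]:
        return [k for k in self.params if k.startswith(f"layer{l}.")]

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


class PredictionHead:
    """Two-layer perceptron with GELU: pooled embedding -> task outputs.

    Emits raw scores; classification losses apply the sigmoid link themselves.
    """

    def __init__(self, in_dim: int, n_tasks: int, hidden: int | None = None,
                 seed: int = 0, name: str = "head"):
        rng = np.random.default_rng(seed)
        h = in_dim if hidden is None else hidden
        self.in_dim, self.n_tasks, self.hidden, self.name = in_dim, n_tasks, h, name
        self.params = {
            f"{name}.W1": Tensor(trunc_normal((h, in_dim), 0.02, rng), requires_grad=True),
            f"{name}.b1": Tensor(np.zeros(h), requires_grad=True),
            f"{name}.W2": Tensor(trunc_normal((n_tasks, h), 0.02, rng), requires_grad=True),
            f"{name}.b2": Tensor(np.zeros(n_tasks), requires_grad=True),
        }

    def __call__(self, x: Tensor) -> Tensor:
        return predict_head(x, self)


def predict_head(x: Tensor, head: PredictionHead) -> Tensor:
    """Apply a 2-layer GELU perceptron to a vector or a matrix of rows."""
    if x.shape[-1] != head.in_dim:
        raise ValueError(f"input dim {x.shape[-1]} != head dim {head.in_dim}")
    p, n = head.params, head.name
    hidden = (x @ p[f"{n}.W1"].T + p[f"{n}.b1"]).gelu()
    return hidden @ p[f"{n}.W2"].T + p[f"{n}.b2"]


# ---------------------------------------------------------------------------
# forward pieces


def _base_graph(g) -> LineGraph:
    return g.base if isinstance(g, AugmentedGraph) else g


def embed_nodes(g, m: LiGhTModel) -> Tensor:
    """Initial node embedding matrix H^0, shape [N, hidden].

    Base rows are concat(W_v x_i + W_v x_j + b_v, W_e x_e + b_e); the atom sum
    makes the embedding symmetric in the two endpoints.  Nodes flagged as
    masked by the pre-training corruption are replaced by the learned mask
    token.  The knowledge-node row (if present) projects the 712-vector, with
    a second projection of the mask-indicator channel added in.
    """
    base = _base_graph(g)
    cfg, p = m.config, m.params
    xi = np.stack([nd.x_i for nd in base.nodes])
    xj = np.stack([nd.x_j for nd in base.nodes])
    xe = np.stack([nd.x_e for nd in base.nodes])
    if xi.shape[1] != cfg.atom_dim or xe.shape[1] != cfg.bond_dim:
        raise ValueError("graph feature dims do not match the model config")
    left = Tensor(xi + xj) @ p["embed.Wv"].T + p["embed.bv"]
    right = Tensor(xe) @ p["embed.We"].T + p["embed.be"]
    h = concat([left, right], axis=1)

    masked = np.array([nd.is_masked for nd in base.nodes], dtype=float)[:, None]
    if masked.any():
        h = h * Tensor(1.0 - masked) + Tensor(masked) * p["embed.mask_token"]

    if isinstance(g, AugmentedGraph):
        if g.knowledge.shape != (cfg.knowledge_dim,):
            raise ValueError("knowledge vector dim does not match the model config")
        kmask = (np.zeros(cfg.knowledge_dim) if g.knowledge_mask is None
                 else np.asarray(g.knowledge_mask, dtype=float))
        values = g.knowledge * (1.0 - kmask)
        k_row = (p["know.Wk"] @ Tensor(values) + p["know.Wmask"] @ Tensor(kmask)
                 + p["know.bk"])
        h = concat([h, k_row.reshape(1, -1)], axis=0)
    return h


def _with_k_border(block: Tensor, n_base: int, scalar: Tensor) -> Tensor:
    """Surround an [n_base, n_base] bias block with knowledge-node rows/cols."""
    ones_col = Tensor(np.ones((n_base, 1)))
    ones_row = Tensor(np.ones((1, n_base + 1)))
    top = concat([block, ones_col * scalar], axis=1)
    bottom = ones_row * scalar
    return concat([top, bottom], axis=0)


def path_bias(g, m: LiGhTModel, h0: Tensor) -> Tensor:
    """Shortest-path attention bias A^p, shape [N, N].

    a^p_{ij} = W_a (1/N_p) sum_n W_n h^0_{p_n} over the stored path; diagonal
    pairs use the length-1 path (the node itself).  Unreachable pairs and all
    knowledge-node pairs receive their dedicated learned scalars.
    """
    base = _base_graph(g)
    cfg, p = m.config, m.params
    if base.paths is None:
        raise ValueError("line graph has no stored paths")
    nb, P = base.n_nodes, cfg.max_path_nodes
    if base.path_arrays is not None and base.path_arrays[0].shape[2] == P:
        idx, valid, counts, reach = base.path_arrays
    else:
        idx = np.zeros((nb, nb, P), dtype=np.intp)
        valid = np.zeros((nb, nb, P), dtype=float)
        reach = np.zeros((nb, nb), dtype=float)
        for i in range(nb):
            for j in range(nb):
                path = base.paths[i][j]
                if path is None:
                    continue
                for n, node in enumerate(path[:P]):
                    idx[i, j, n] = node
                    valid[i, j, n] = 1.0
                reach[i, j] = 1.0
        counts = np.maximum(valid.sum(axis=2), 1.0)

    acc = None
    for n in range(P):
        rows = h0.take_rows(idx[:, :, n].ravel())           # [nb*nb, hidden]
        term = (rows @ p[f"path.W{n + 1}"].T) * Tensor(valid[:, :, n].ravel()[:, None])
        acc = term if acc is None else acc + term
    mean = acc * Tensor(1.0 / counts.ravel()[:, None])
    a = (mean @ p["path.Wa"].T).reshape(nb, nb)
    a = a * Tensor(reach) + p["path.unreach_scalar"] * Tensor(1.0 - reach)
    if isinstance(g, AugmentedGraph):
        a = _with_k_border(a, nb, p["path.k_scalar"])
    return a


def distance_bias(g, m: LiGhTModel) -> Tensor:
    """Hop-distance attention bias A^d = W_2 GELU(W_1 d), shape [N, N].

    Distances are clipped at ``distance_clip``; the unreachable sentinel and
    knowledge-node pairs use dedicated learned scalars.
    """
    base = _base_graph(g)
    cfg, p = m.config, m.params
    if base.dist is None:
        raise ValueError("line graph has no distance matrix")
    nb = base.n_nodes
    d = base.dist.astype(float)
    reach = (base.dist != UNREACHABLE).astype(float)
    d = np.clip(np.where(reach > 0, d, 0.0), 0, cfg.distance_clip)
    col = Tensor(d.ravel()[:, None])                       # [nb*nb, 1]
    a = ((col @ p["dist.W1"].T).gelu() @ p["dist.W2"].T).reshape(nb, nb)
    a = a * Tensor(reach) + p["dist.unreach_scalar"] * Tensor(1.0 - reach)
    if isinstance(g, AugmentedGraph):
        a = _with_k_border(a, nb, p["dist.k_scalar"])
    return a


def attention_bias(g, m: LiGhTModel, h0: Tensor) -> AttentionBias:
    return AttentionBias(a_path=path_bias(g, m, h0), a_dist=distance_bias(g, m))


def attention_layer(h_prev: Tensor, bias: AttentionBias, m: LiGhTModel, l: int) -> Tensor:
    """Biased multi-head self-attention; returns the pre-FFN output H^l."""
    if not np.isfinite(h_prev.data).all():
        raise ValueError("non-finite activations entering attention")
    cfg, p = m.config, m.params
    dh = cfg.head_dim
    q = h_prev @ p[f"layer{l}.Wq"] + p[f"layer{l}.bq"]
    k = h_prev @ p[f"layer{l}.Wk"] + p[f"layer{l}.bk"]
    v = h_prev @ p[f"layer{l}.Wv"] + p[f"layer{l}.bv"]
    b = bias.total()
    heads = []
    for head in range(cfg.n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        scores = (q[:, sl] @ k[:, sl].T) * (1.0 / math.sqrt(dh)) + b
        attn = scores.softmax(axis=-1)
        attn = dropout(attn, cfg.dropout, m.rng, m.training)
        heads.append(attn @ v[:, sl])
    return concat(heads, axis=1)


def ffn_block(h_prev: Tensor, h_attn: Tensor, m: LiGhTModel, l: int) -> Tensor:
    """Post-norm residual FFN: LN(W2 GELU(W1 LN(H_prev + H_attn)) + LN(...))."""
    cfg, p = m.config, m.params
    h_hat = (h_prev + h_attn).layer_norm(p[f"layer{l}.ln1.gamma"], p[f"layer{l}.ln1.beta"])
    hidden = (h_hat @ p[f"layer{l}.W1"].T + p[f"layer{l}.b1"]).gelu()
    hidden = dropout(hidden, cfg.dropout, m.rng, m.training)
    out = hidden @ p[f"layer{l}.W2"].T + p[f"layer{l}.b2"] + h_hat
    return out.layer_norm(p[f"layer{l}.ln2.gamma"], p[f"layer{l}.ln2.beta"])


def forward(g, m: LiGhTModel, h0: Tensor | None = None):
    """Run the full encoder; returns (node embeddings [N, D], pooled [D]).

    The bias matrices are computed once from the initial embeddings and shared
    by every layer (set ``recompute_bias_per_layer`` to re-derive them from
    each layer's hidden states instead).  Pooling is the mean over all nodes;
    the knowledge node participates unless ``include_k_in_pool`` is off.
    """
    cfg = m.config
    h = embed_nodes(g, m) if h0 is None else h0
    bias = attention_bias(g, m, h)
    for l in range(cfg.n_layers):
        if cfg.recompute_bias_per_layer and l > 0:
            bias = attention_bias(g, m, h)
        h_attn = attention_layer(h, bias, m, l)
        h = ffn_block(h, h_attn, m, l)
    if isinstance(g, AugmentedGraph) and not cfg.include_k_in_pool:
        pooled = h[: g.base.n_nodes, :].mean(axis=0)
    else:
        pooled = h.mean(axis=0)
    return h, pooled


def count_parameters(m: LiGhTModel, *heads: PredictionHead) -> int:
    """Total trainable scalar count of the encoder (plus any given heads)."""
    total = sum(t.size for t in m.params.values())
    for head in heads:
        total += sum(t.size for t in head.params.values())
    return total
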