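"""Knowledge-guided masked-graph pre-training.

A self-supervised objective over molecular line graphs: a random proportion of
nodes (default rate 0.5) is selected, and each selected node is replaced by a
learned mask token, by a random node drawn from the current batch, or left
unchanged, with ratio 8:1:1.  The encoder is trained to recover the type of
the original node — (unordered element pair, bond type) — with a cross-entropy
loss.  In parallel, a random proportion of the knowledge node's 712 input
features is zeroed (with a mask-indicator channel) and the model predicts the
masked molecular descriptors (RMSE loss) and fingerprint bits (binary
cross-entropy), reading both off the knowledge node's final embedding.  The
total loss is the sum of the three terms with configurable weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .knowledge import (
    DescriptorNormalizer,
    KNOWLEDGE_DIM,
    N_DESCRIPTORS,
    build_knowledge_vector,
    compute_descriptors,
    fit_normalizer,
)
from .light import LiGhTConfig, LiGhTModel, PredictionHead, forward, predict_head
from .molgraph import (
    AugmentedGraph,
    LineGraph,
    LineGraphNode,
    SMILESParseError,
    DEFAULT_SCHEME,
    augment_with_k_node,
    parse_smiles,
    to_line_graph,
)
from .nn import Adam, Tensor

__all__ = [
    "MASK", "RANDOM", "KEEP",
    "MaskPlan", "NodeTypeVocab", "PretrainTargets", "PretrainLoss",
    "PretrainConfig", "PretrainResult",
    "make_mask_plan", "corrupt_graph", "node_type_label", "pretrain_losses",
    "prepare_corpus", "pretrain_run", "masked_node_accuracy",
]

MASK, RANDOM, KEEP = "MASK", "RANDOM", "KEEP"
_ACTIONS = (MASK, RANDOM, KEEP)
_ACTION_PROBS = (0.8, 0.1, 0.1)


@dataclass
class MaskPlan:
    """Per-node corruption actions and knowledge-feature mask for one graph."""

    node_actions: dict[int, str]
    knowledge_mask: np.ndarray  # binary, length 712
    rate: float
    seed: int | None = None

    def selected(self) -> list[int]:
        return sorted(self.node_actions)


def make_mask_plan(g: AugmentedGraph | LineGraph, rate: float = 0.5,
                   seed: int | np.random.Generator | None = 0) -> MaskPlan:
    """Draw a corruption plan: nodes i.i.d. at ``rate``, actions 8:1:1.

    Knowledge-feature entries are masked independently at the same rate.  The
    knowledge node itself is never a corruption target.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"masking rate must lie in [0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = g.base if isinstance(g, AugmentedGraph) else g
    actions: dict[int, str] = {}
    for i in range(base.n_nodes):
        if rng.random() < rate:
            actions[i] = _ACTIONS[rng.choice(3, p=_ACTION_PROBS)]
    kmask = (rng.random(KNOWLEDGE_DIM) < rate).astype(float)
    return MaskPlan(node_actions=actions, knowledge_mask=kmask, rate=rate,
                    seed=None if isinstance(seed, np.random.Generator) else seed)


class NodeTypeVocab:
    """Vocabulary of line-graph node types.

    A node's type is the unordered pair of its endpoint element symbols plus
    its bond type — the minimal label space at bond granularity.  Types not
    seen when the vocabulary was built map to a reserved UNK id.
    """

    def __init__(self, type_to_id: dict[tuple, int] | None = None):
        self._map: dict[tuple, int] = dict(type_to_id or {})

    @property
    def unk_id(self) -> int:
        return len(self._map)

    @property
    def size(self) -> int:
        return len(self._map) + 1  # + UNK

    @staticmethod
    def key_of(node: LineGraphNode, scheme=DEFAULT_SCHEME) -> tuple:
        n_el = len(scheme.elements) + 1
        ei = int(np.argmax(node.x_i[:n_el]))
        ej = int(np.argmax(node.x_j[:n_el]))
        if node.x_e.sum() == 0:  # bond-less single-atom molecule
            bt = -1
        else:
            bt = int(np.argmax(node.x_e[: len(scheme.bond_types) + 1]))
        return (min(ei, ej), max(ei, ej), bt)

    @classmethod
    def build(cls, line_graphs, scheme=DEFAULT_SCHEME) -> "NodeTypeVocab":
        keys = set()
        for lg in line_graphs:
            base = lg.base if isinstance(lg, AugmentedGraph) else lg
            for nd in base.nodes:
                keys.add(cls.key_of(nd, scheme))
        return cls({k: i for i, k in enumerate(sorted(keys))})

    def label(self, node: LineGraphNode, scheme=DEFAULT_SCHEME) -> int:
        return self._map.get(self.key_of(node, scheme), self.unk_id)

    def to_dict(self) -> dict:
        return {",".join(map(str, k)): v for k, v in self._map.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeTypeVocab":
        return cls({tuple(int(x) for x in k.split(",")): v for k, v in d.items()})


def node_type_label(node: LineGraphNode, vocab: NodeTypeVocab,
                    scheme=DEFAULT_SCHEME) -> int:
    return vocab.label(node, scheme)


@dataclass
class PretrainTargets:
    """Ground truth recorded before corruption."""

    selected: np.ndarray            # indices of selected nodes
    node_labels: np.ndarray         # original type ids, aligned with selected
    knowledge_values: np.ndarray    # original knowledge vector (712,)
    knowledge_mask: np.ndarray      # which knowledge entries were masked


def corrupt_graph(g: AugmentedGraph, plan: MaskPlan, batch_pool: list[LineGraphNode],
                  vocab: NodeTypeVocab,
                  rng: np.random.Generator | None = None) -> tuple[AugmentedGraph, PretrainTargets]:
    """Apply a mask plan: returns the corrupted graph and prediction targets.

    MASK nodes are flagged so the encoder substitutes its learned mask token;
    RANDOM nodes take the raw triple of a uniformly drawn batch-pool node;
    KEEP nodes are unchanged but still prediction targets.  Masked knowledge
    entries are zeroed, with the mask itself carried as an indicator channel.
    """
    rng = rng or np.random.default_rng(plan.seed)
    selected = plan.selected()
    if any(a == RANDOM for a in plan.node_actions.values()) and not batch_pool:
        raise ValueError("RANDOM replacement requires a non-empty batch pool")
    labels = np.array([vocab.label(g.base.nodes[i]) for i in selected], dtype=np.intp)

    new_nodes = []
    for i, nd in enumerate(g.base.nodes):
        action = plan.node_actions.get(i)
        if action == MASK:
            new_nodes.append(LineGraphNode(nd.bond_index, np.zeros_like(nd.x_i),
                                           np.zeros_like(nd.x_j), np.zeros_like(nd.x_e),
                                           is_masked=True))
        elif action == RANDOM:
            src = batch_pool[int(rng.integers(len(batch_pool)))]
            new_nodes.append(LineGraphNode(nd.bond_index, src.x_i.copy(),
                                           src.x_j.copy(), src.x_e.copy()))
        else:
            new_nodes.append(LineGraphNode(nd.bond_index, nd.x_i.copy(),
                                           nd.x_j.copy(), nd.x_e.copy()))
    corrupted_base = LineGraph(new_nodes, g.base.edges, g.base.n_nodes,
                               g.base.smiles_canonical, g.base.dist, g.base.paths,
                               g.base.path_arrays)
    corrupted = AugmentedGraph(
        base=corrupted_base,
        k_index=g.k_index,
        knowledge=g.knowledge * (1.0 - plan.knowledge_mask),
        k_edges=g.k_edges,
        knowledge_mask=plan.knowledge_mask.copy(),
    )
    targets = PretrainTargets(
        selected=np.array(selected, dtype=np.intp),
        node_labels=labels,
        knowledge_values=g.knowledge.copy(),
        knowledge_mask=plan.knowledge_mask.copy(),
    )
    return corrupted, targets


@dataclass
class PretrainLoss:
    node_ce: Tensor
    desc_rmse: Tensor
    fp_ce: Tensor
    total: Tensor
    weights: tuple = (1.0, 1.0, 1.0)

    def as_floats(self) -> dict[str, float]:
        return {
            "node_ce": float(self.node_ce.data),
            "desc_rmse": float(self.desc_rmse.data),
            "fp_ce": float(self.fp_ce.data),
            "total": float(self.total.data),
        }


def pretrain_losses(node_logits: Tensor | None, desc_pred: Tensor, fp_logits: Tensor,
                    targets: PretrainTargets,
                    weights: tuple = (1.0, 1.0, 1.0)) -> PretrainLoss:
    """Three-term loss: node CE + masked-descriptor RMSE + masked-bit BCE.

    Each term averages only over its masked/selected positions; a term with no
    such positions is identically zero and contributes no gradient.
    """
    zero = Tensor(0.0)
    n_sel = len(targets.selected)
    if node_logits is not None and n_sel > 0:
        logp = node_logits.log_softmax(axis=-1)
        picked = logp[np.arange(n_sel), targets.node_labels]
        node_ce = -picked.mean()
    else:
        node_ce = zero

    dmask = targets.knowledge_mask[:N_DESCRIPTORS]
    if dmask.sum() > 0:
        diff = (desc_pred - Tensor(targets.knowledge_values[:N_DESCRIPTORS])) * Tensor(dmask)
        desc_rmse = ((diff * diff).sum() * (1.0 / dmask.sum())) ** 0.5
    else:
        desc_rmse = zero

    fmask = targets.knowledge_mask[N_DESCRIPTORS:]
    if fmask.sum() > 0:
        y = Tensor(targets.knowledge_values[N_DESCRIPTORS:])
        # binary CE with logits: softplus(x) - x*y, stable for any x
        per_bit = fp_logits.softplus() - fp_logits * y
        fp_ce = (per_bit * Tensor(fmask)).sum() * (1.0 / fmask.sum())
    else:
        fp_ce = zero

    w = weights
    total = node_ce * w[0] + desc_rmse * w[1] + fp_ce * w[2]
    return PretrainLoss(node_ce, desc_rmse, fp_ce, total, w)


# ---------------------------------------------------------------------------
# corpus preparation and the training loop


@dataclass
class PretrainConfig:
    light: LiGhTConfig = field(default_factory=LiGhTConfig)
    mask_rate: float = 0.5
    loss_weights: tuple = (1.0, 1.0, 1.0)
    lr: float = 2e-4
    warmup_frac: float = 0.1     # linear LR warmup over this fraction of steps
    lr_schedule: str = "constant"  # "constant" (after warmup) | "cosine"
    weight_decay: float = 1e-6
    batch_size: int = 16
    n_steps: int = 200
    seed: int = 0
    log_every: int = 10


@dataclass
class PreparedMolecule:
    smiles: str
    graph: AugmentedGraph
    raw_descriptors: np.ndarray


@dataclass
class PreparedCorpus:
    molecules: list[PreparedMolecule]
    normalizer: DescriptorNormalizer
    vocab: NodeTypeVocab
    n_skipped: int
    skipped: list[str]


def prepare_corpus(smiles_list, max_path_nodes: int = 5) -> PreparedCorpus:
    """Parse a SMILES corpus into knowledge-augmented line graphs.

    Unparseable entries are skipped (and reported); the descriptor normalizer
    is fitted on the corpus and the node-type vocabulary enumerated from it.
    """
    parsed, skipped, raws = [], [], []
    for smi in smiles_list:
        try:
            mol = parse_smiles(smi)
        except SMILESParseError:
            skipped.append(smi)
            continue
        parsed.append((smi, mol))
        raws.append(compute_descriptors(mol))
    if not parsed:
        raise ValueError("no parseable molecules in the pre-training corpus")
    normalizer = fit_normalizer(raws)
    molecules = []
    lgs = []
    for (smi, mol), raw in zip(parsed, raws):
        lg = to_line_graph(mol, max_path_nodes=max_path_nodes)
        lgs.append(lg)
        kv = build_knowledge_vector(mol, normalizer)
        molecules.append(PreparedMolecule(smi, augment_with_k_node(lg, kv.vector), raw))
    vocab = NodeTypeVocab.build(lgs)
    return PreparedCorpus(molecules, normalizer, vocab, len(skipped), skipped)


@dataclass
class PretrainResult:
    model: LiGhTModel
    node_head: PredictionHead
    desc_head: PredictionHead
    fp_head: PredictionHead
    normalizer: DescriptorNormalizer
    vocab: NodeTypeVocab
    history: list[dict]
    n_skipped: int

    def heads(self) -> dict[str, PredictionHead]:
        return {"node": self.node_head, "desc": self.desc_head, "fp": self.fp_head}


def _pretrain_step_loss(model: LiGhTModel, heads, vocab: NodeTypeVocab,
                        prepared: list[PreparedMolecule],
                        cfg: PretrainConfig, rng: np.random.Generator) -> PretrainLoss:
    node_head, desc_head, fp_head = heads
    pool = [nd for pm in prepared for nd in pm.graph.base.nodes]
    losses = []
    for pm in prepared:
        plan = make_mask_plan(pm.graph, cfg.mask_rate, rng)
        corrupted, targets = corrupt_graph(pm.graph, plan, pool, vocab, rng)
        h, _ = forward(corrupted, model)
        logits = (predict_head(h.take_rows(targets.selected), node_head)
                  if len(targets.selected) else None)
        k_emb = h[corrupted.k_index, :]
        losses.append(pretrain_losses(logits, predict_head(k_emb, desc_head),
                                      predict_head(k_emb, fp_head), targets,
                                      cfg.loss_weights))
    n = float(len(losses))
    agg = PretrainLoss(
        node_ce=sum((l.node_ce for l in losses), Tensor(0.0)) * (1.0 / n),
        desc_rmse=sum((l.desc_rmse for l in losses), Tensor(0.0)) * (1.0 / n),
        fp_ce=sum((l.fp_ce for l in losses), Tensor(0.0)) * (1.0 / n),
        total=sum((l.total for l in losses), Tensor(0.0)) * (1.0 / n),
        weights=cfg.loss_weights,
    )
    return agg


def pretrain_run(corpus, config: PretrainConfig,
                 prepared: PreparedCorpus | None = None,
                 progress: bool = False) -> PretrainResult:
    """Run masked-graph pre-training on a SMILES corpus.

    Fully seeded: two runs with the same corpus and config produce identical
    loss trajectories.  Returns the trained encoder, the three prediction
    heads, the fitted normalizer, the node-type vocabulary and a per-step log
    of the three loss terms.
    """
    if prepared is None:
        prepared = prepare_corpus(corpus, max_path_nodes=config.light.max_path_nodes)
    rng = np.random.default_rng(config.seed)
    model = LiGhTModel.init(config.light, seed=int(rng.integers(2**31)))
    node_head = PredictionHead(config.light.hidden, prepared.vocab.size,
                               seed=int(rng.integers(2**31)), name="node_head")
    desc_head = PredictionHead(config.light.hidden, N_DESCRIPTORS,
                               seed=int(rng.integers(2**31)), name="desc_head")
    fp_head = PredictionHead(config.light.hidden, KNOWLEDGE_DIM - N_DESCRIPTORS,
                             seed=int(rng.integers(2**31)), name="fp_head")
    params = dict(model.params)
    for head in (node_head, desc_head, fp_head):
        params.update(head.params)
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    mols = prepared.molecules
    history = []
    iterator = range(config.n_steps)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="pretrain")
    warmup_steps = int(round(config.warmup_frac * config.n_steps))
    for step in iterator:
        scale = 1.0
        if warmup_steps > 0 and step < warmup_steps:
            scale = (step + 1) / warmup_steps
        elif config.lr_schedule == "cosine":
            progress = (step - warmup_steps) / max(config.n_steps - warmup_steps, 1)
            scale = 0.5 * (1.0 + np.cos(np.pi * progress))
        opt.lr_scale = scale
        batch_idx = rng.choice(len(mols), size=min(config.batch_size, len(mols)),
                               replace=False)
        batch = [mols[i] for i in batch_idx]
        model.train(rng)
        loss = _pretrain_step_loss(model, (node_head, desc_head, fp_head),
                                   prepared.vocab, batch, config, rng)
        opt.zero_grad()
        loss.total.backward()
        opt.step()
        row = {"step": step, **loss.as_floats(), "time": time.time()}
        history.append(row)
    model.eval()
    return PretrainResult(model, node_head, desc_head, fp_head,
                          prepared.normalizer, prepared.vocab, history,
                          prepared.n_skipped)


def masked_node_accuracy(model: LiGhTModel, node_head: PredictionHead,
                         molecules: list[PreparedMolecule], vocab: NodeTypeVocab,
                         rate: float = 0.5, seed: int = 0) -> tuple[float, float]:
    """Held-out masked-node classification accuracy and majority baseline.

    Corrupts each molecule once (seeded), predicts the selected nodes' types,
    and compares against always answering the most frequent true type.
    """
    rng = np.random.default_rng(seed)
    model.eval()
    correct, labels_all = 0, []
    preds_all = []
    pool = [nd for pm in molecules for nd in pm.graph.base.nodes]
    for pm in molecules:
        plan = make_mask_plan(pm.graph, rate, rng)
        corrupted, targets = corrupt_graph(pm.graph, plan, pool, vocab, rng)
        if len(targets.selected) == 0:
            continue
        h, _ = forward(corrupted, model)
        logits = predict_head(h.take_rows(targets.selected), node_head)
        preds = logits.data.argmax(axis=1)
        preds_all.extend(preds.tolist())
        labels_all.extend(targets.node_labels.tolist())
        correct += int((preds == targets.node_labels).sum())
    labels_all = np.array(labels_all)
    accuracy = correct / len(labels_all)
    majority = np.bincount(labels_all).max() / len(labels_all)
    return accuracy, majority
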