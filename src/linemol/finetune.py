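"""Transfer learning on top of a pre-trained encoder.

Two settings: *finetuning*, where the encoder is trainable and four
strategies temper how far it drifts from the pre-trained point, and *feature
extraction*, where the frozen encoder's pooled embeddings ("neural
fingerprints") feed a trainable predictor or a k-nearest-neighbour probe.

Finetuning strategies (independently switchable):

* LLRD — layer-wise learning rate decay: the head and top transformer layer
  train at the base rate; each layer below is decayed geometrically by a
  factor gamma, the embedding/bias block most of all.
* ReInit — re-initialize the top n transformer layers before finetuning,
  discarding the most pre-training-specific weights.
* FLAG — adversarial feature augmentation: gradient-ascent perturbations on
  the initial node embeddings, with the loss averaged over ascent steps.
* L2-SP — an L2 penalty pulling encoder parameters toward their pre-trained
  values (the freshly initialized head has no reference point and is exempt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .checkpoint import Checkpoint
from .knowledge import DescriptorNormalizer, build_knowledge_vector
from .light import LiGhTModel, PredictionHead, embed_nodes, forward, predict_head
from .molgraph import SMILESParseError, augment_with_k_node, parse_smiles, to_line_graph
from .nn import Adam, Tensor, trunc_normal
from .tasks import LabeledSet, SplitAssignment, compute_metrics

__all__ = [
    "FinetuneConfig", "FinetuneResult",
    "llrd_schedule", "build_llrd_groups", "reinit_top", "l2sp_penalty",
    "flag_augmented_loss", "finetune_run",
    "extract_neural_fingerprints", "knn_predict",
]


@dataclass
class FinetuneConfig:
    """Switches and rates for one transfer-learning run.

    Strategy defaults when enabled: gamma 0.95, reinit_top_n 1, flag m=3 with
    alpha 1e-3, l2sp lambda 1e-4; all off unless set.
    """

    mode: str = "finetune"              # "finetune" | "feature_extraction"
    task_type: str = "classification"   # "classification" | "regression"
    n_tasks: int = 1
    base_lr: float = 1e-4
    llrd_gamma: float = 1.0             # 1.0 = no decay
    reinit_top_n: int = 0
    flag_steps: int = 0
    flag_alpha: float = 1e-3
    l2sp_weight: float = 0.0
    epochs: int = 10
    batch_size: int = 16
    weight_decay: float = 1e-6
    dropout: float | None = 0.0         # override encoder dropout; None keeps it
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("finetune", "feature_extraction"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.llrd_gamma <= 1.0:
            raise ValueError("llrd_gamma must lie in (0, 1]")
        if self.reinit_top_n < 0 or self.flag_steps < 0 or self.l2sp_weight < 0:
            raise ValueError("reinit_top_n, flag_steps and l2sp_weight must be >= 0")


def llrd_schedule(n_layers: int, base_lr: float, gamma: float) -> dict:
    """Geometric layer-wise learning rates.

    The head and top layer get ``base_lr``; the i-th layer counted from the
    top gets ``base_lr * gamma**i``; the embedding (and bias-bank) block gets
    ``base_lr * gamma**n_layers``.  Returned dict: ``head``, ``embed`` and
    ``layers`` (a list indexed bottom-up, matching model layer indices).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    layers = [base_lr * gamma ** (n_layers - 1 - l) for l in range(n_layers)]
    return {"head": base_lr, "layers": layers, "embed": base_lr * gamma ** n_layers}


def _encoder_blocks(model: LiGhTModel) -> tuple[dict, list[dict]]:
    """Split encoder params into the embedding/bias block and per-layer dicts."""
    layer_params = [
        {k: v for k, v in model.params.items() if k.startswith(f"layer{l}.")}
        for l in range(model.config.n_layers)
    ]
    in_layers = {k for d in layer_params for k in d}
    embed = {k: v for k, v in model.params.items() if k not in in_layers}
    return embed, layer_params


def build_llrd_groups(model: LiGhTModel, head: PredictionHead,
                      base_lr: float, gamma: float) -> list[tuple[dict, float]]:
    sched = llrd_schedule(model.config.n_layers, base_lr, gamma)
    embed, layer_params = _encoder_blocks(model)
    groups: list[tuple[dict, float]] = [(head.params, sched["head"])]
    for l, params in enumerate(layer_params):
        groups.append((params, sched["layers"][l]))
    groups.append((embed, sched["embed"]))
    return groups


def reinit_top(model: LiGhTModel, n: int, seed: int = 0) -> LiGhTModel:
    """Freshly initialize the parameters of the top ``n`` transformer layers.

    Every other parameter is left bitwise-unchanged.  Mutates and returns the
    model.
    """
    L = model.config.n_layers
    if not 0 <= n <= L:
        raise ValueError(f"reinit_top n={n} outside [0, {L}]")
    rng = np.random.default_rng(seed)
    D = model.config.hidden
    for l in range(L - n, L):
        for suffix, shape in (("Wq", (D, D)), ("Wk", (D, D)), ("Wv", (D, D)),
                              ("W1", (4 * D, D)), ("W2", (D, 4 * D))):
            model.params[f"layer{l}.{suffix}"].data = trunc_normal(shape, 0.02, rng)
        for suffix in ("bq", "bk", "bv", "b1", "b2", "ln1.beta", "ln2.beta"):
            p = model.params[f"layer{l}.{suffix}"]
            p.data = np.zeros_like(p.data)
        for suffix in ("ln1.gamma", "ln2.gamma"):
            p = model.params[f"layer{l}.{suffix}"]
            p.data = np.ones_like(p.data)
    return model


def l2sp_penalty(model: LiGhTModel, reference: dict[str, np.ndarray],
                 weight: float) -> Tensor:
    """lambda * sum ||theta - theta_ref||^2 over encoder parameters."""
    if weight == 0.0:
        return Tensor(0.0)
    total = Tensor(0.0)
    for name, p in model.params.items():
        ref = reference[name]
        if ref.shape != p.data.shape:
            raise ValueError(f"reference shape mismatch for {name}")
        d = p - Tensor(ref)
        total = total + (d * d).sum()
    return total * weight


def flag_augmented_loss(loss_of_h0, h0: Tensor, m: int, alpha: float,
                        scale: float = 1.0) -> float:
    """FLAG: adversarial ascent on initial node embeddings.

    ``loss_of_h0`` maps an initial-embedding Tensor to a scalar loss Tensor;
    ``h0`` stays attached to the graph, so embedding weights keep training.
    With m == 0 this is exactly one plain backward pass.  Otherwise the
    perturbation delta takes m sign-gradient ascent steps of size alpha
    (so ||delta||_inf <= m * alpha), and parameter gradients accumulate as
    the mean of the m step losses.  Returns the (mean) loss value; gradients
    are left accumulated on the parameters.
    """
    if m == 0:
        loss = loss_of_h0(h0) * scale
        loss.backward()
        return float(loss.data) / scale
    delta = np.zeros(h0.shape)
    total = 0.0
    for _ in range(m):
        delta_t = Tensor(delta, requires_grad=True)
        loss = loss_of_h0(h0 + delta_t) * (scale / m)
        loss.backward()
        total += float(loss.data) * m / scale
        if delta_t.grad is not None:
            delta = delta + alpha * np.sign(delta_t.grad)
    return total / m


# ---------------------------------------------------------------------------
# the finetuning loop


@dataclass
class FinetuneResult:
    model: LiGhTModel
    head: PredictionHead
    history: list[dict]
    best_epoch: int
    valid_metrics: dict
    test_metrics: dict
    config: FinetuneConfig


def _prepare_graphs(smiles_list, normalizer: DescriptorNormalizer,
                    max_path_nodes: int):
    graphs = []
    for smi in smiles_list:
        mol = parse_smiles(smi)
        lg = to_line_graph(mol, max_path_nodes=max_path_nodes)
        kv = build_knowledge_vector(mol, normalizer)
        graphs.append(augment_with_k_node(lg, kv.vector))
    return graphs


def _supervised_loss(logits: Tensor, y_row: np.ndarray, task_type: str) -> Tensor:
    """Per-molecule loss with missing-label masking (NaN labels skipped)."""
    mask = np.isfinite(y_row).astype(float)
    y = np.where(mask > 0, y_row, 0.0)
    if mask.sum() == 0:
        return Tensor(0.0)
    if task_type == "classification":
        per = logits.softplus() - logits * Tensor(y)
    else:
        d = logits - Tensor(y)
        per = d * d
    return (per * Tensor(mask)).sum() * (1.0 / mask.sum())


def _scores(model, head, graphs) -> np.ndarray:
    model.eval()
    out = []
    for g in graphs:
        _, pooled = forward(g, model)
        out.append(predict_head(pooled, head).data)
    return np.stack(out)


def _val_score(metrics: dict, task_type: str) -> float:
    # higher is better: AUROC for classification, -RMSE for regression
    if task_type == "classification":
        return -np.inf if metrics.get("auroc") is None else metrics["auroc"]
    return -metrics["rmse"]


def finetune_run(ckpt: Checkpoint, dataset: LabeledSet, split: SplitAssignment,
                 cfg: FinetuneConfig) -> FinetuneResult:
    """Train a predictor on a labeled set starting from a pre-trained encoder.

    The epoch whose validation metric (AUROC up / RMSE down) is best selects
    the reported parameters; test metrics are computed once, at that epoch.
    Fully seeded and deterministic.
    """
    if not split.train or not split.valid or not split.test:
        raise ValueError("empty split")
    if cfg.n_tasks != dataset.n_tasks:
        raise ValueError(f"config n_tasks={cfg.n_tasks} != dataset n_tasks={dataset.n_tasks}")
    model = ckpt.model
    if cfg.dropout is not None:
        model.config.dropout = cfg.dropout
    if cfg.reinit_top_n and cfg.mode == "finetune":
        reinit_top(model, cfg.reinit_top_n, seed=cfg.seed + 1)
    reference = {k: v.data.copy() for k, v in model.params.items()}
    head = PredictionHead(model.config.hidden, cfg.n_tasks, seed=cfg.seed + 2)

    graphs = _prepare_graphs(dataset.smiles, ckpt.normalizer,
                             model.config.max_path_nodes)
    rng = np.random.default_rng(cfg.seed)

    if cfg.mode == "feature_extraction":
        opt = Adam(head.params, lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    else:
        groups = build_llrd_groups(model, head, cfg.base_lr, cfg.llrd_gamma)
        opt = Adam(groups, lr=cfg.base_lr, weight_decay=cfg.weight_decay)

    trainable_encoder = cfg.mode == "finetune"
    history = []
    best = (-np.inf, -1, None, None)  # score, epoch, model params, head params
    train_idx = list(split.train)
    for epoch in range(cfg.epochs):
        rng.shuffle(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(train_idx), cfg.batch_size):
            batch = train_idx[start:start + cfg.batch_size]
            opt.zero_grad()
            scale = 1.0 / len(batch)
            batch_loss = 0.0
            for i in batch:
                g = graphs[i]
                y_row = dataset.labels[i]
                if trainable_encoder:
                    model.train(rng)

                def loss_of_h0(h0, g=g, y_row=y_row):
                    _, pooled = forward(g, model, h0=h0)
                    logits = predict_head(pooled, head)
                    loss = _supervised_loss(logits, y_row, cfg.task_type)
                    if trainable_encoder and cfg.l2sp_weight > 0:
                        loss = loss + l2sp_penalty(model, reference, cfg.l2sp_weight)
                    return loss

                h0 = embed_nodes(g, model)
                if trainable_encoder:
                    batch_loss += flag_augmented_loss(
                        loss_of_h0, h0, cfg.flag_steps, cfg.flag_alpha, scale)
                else:
                    loss = loss_of_h0(Tensor(h0.data)) * scale
                    loss.backward()
                    batch_loss += float(loss.data) / scale
                model.eval()
            if not trainable_encoder:
                for p in model.params.values():
                    p.grad = None
            opt.step()
            epoch_loss += batch_loss / len(batch)
            n_batches += 1
        val_scores = _scores(model, head, [graphs[i] for i in split.valid])
        if cfg.task_type == "classification":
            val_scores = 1.0 / (1.0 + np.exp(-val_scores))
        vm = compute_metrics(dataset.labels[split.valid], val_scores, cfg.task_type)
        score = _val_score(vm, cfg.task_type)
        history.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                        **{f"valid_{k}": v for k, v in vm.items()
                           if not isinstance(v, list)}})
        if score > best[0]:
            best = (score, epoch,
                    {k: v.data.copy() for k, v in model.params.items()},
                    {k: v.data.copy() for k, v in head.params.items()})

    _, best_epoch, best_model, best_head = best
    if best_model is None:
        # validation metric undefined throughout; keep the final epoch
        best_epoch = len(history) - 1
    else:
        for k, v in model.params.items():
            v.data = best_model[k]
        for k, v in head.params.items():
            v.data = best_head[k]
    val_scores = _scores(model, head, [graphs[i] for i in split.valid])
    test_scores = _scores(model, head, [graphs[i] for i in split.test])
    if cfg.task_type == "classification":
        val_scores = 1.0 / (1.0 + np.exp(-val_scores))
        test_scores = 1.0 / (1.0 + np.exp(-test_scores))
    valid_metrics = compute_metrics(dataset.labels[split.valid], val_scores, cfg.task_type)
    test_metrics = compute_metrics(dataset.labels[split.test], test_scores, cfg.task_type)
    return FinetuneResult(model, head, history, best_epoch, valid_metrics,
                          test_metrics, cfg)


# ---------------------------------------------------------------------------
# feature extraction


def extract_neural_fingerprints(ckpt: Checkpoint | LiGhTModel, smiles_list,
                                normalizer: DescriptorNormalizer | None = None,
                                on_error: str = "raise"):
    """Pooled encoder embeddings for a list of SMILES, one row per input.

    ``on_error='raise'`` fails on the first unparseable SMILES, reporting all
    offending indices; ``on_error='drop'`` returns (matrix, kept_indices).
    """
    if isinstance(ckpt, Checkpoint):
        model = ckpt.model
        normalizer = normalizer or ckpt.normalizer
    else:
        model = ckpt
    if normalizer is None:
        raise ValueError("a descriptor normalizer is required")
    model.eval()
    rows, kept, failed = [], [], []
    for i, smi in enumerate(smiles_list):
        try:
            mol = parse_smiles(smi)
        except SMILESParseError:
            failed.append(i)
            continue
        lg = to_line_graph(mol, max_path_nodes=model.config.max_path_nodes)
        g = augment_with_k_node(lg, build_knowledge_vector(mol, normalizer).vector)
        _, pooled = forward(g, model)
        rows.append(pooled.data)
        kept.append(i)
    if failed and on_error == "raise":
        raise ValueError(f"unparseable SMILES at indices {failed}")
    X = np.stack(rows) if rows else np.zeros((0, model.config.hidden))
    if on_error == "drop":
        return X, kept
    return X


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                k: int) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean k-nearest-neighbour majority vote.

    Returns (predicted labels, positive-vote fractions).  Distance ties are
    broken by the smaller training index; a split vote falls back to the
    nearest neighbour's label.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y).ravel()
    n_train = train_X.shape[0]
    if not 1 <= k <= n_train:
        raise ValueError(f"k={k} outside [1, {n_train}]")
    d2 = ((test_X[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = train_y[order]
    prob = votes.mean(axis=1)
    pred = np.where(prob > 0.5, 1.0, np.where(prob < 0.5, 0.0, votes[:, 0]))
    return pred, prob
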