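"""Fine-tuning objectives: masked-token, group classification, contrastive.

All three losses are the negative-log-likelihood / hybrid forms used for
adapter fine-tuning of protein encoders:

* masked-token:      Loss = -sum_i log P(true_token_i | context)
* classification:    Loss = -sum_i log P(true_group_i | x_i)
* contrastive pair:  Loss = alpha * |t - cos(A,B)| + (1-alpha) * (cos(A,B) - t)^2
  with targets t=1 for anchor-positive and t=0 for anchor-negative pairs
  ("similarity-target" mode).  A literal "vector-mse" alternative,
  alpha*(1-cos) + (1-alpha)*mean((A-B)^2), is available for positive pairs
  only — applied to a negative pair it would pull the vectors together,
  which contradicts the triplet objective.

The loss functions accept either plain numpy arrays (returning a float) or
autodiff tensors (returning a differentiable scalar); the training loop
uses the tensor path and updates only LoRA factors plus the task head with
Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, log_softmax
from .data import OrthologGroupSet, SplitResult, sample_triplets
from .encoder import AdaptedEncoder
from .vocab import AminoAcidVocabulary, tokenize


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedBatch:
    input_tokens: tuple[int, ...]
    selected_positions: tuple[int, ...]
    original_tokens: tuple[int, ...]


def apply_masking(
    tokens: list[int],
    vocab: AminoAcidVocabulary,
    select_frac: float = 0.15,
    mask_token_prob: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MaskedBatch:
    """Select ``round(select_frac * L)`` residue positions (at least one) and
    replace each by the mask token with probability ``mask_token_prob``.

    Selected-but-unreplaced positions keep their original token; every
    selected position is scored by the loss either way.  Special tokens are
    never selected.
    """
    if not tokens:
        raise ValueError("cannot mask an empty token sequence")
    if not 0 < select_frac < 1:
        raise ValueError("select_frac must lie in (0, 1)")
    if not 0 < mask_token_prob <= 1:
        raise ValueError("mask_token_prob must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    residue_positions = [i for i, t in enumerate(tokens) if not vocab.is_special(t)]
    L = len(residue_positions)
    if L == 0:
        raise ValueError("sequence contains no residue positions to mask")
    n_select = max(1, int(np.floor(select_frac * L + 0.5)))
    chosen = rng.choice(L, size=n_select, replace=False)
    selected = tuple(sorted(residue_positions[i] for i in chosen))
    masked = list(tokens)
    originals = []
    for pos in selected:
        originals.append(tokens[pos])
        if rng.random() < mask_token_prob:
            masked[pos] = vocab.mask_id
    return MaskedBatch(tuple(masked), selected, tuple(originals))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _finalize(loss: Tensor, was_array: bool):
    return float(loss.data) if was_array else loss


def mlm_loss(logits, original_tokens, reduction: str = "sum"):
    """Negative log-likelihood of the true tokens at the selected positions.

    ``logits`` is an N x V matrix (one row per selected position); natural
    log; ``reduction`` is "sum" (the written form) or "mean".
    """
    was_array = not isinstance(logits, Tensor)
    logits = as_tensor(logits)
    targets = np.asarray(original_tokens, dtype=np.intp)
    if logits.shape[0] != len(targets):
        raise ValueError(
            f"{logits.shape[0]} logit rows for {len(targets)} selected positions"
        )
    logp = log_softmax(logits, axis=-1)
    picked = logp[(np.arange(len(targets)), targets)]
    loss = -(picked.mean() if reduction == "mean" else picked.sum())
    return _finalize(loss, was_array)


def cross_entropy(logits, labels, reduction: str = "sum"):
    """Softmax cross-entropy of an N x G logit matrix against integer labels."""
    was_array = not isinstance(logits, Tensor)
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n_classes = logits.shape[-1]
    if labels.min(initial=0) < 0 or labels.max(initial=-1) >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    logp = log_softmax(logits, axis=-1)
    picked = logp[(np.arange(len(labels)), labels)]
    loss = -(picked.mean() if reduction == "mean" else picked.sum())
    return _finalize(loss, was_array)


class ClassificationHead:
    """Single affine map from pooled embeddings to group logits."""

    def __init__(self, embedding_dim: int, n_groups: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = Tensor(rng.normal(0.0, 0.02, (embedding_dim, n_groups)), requires_grad=True)
        self.b = Tensor(np.zeros(n_groups), requires_grad=True)

    def __call__(self, pooled) -> Tensor:
        return as_tensor(pooled) @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def classification_loss(pooled, head: ClassificationHead, labels, reduction: str = "sum"):
    """Cross-entropy of head(pooled) against orthologous-group labels."""
    was_array = not isinstance(pooled, Tensor)
    loss = cross_entropy(head(as_tensor(pooled)), labels, reduction=reduction)
    return _finalize(loss, was_array)


def _cosine_t(a: Tensor, b: Tensor) -> Tensor:
    na = (a * a).sum() ** 0.5
    nb = (b * b).sum() ** 0.5
    if float(na.data) == 0.0 or float(nb.data) == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return (a * b).sum() / (na * nb)


def hybrid_pair_loss(
    a,
    b,
    target_sim: float,
    alpha_weight: float = 0.5,
    mode: str = "similarity-target",
):
    """Hybrid cosine / MSE loss for one embedding pair.

    ``similarity-target`` (default): alpha*|t - cos| + (1-alpha)*(cos - t)^2,
    pushing the cosine toward the target (1 for positives, 0 for negatives).
    ``vector-mse``: alpha*(1 - cos) + (1-alpha)*mean((a-b)^2); only valid
    for target_sim == 1.
    """
    if not 0 <= alpha_weight <= 1:
        raise ValueError("alpha_weight must lie in [0, 1]")
    was_array = not isinstance(a, Tensor) and not isinstance(b, Tensor)
    a, b = as_tensor(a), as_tensor(b)
    cos = _cosine_t(a, b)
    if mode == "similarity-target":
        loss = alpha_weight * (target_sim - cos).abs() + (1 - alpha_weight) * (
            cos - target_sim
        ) ** 2
    elif mode == "vector-mse":
        if target_sim != 1:
            raise ValueError("vector-mse mode is only defined for positive pairs")
        diff = a - b
        loss = alpha_weight * (1 - cos) + (1 - alpha_weight) * (diff * diff).mean()
    else:
        raise ValueError(f"unknown hybrid loss mode {mode!r}")
    return _finalize(loss, was_array)


def triplet_loss(anchor, positive, negative, alpha_weight: float = 0.5,
                 mode: str = "similarity-target"):
    """Anchor-positive pair scored against 1 plus anchor-negative against 0."""
    was_array = not any(isinstance(v, Tensor) for v in (anchor, positive, negative))
    anchor = as_tensor(anchor)
    loss = hybrid_pair_loss(anchor, positive, 1.0, alpha_weight, mode=mode) + \
        hybrid_pair_loss(anchor, negative, 0.0, alpha_weight)
    return _finalize(loss, was_array)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyper-parameters.

    The learning-rate default of 1e-9 is the setting recorded for full-size
    encoder fine-tuning; on the tiny reference encoder it produces no
    measurable update, so desk-scale runs typically pass 1e-3.
    """

    objective: str = "con"  # one of mlm / cls / con
    learning_rate: float = 1e-9
    epochs: int = 2
    alpha_weight: float = 0.5
    select_frac: float = 0.15
    mask_token_prob: float = 0.8
    batch_size: int = 4
    max_steps: int | None = None
    triplets_per_epoch: int | None = None
    reduction: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.objective not in ("mlm", "cls", "con"):
            raise ValueError("objective must be one of 'mlm', 'cls', 'con'")
        if not 0 <= self.alpha_weight <= 1:
            raise ValueError("alpha_weight must lie in [0, 1]")
        if not 0 < self.select_frac < 1:
            raise ValueError("select_frac must lie in (0, 1)")


class Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainResult:
    encoder: AdaptedEncoder
    head: ClassificationHead | None
    history: list[dict]
    manifest: dict = field(default_factory=dict)


def _pooled(encoder, sequence: str) -> Tensor:
    hidden, _, ids = encoder.encode(sequence)
    vocab = encoder.vocab
    keep = [i for i, t in enumerate(ids) if not vocab.is_special(t)]
    return hidden[np.asarray(keep, dtype=np.intp)].mean(axis=0)


def _epoch_losses(encoder, data, ids, config, label_map, head, rng,
                  train: bool, optimizer=None, step_budget=None):
    """One pass over the data; returns (mean loss, steps used)."""
    vocab = encoder.vocab
    total, count, steps = 0.0, 0, 0
    if config.objective == "con":
        n = config.triplets_per_epoch or max(len(ids), config.batch_size)
        if train:
            triplets = sample_triplets(
                data.subset(ids), n, seed=int(rng.integers(2**31))
            )
        else:
            # held-out anchors; positives/negatives may come from the full
            # set, since one-member-per-group test splits admit no
            # within-subset positives
            triplets = sample_triplets(
                data, n, seed=int(rng.integers(2**31)), anchor_ids=ids
            )
        for start in range(0, len(triplets), config.batch_size):
            batch = triplets[start : start + config.batch_size]
            losses = []
            for a, p, ng in batch:
                la = triplet_loss(
                    _pooled(encoder, data[a].sequence),
                    _pooled(encoder, data[p].sequence),
                    _pooled(encoder, data[ng].sequence),
                    alpha_weight=config.alpha_weight,
                )
                losses.append(la)
            loss = sum(losses[1:], losses[0]) * (1.0 / len(losses))
            total += float(loss.data) * len(losses)
            count += len(losses)
            if train:
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                steps += 1
                if step_budget is not None and steps >= step_budget:
                    break
        return total / max(count, 1), steps

    order = list(ids)
    rng.shuffle(order)
    for start in range(0, len(order), config.batch_size):
        batch = order[start : start + config.batch_size]
        losses = []
        n_items = 0
        for sid in batch:
            seq = data[sid].sequence
            tokens = tokenize(seq, vocab, encoder.config.max_sequence_length)
            if config.objective == "mlm":
                masked = apply_masking(
                    tokens, vocab, config.select_frac, config.mask_token_prob, rng=rng
                )
                _, logits = encoder.forward(masked.input_tokens)
                sel = np.asarray(masked.selected_positions, dtype=np.intp)
                loss_i = mlm_loss(
                    logits[sel], masked.original_tokens, reduction=config.reduction
                )
            else:  # cls
                pooled = _pooled(encoder, seq)
                logits = head(pooled.reshape(1, -1))
                loss_i = cross_entropy(
                    logits, [label_map[data[sid].group_id]], reduction="sum"
                )
            n_items += 1
            losses.append(loss_i)
        loss = sum(losses[1:], losses[0]) * (1.0 / max(n_items, 1))
        total += float(loss.data) * n_items
        count += n_items
        if train:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            steps += 1
            if step_budget is not None and steps >= step_budget:
                break
    return total / max(count, 1), steps


def train(
    encoder: AdaptedEncoder,
    data: OrthologGroupSet,
    config: TrainConfig,
    split: SplitResult | None = None,
) -> TrainResult:
    """Seeded fine-tuning loop updating only LoRA factors and the task head.

    Returns the adapted encoder together with a per-epoch loss trajectory
    (train loss, and test loss when a held-out split is supplied).  The
    frozen base weights are guaranteed untouched; callers can verify via
    ``encoder.base_weight_hash()``.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    if config.objective in ("cls", "con") and len(data.groups) < 2:
        raise ValueError(f"objective {config.objective!r} needs at least two groups")

    train_ids = sorted(split.train_ids) if split is not None else sorted(
        r.id for r in data.records
    )
    test_ids = sorted(split.test_ids) if split is not None else []

    label_map = {g: i for i, g in enumerate(data.group_ids)}
    head = None
    params = encoder.trainable_parameters()
    if config.objective == "cls":
        head = ClassificationHead(
            encoder.config.embedding_dim, len(label_map), seed=config.seed
        )
        params = params + head.parameters()
    optimizer = Adam(params, lr=config.learning_rate)

    history: list[dict] = []
    steps_done = 0
    for epoch in range(config.epochs):
        # Each epoch re-seeds its sampling stream identically, so the data
        # order, masks, and triplets are a fixed function of config.seed.
        # With a zero learning rate the loss trajectory is therefore
        # constant — a useful determinism check.
        rng = np.random.default_rng(config.seed)
        budget = None if config.max_steps is None else config.max_steps - steps_done
        if budget is not None and budget <= 0:
            break
        train_loss, steps = _epoch_losses(
            encoder, data, train_ids, config, label_map, head, rng,
            train=True, optimizer=optimizer, step_budget=budget,
        )
        steps_done += steps
        entry = {"epoch": epoch, "train_loss": train_loss, "steps": steps_done}
        if test_ids:
            eval_rng = np.random.default_rng(config.seed + 10_000 + epoch)
            test_loss, _ = _epoch_losses(
                encoder, data, test_ids, config, label_map, head, eval_rng, train=False
            )
            entry["test_loss"] = test_loss
        history.append(entry)

    manifest = {
        "config": {**config.__dict__},
        "n_sequences": len(data),
        "n_groups": len(data.groups),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "trainable_parameters": sum(p.data.size for p in params),
        "loss_reduction": config.reduction,
        "history": history,
    }
    return TrainResult(encoder, head, history, manifest)
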