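"""Masking rules, closed-form loss values, and training-loop behaviour."""

import numpy as np
import pytest

from plmtune import (
    LoRAConfig,
    SyntheticFamilyConfig,
    TrainConfig,
    apply_masking,
    cross_entropy,
    classification_loss,
    generate_families,
    hybrid_pair_loss,
    inject_lora,
    mlm_loss,
    train,
    triplet_loss,
)
from plmtune.objectives import ClassificationHead


# -- masking ----------------------------------------------------------------

def test_masking_selects_exact_count_of_distinct_residues(vocab):
    tokens = vocab.encode("A" * 100)
    batch = apply_masking(tokens, vocab, select_frac=0.15, seed=0)
    assert len(batch.selected_positions) == 15
    assert len(set(batch.selected_positions)) == 15


def test_masking_probability_one_masks_every_selected(vocab):
    tokens = vocab.encode("ACDEFGHIKL" * 3)
    batch = apply_masking(tokens, vocab, mask_token_prob=1.0, seed=1)
    assert all(batch.input_tokens[p] == vocab.mask_id for p in batch.selected_positions)
    assert all(batch.original_tokens[i] == tokens[p]
               for i, p in enumerate(batch.selected_positions))


def test_masking_never_touches_special_tokens():
    from plmtune import AminoAcidVocabulary
    vocab = AminoAcidVocabulary(include_bos_eos=True)
    tokens = vocab.encode("ACDEFGHIKL")
    batch = apply_masking(tokens, vocab, seed=2)
    assert all(0 < p < len(tokens) - 1 for p in batch.selected_positions)


def test_masked_fraction_concentrates_at_mask_token_prob(vocab):
    rng = np.random.default_rng(3)
    masked = total = 0
    tokens = vocab.encode("ACDEFGHIKLMNPQRSTVWY" * 5)
    while total < 10_000:
        batch = apply_masking(tokens, vocab, mask_token_prob=0.8, rng=rng)
        for p in batch.selected_positions:
            total += 1
            masked += batch.input_tokens[p] == vocab.mask_id
    assert abs(masked / total - 0.8) < 0.02


def test_length_one_sequence_still_selects_one(vocab):
    batch = apply_masking(vocab.encode("A"), vocab, seed=0)
    assert len(batch.selected_positions) == 1


# -- closed-form losses -----------------------------------------------------

def test_mlm_loss_uniform_logits_closed_form():
    assert mlm_loss(np.zeros((3, 25)), [0, 5, 24]) == pytest.approx(3 * np.log(25), abs=1e-9)


def test_mlm_loss_confident_and_extreme_logits():
    logits = np.full((2, 10), -1e4)
    logits[0, 3] = logits[1, 7] = 1e4
    assert mlm_loss(logits, [3, 7]) == pytest.approx(0.0, abs=1e-6)
    assert np.isfinite(mlm_loss(np.array([[1e9, -1e9]]), [1]))  # no NaN/overflow


def test_mlm_loss_half_probability():
    # two equal logits -> probability 0.5 on the true token
    assert mlm_loss(np.array([[0.0, 0.0, -1e9]]), [0]) == pytest.approx(np.log(2), abs=1e-9)


def test_classification_loss_uniform_logits():
    assert cross_entropy(np.zeros((4, 10)), [0, 1, 2, 3]) == pytest.approx(
        4 * np.log(10), abs=1e-9
    )
    assert cross_entropy(np.zeros((1, 2)), [1]) == pytest.approx(np.log(2), abs=1e-9)


def test_classification_loss_label_out_of_range():
    head = ClassificationHead(4, 3, seed=0)
    with pytest.raises(ValueError):
        classification_loss(np.ones((1, 4)), head, [3])


def test_hybrid_pair_loss_edge_cases():
    u = np.array([1.0, 0.0])
    v = np.array([0.0, 1.0])
    for alpha in (0.0, 0.3, 1.0):
        assert hybrid_pair_loss(u, u, 1.0, alpha) == pytest.approx(0.0, abs=1e-12)
        assert hybrid_pair_loss(u, u, 1.0, alpha, mode="vector-mse") == pytest.approx(0.0, abs=1e-12)
    assert hybrid_pair_loss(u, v, 1.0, 1.0) == pytest.approx(1.0, abs=1e-12)
    # identical vectors scored as a negative pair at alpha = 0.5
    assert hybrid_pair_loss(u, u, 0.0, 0.5) == pytest.approx(1.0, abs=1e-12)


def test_vector_mse_mode_rejects_negative_pairs():
    with pytest.raises(ValueError):
        hybrid_pair_loss(np.ones(3), np.ones(3), 0.0, 0.5, mode="vector-mse")


def test_zero_vector_cosine_rejected():
    with pytest.raises(ValueError):
        hybrid_pair_loss(np.zeros(3), np.ones(3), 1.0)


def test_triplet_loss_values_and_monotonicity():
    a = np.array([1.0, 0.0])
    perp = np.array([0.0, 1.0])
    assert triplet_loss(a, a, perp, 0.5) == pytest.approx(0.0, abs=1e-12)
    assert triplet_loss(a, a, a, 0.5) == pytest.approx(1.0, abs=1e-12)
    # rotating the negative from parallel to orthogonal strictly lowers the loss
    losses = []
    for t in np.linspace(0.0, np.pi / 2, 10):
        neg = np.array([np.cos(t), np.sin(t)])
        losses.append(triplet_loss(a, a, neg, 0.5))
    assert all(l2 < l1 for l1, l2 in zip(losses, losses[1:]))


# -- training loop ----------------------------------------------------------

@pytest.fixture(scope="module")
def train_data():
    data, _ = generate_families(SyntheticFamilyConfig(
        n_groups=4, members_per_group=6, ancestor_length=30,
        conserved_blocks=((5, 8),), substitution_rate=0.3, seed=2,
    ))
    return data


def test_zero_learning_rate_is_identity(tiny_encoder, train_data):
    adapted = inject_lora(tiny_encoder, LoRAConfig(rank_r=4, init_seed=1))
    before = {k: (A.data.copy(), B.data.copy()) for k, (A, B) in adapted.factors.items()}
    result = train(adapted, train_data, TrainConfig(
        objective="con", learning_rate=0.0, epochs=3, max_steps=None,
        triplets_per_epoch=8, seed=0,
    ))
    losses = [h["train_loss"] for h in result.history]
    assert len(set(losses)) == 1  # constant trajectory
    for k, (A, B) in adapted.factors.items():
        np.testing.assert_array_equal(A.data, before[k][0])
        np.testing.assert_array_equal(B.data, before[k][1])


@pytest.mark.parametrize("objective", ["mlm", "cls", "con"])
def test_training_reduces_loss_and_is_deterministic(tiny_encoder, train_data, objective):
    def run():
        adapted = inject_lora(tiny_encoder, LoRAConfig(rank_r=4, init_seed=1))
        cfg = TrainConfig(objective=objective, learning_rate=1e-2, epochs=4,
                          batch_size=4, triplets_per_epoch=16, seed=0)
        return train(adapted, train_data, cfg).history

    h1, h2 = run(), run()
    assert h1 == h2  # bitwise-identical trajectories for identical seeds
    assert h1[-1]["train_loss"] < h1[0]["train_loss"]


def test_contrastive_training_needs_two_groups(tiny_encoder, train_data):
    single = train_data.subset(train_data.members(train_data.group_ids[0]))
    adapted = inject_lora(tiny_encoder, LoRAConfig(rank_r=4))
    with pytest.raises(ValueError):
        train(adapted, single, TrainConfig(objective="con", seed=0))


def test_cls_training_reaches_above_chance_heldout_accuracy(tiny_encoder, train_data):
    from plmtune import stratified_split
    from plmtune.objectives import _pooled

    split = stratified_split(train_data, test_fraction=0.2, seed=0)
    adapted = inject_lora(tiny_encoder, LoRAConfig(rank_r=4, init_seed=1))
    result = train(adapted, train_data, TrainConfig(
        objective="cls", learning_rate=2e-2, epochs=10, batch_size=6, seed=0,
    ), split=split)
    label_map = {g: i for i, g in enumerate(train_data.group_ids)}
    correct = 0
    test_ids = sorted(split.test_ids)
    for sid in test_ids:
        logits = result.head(_pooled(adapted, train_data[sid].sequence).reshape(1, -1))
        correct += int(np.argmax(logits.data)) == label_map[train_data[sid].group_id]
    assert correct / len(test_ids) > 1 / len(label_map)  # above chance
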