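"""Pre-training objectives: closed forms, oracles, queue and schedule behavior."""

import numpy as np
import pytest
from scipy import stats as sps

from pvlm import nn
from pvlm.nn import Tensor
from pvlm.pretrain import (FeatureQueue, LossBundle, contrastive_loss,
                           intermodal_similarities, npp_loss, nwp_loss,
                           select_hard_negatives, similarity, spm_loss,
                           soft_cross_entropy, PretrainSchedule)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------
def test_similarity_identical_projection_is_one():
    v = np.array([[0.6, 0.8]])
    assert similarity(v, v)[0, 0] == pytest.approx(1.0)


def test_similarity_orthogonal_is_zero():
    a, b = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
    assert similarity(a, b)[0, 0] == pytest.approx(0.0)


def test_similarity_matches_normalize_then_dot_oracle():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(4, 8))
    b = rng.normal(size=(4, 8))
    a_n = a / np.linalg.norm(a, axis=1, keepdims=True)
    b_n = b / np.linalg.norm(b, axis=1, keepdims=True)
    expected = np.array([[a_n[i] @ b_n[j] for j in range(4)] for i in range(4)])
    np.testing.assert_allclose(similarity(a_n, b_n), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# temperature softmax distributions
# ---------------------------------------------------------------------------
def test_single_candidate_distribution_is_one():
    anchor = Tensor(np.array([[1.0, 0.0]]))
    cands = np.array([[0.3, 0.4]])
    d = intermodal_similarities(anchor, cands, 0.07)
    np.testing.assert_allclose(d.data, [[1.0]])


def test_equal_similarities_give_uniform():
    anchor = Tensor(np.array([[1.0, 0.0]]))
    cands = np.tile([[0.5, 0.5]], (6, 1))
    d = intermodal_similarities(anchor, cands, 0.1)
    np.testing.assert_allclose(d.data, 1.0 / 6, atol=1e-12)


def test_softmax_rows_match_hand_oracle():
    rng = np.random.default_rng(1)
    anchor, cands, tau = rng.normal(size=(3, 5)), rng.normal(size=(3, 5)), 0.1
    d = intermodal_similarities(Tensor(anchor), cands, tau).data
    for i in range(3):
        logits = np.array([anchor[i] @ cands[j] / tau for j in range(3)])
        expect = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(d[i], expect, atol=1e-6)
    assert np.allclose(d.sum(axis=1), 1.0)


def test_nonpositive_temperature_errors():
    with pytest.raises(ValueError, match="temperature"):
        intermodal_similarities(Tensor(np.ones((1, 2))), np.ones((1, 2)), 0.0)


# ---------------------------------------------------------------------------
# contrastive loss
# ---------------------------------------------------------------------------
def _uniform_dists(B, N):
    return {k: Tensor(np.full((B, N), 1.0 / N)) for k in ("s2p", "p2s", "s2s", "p2p")}


def _onehot_targets(B, N):
    t = np.zeros((B, N))
    t[np.arange(B), np.arange(B)] = 1.0
    return {k: t for k in ("s2p", "p2s", "s2s", "p2p")}


def test_contrastive_zero_when_prediction_equals_onehot():
    B = 3
    targets = _onehot_targets(B, B)
    dists = {k: Tensor(v.copy()) for k, v in targets.items()}
    loss = contrastive_loss(dists, targets, None, alpha=0.0)
    assert loss.item() == pytest.approx(0.0, abs=1e-9)


def test_contrastive_uniform_closed_form_2lnN():
    B, N = 2, 7
    loss = contrastive_loss(_uniform_dists(B, N), _onehot_targets(B, N), None, 0.0)
    assert loss.item() == pytest.approx(2 * np.log(N), rel=1e-9)


def test_contrastive_alpha_mix_matches_naive_oracle():
    rng = np.random.default_rng(2)
    B, N, alpha = 2, 4, 0.4
    dists, momentum = {}, {}
    for k in ("s2p", "p2s", "s2s", "p2p"):
        d = rng.random((B, N)); d /= d.sum(1, keepdims=True)
        m = rng.random((B, N)); m /= m.sum(1, keepdims=True)
        dists[k] = Tensor(d)
        momentum[k] = m
    targets = _onehot_targets(B, N)
    loss = contrastive_loss(dists, targets, momentum, alpha).item()
    expect = 0.0
    for k in ("s2p", "p2s", "s2s", "p2p"):
        y = (1 - alpha) * targets[k] + alpha * momentum[k]
        h = -(y * np.log(dists[k].data + 1e-12)).sum(axis=1).mean()
        expect += 0.5 * h
    assert loss == pytest.approx(expect, abs=1e-6)


def test_contrastive_shape_mismatch_errors():
    dists = _uniform_dists(2, 5)
    targets = _onehot_targets(2, 4)
    with pytest.raises(ValueError):
        contrastive_loss(dists, targets, None, 0.0)


# ---------------------------------------------------------------------------
# NWP loss
# ---------------------------------------------------------------------------
def test_nwp_zero_when_prediction_onehot_correct():
    V, L = 6, 4
    tgt = np.array([[1, 2, 3, 0]])
    valid = np.array([[True, True, True, False]])
    logits = np.full((1, L, V), -1e3)
    for i in range(3):
        logits[0, i, tgt[0, i]] = 1e3
    assert nwp_loss(Tensor(logits), tgt, valid).item() == pytest.approx(0.0, abs=1e-9)


def test_nwp_uniform_closed_form_n_lnV():
    V, n = 9, 5
    tgt = np.zeros((1, n), dtype=int)
    valid = np.ones((1, n), dtype=bool)
    logits = np.zeros((1, n, V))
    assert nwp_loss(Tensor(logits), tgt, valid).item() == pytest.approx(n * np.log(V), rel=1e-9)


def test_nwp_soft_label_matches_naive_oracle():
    rng = np.random.default_rng(3)
    B, L, V, alpha = 2, 3, 5, 0.4
    logits = rng.normal(size=(B, L, V))
    tgt = rng.integers(0, V, size=(B, L))
    valid = np.array([[1, 1, 0], [1, 1, 1]], dtype=bool)
    momentum = rng.random((B, L, V))
    momentum /= momentum.sum(-1, keepdims=True)
    got = nwp_loss(Tensor(logits), tgt, valid, momentum, alpha).item()

    probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
    expect = 0.0
    for b in range(B):
        acc = 0.0
        for l in range(L):
            if not valid[b, l]:
                continue
            y = alpha * momentum[b, l].copy()
            y[tgt[b, l]] += 1 - alpha
            acc += -(y * np.log(probs[b, l] + 1e-12)).sum()
        expect += acc / B
    assert got == pytest.approx(expect, abs=1e-6)


def test_nwp_target_out_of_vocab_errors():
    with pytest.raises(ValueError, match="vocabulary"):
        nwp_loss(Tensor(np.zeros((1, 2, 3))), np.array([[0, 7]]),
                 np.ones((1, 2), dtype=bool))


# ---------------------------------------------------------------------------
# NPP loss
# ---------------------------------------------------------------------------
def test_npp_zero_on_exact_prediction():
    v = np.random.default_rng(0).normal(size=(2, 5))
    known = np.ones((2, 5), dtype=bool)
    assert npp_loss(Tensor(v.copy()), v, known).item() == pytest.approx(0.0)


def test_npp_all_unknown_contributes_zero():
    pred = Tensor(np.random.default_rng(1).normal(size=(2, 5)))
    known = np.zeros((2, 5), dtype=bool)
    assert npp_loss(pred, np.zeros((2, 5)), known).item() == pytest.approx(0.0)


def test_npp_residual_arithmetic():
    # residuals (1, -2) on the two known positions -> 1 + 4 = 5
    target = np.array([[0.0, 0.0, 7.0]])
    pred = np.array([[1.0, -2.0, 123.0]])
    known = np.array([[True, True, False]])
    assert npp_loss(Tensor(pred), target, known).item() == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# SPM loss
# ---------------------------------------------------------------------------
def test_spm_zero_when_confident_and_correct():
    logits = np.array([[ -50.0, 50.0], [50.0, -50.0]])
    labels = np.array([1, 0])
    assert spm_loss(Tensor(logits), labels).item() == pytest.approx(0.0, abs=1e-9)


def test_spm_uniform_closed_form_ln2():
    logits = np.zeros((4, 2))
    labels = np.array([1, 1, 0, 0])
    assert spm_loss(Tensor(logits), labels).item() == pytest.approx(np.log(2), rel=1e-9)


def test_spm_matches_naive_oracle():
    rng = np.random.default_rng(4)
    logits = rng.normal(size=(4, 2))
    labels = np.array([1, 1, 0, 0])
    got = spm_loss(Tensor(logits), labels).item()
    probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
    expect = np.mean([-np.log(probs[i, labels[i]] + 1e-12) for i in range(4)])
    assert got == pytest.approx(expect, abs=1e-6)


# ---------------------------------------------------------------------------
# hard-negative mining
# ---------------------------------------------------------------------------
def test_batch_of_two_always_picks_the_only_negative():
    probs = np.full((2, 2), 0.5)
    rng = np.random.default_rng(0)
    for _ in range(20):
        picks = select_hard_negatives(probs, rng)
        assert picks[0] == 1 and picks[1] == 0


def test_batch_of_one_errors():
    with pytest.raises(ValueError, match="at least 2"):
        select_hard_negatives(np.ones((1, 1)), np.random.default_rng(0))


def test_positives_never_selected():
    rng = np.random.default_rng(5)
    probs = rng.random((6, 6))
    probs /= probs.sum(1, keepdims=True)
    for _ in range(200):
        picks = select_hard_negatives(probs, rng)
        assert np.all(picks != np.arange(6))


def test_uniform_similarities_give_uniform_selection():
    B, n_draws = 4, 10_000
    probs = np.full((B, B), 1.0 / B)
    rng = np.random.default_rng(6)
    counts = np.zeros(B)
    for _ in range(n_draws):
        counts[select_hard_negatives(probs, rng)[0]] += 1
    observed = counts[1:]  # anchor 0's negatives
    _, p = sps.chisquare(observed)
    assert p > 0.01


def test_selection_proportional_to_similarity_weight():
    # one negative with 10x the weight of the others
    B, n_draws = 4, 10_000
    probs = np.array([[0.2, 10.0, 1.0, 1.0]] * B)
    probs /= probs.sum(1, keepdims=True)
    rng = np.random.default_rng(7)
    counts = np.zeros(B)
    for _ in range(n_draws):
        counts[select_hard_negatives(probs, rng)[0]] += 1
    expected = np.array([10.0, 1.0, 1.0])
    expected = expected / expected.sum() * n_draws
    _, p = sps.chisquare(counts[1:], expected)
    assert p > 0.01
    assert counts[0] == 0


# ---------------------------------------------------------------------------
# queue
# ---------------------------------------------------------------------------
def test_queue_fifo_eviction_order():
    q = FeatureQueue(capacity=5, dim=2)
    for i in range(8):  # k + m enqueues: the m oldest must be gone
        q.enqueue(np.full((1, 2), float(i)))
    assert len(q) == 5
    np.testing.assert_array_equal(q.features[:, 0], [3, 4, 5, 6, 7])


def test_queue_batch_enqueue():
    q = FeatureQueue(capacity=4, dim=3)
    q.enqueue(np.arange(6.0).reshape(2, 3))
    q.enqueue(np.arange(6.0, 15.0).reshape(3, 3))
    assert len(q) == 4
    np.testing.assert_array_equal(q.features[0], [3, 4, 5])


# ---------------------------------------------------------------------------
# schedules and EMA
# ---------------------------------------------------------------------------
def test_lr_schedule_endpoints():
    s = PretrainSchedule(total_steps=200, warmup_steps=40)
    assert s.lr(0) == 0.0
    assert s.lr(40) == pytest.approx(1e-4)  # end of warmup hits the peak
    assert s.lr(200) == pytest.approx(1e-5)
    lrs = [s.lr(t) for t in range(40, 201)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))  # cosine decay monotone


def test_alpha_ramp_linear_over_first_epoch():
    s = PretrainSchedule()
    assert s.alpha(0, steps_per_epoch=100) == 0.0
    assert s.alpha(50, steps_per_epoch=100) == pytest.approx(0.2)
    assert s.alpha(100, steps_per_epoch=100) == pytest.approx(0.4)
    assert s.alpha(500, steps_per_epoch=100) == pytest.approx(0.4)
    ramp = [s.alpha(t, 100) for t in range(101)]
    assert all(b >= a for a, b in zip(ramp, ramp[1:]))


@pytest.mark.parametrize("lam,expected", [(1.0, 1.0), (0.0, 0.0), (0.995, 0.995)])
def test_ema_scalar_closed_form(lam, expected):
    # teacher 1, student 0 -> teacher becomes lam
    student = [nn.Parameter(np.array([0.0]))]
    teacher = [nn.Parameter(np.array([1.0]))]
    nn.ema_update(student, teacher, lam)
    assert teacher[0].data[0] == pytest.approx(expected)


def test_ema_lambda_out_of_range_errors():
    with pytest.raises(ValueError):
        nn.ema_update([], [], 1.5)


def test_ema_parameter_mismatch_errors():
    with pytest.raises(ValueError, match="mismatch"):
        nn.ema_update([nn.Parameter(np.zeros(2))], [], 0.5)


def test_soft_cross_entropy_shape_mismatch():
    with pytest.raises(ValueError):
        soft_cross_entropy(np.ones((2, 3)), Tensor(np.ones((2, 4))))
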