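"""Decoding, generation metrics and attention-map extraction."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from pvlm.generate import (GenerationConfig, attention_map, beam_decode,
                           generate_pv, generate_smiles, generation_metrics,
                           greedy_decode, normalized_rmse, pv_from_conditions)
from pvlm.nn import no_grad
from pvlm.properties import PropertyVector, normalize
from pvlm.tokenizer import tokenize


# ---------------------------------------------------------------------------
# decoding over a hand-built probability table
# ---------------------------------------------------------------------------
BOS, EOS = 0, 1
V, MAX_LEN = 5, 4


def table_step_fn(prefix):
    """Deterministic toy next-token distribution depending on the prefix."""
    rng = np.random.default_rng(hash(tuple(prefix)) % (2 ** 31))
    logits = rng.normal(size=V)
    logits[BOS] = -5.0  # discourage re-emitting BOS
    return logits - np.log(np.exp(logits - logits.max()).sum()) - logits.max()


def enumerate_all_sequences():
    """Brute-force every sequence of length <= MAX_LEN with its joint log-prob."""
    results = []

    def recurse(ids, score):
        if ids[-1] == EOS or len(ids) >= MAX_LEN:
            results.append((ids, score))
            return
        logp = table_step_fn(ids)
        for t in range(V):
            recurse(ids + [t], score + logp[t])

    recurse([BOS], 0.0)
    return results


def test_beam_k2_matches_exhaustive_enumeration():
    all_seqs = sorted(enumerate_all_sequences(), key=lambda x: -x[1])
    # drop continuations that a width-2 beam could never rank: compare sets
    got = beam_decode(table_step_fn, BOS, EOS, MAX_LEN, k=2)
    expect = all_seqs[:2]
    assert [ids for ids, _ in got] == [ids for ids, _ in expect]
    for (_, s_got), (_, s_exp) in zip(got, expect):
        assert s_got == pytest.approx(s_exp, abs=1e-12)


def test_beam_k1_equals_greedy_on_table():
    greedy = greedy_decode(table_step_fn, BOS, EOS, MAX_LEN)
    beam = beam_decode(table_step_fn, BOS, EOS, MAX_LEN, k=1)
    assert beam[0][0] == greedy


def test_beam_k1_equals_greedy_on_model(tiny_ckpt):
    pv = PropertyVector.all_unknown(tiny_ckpt.model.config.n_properties)
    greedy = generate_smiles(pv, tiny_ckpt, GenerationConfig(mode="greedy", max_len=12))
    beam = generate_smiles(pv, tiny_ckpt,
                           GenerationConfig(mode="beam", beam_width=1, max_len=12))
    assert greedy == beam


def test_greedy_is_deterministic(tiny_ckpt):
    pv = PropertyVector.all_unknown(tiny_ckpt.model.config.n_properties)
    cfg = GenerationConfig(mode="greedy", max_len=12)
    assert generate_smiles(pv, tiny_ckpt, cfg) == generate_smiles(pv, tiny_ckpt, cfg)


def test_stochastic_same_seed_identical(tiny_ckpt):
    pv = PropertyVector.all_unknown(tiny_ckpt.model.config.n_properties)
    cfg = GenerationConfig(mode="stochastic", max_len=12, seed=5)
    assert generate_smiles(pv, tiny_ckpt, cfg) == generate_smiles(pv, tiny_ckpt, cfg)


def test_rigged_model_emits_empty_string(tiny_ckpt):
    # force the next-token head to always pick [SEP] immediately
    model = tiny_ckpt.model
    w, b = model.nwp_head.weight.data.copy(), model.nwp_head.bias.data.copy()
    model.nwp_head.weight.data = np.zeros_like(w)
    model.nwp_head.bias.data = np.full_like(b, -100.0)
    model.nwp_head.bias.data[tiny_ckpt.vocab.sep_id] = 100.0
    try:
        pv = PropertyVector.all_unknown(model.config.n_properties)
        out = generate_smiles(pv, tiny_ckpt, GenerationConfig(mode="greedy"))
        assert out == [""]
    finally:
        model.nwp_head.weight.data = w
        model.nwp_head.bias.data = b


# ---------------------------------------------------------------------------
# SMILES -> PV
# ---------------------------------------------------------------------------
def test_generate_pv_length_and_determinism(tiny_ckpt):
    out1 = generate_pv("CCO", tiny_ckpt)
    out2 = generate_pv("CCO", tiny_ckpt)
    assert out1.shape == (tiny_ckpt.model.config.n_properties,)
    np.testing.assert_array_equal(out1, out2)


def test_generate_pv_zero_weight_head_gives_property_means(tiny_ckpt):
    model = tiny_ckpt.model
    w, b = model.npp_head.weight.data.copy(), model.npp_head.bias.data.copy()
    model.npp_head.weight.data = np.zeros_like(w)
    model.npp_head.bias.data = np.zeros_like(b)
    try:
        out = generate_pv("CCO", tiny_ckpt)
        np.testing.assert_allclose(out, tiny_ckpt.stats.mean, atol=1e-10)
    finally:
        model.npp_head.weight.data = w
        model.npp_head.bias.data = b


def test_generate_pv_matches_no_cache_full_recompute_oracle(tiny_ckpt):
    """Stepwise decoding equals a naive loop that re-runs every encoder from
    scratch (including the SMILES side) at each step."""
    smiles = "CCOc1ccccc1"
    got = generate_pv(smiles, tiny_ckpt)

    model, vocab, stats = tiny_ckpt.model, tiny_ckpt.vocab, tiny_ckpt.stats
    P = model.config.n_properties
    ids = np.asarray([tokenize(smiles, vocab).ids], dtype=np.intp)
    pred = np.zeros(P)
    with no_grad():
        for i in range(P):
            s_feats = model.encode_smiles(ids, causal=False)  # recomputed each step
            values, known = np.zeros((1, P)), np.zeros((1, P), dtype=bool)
            values[0, :i], known[0, :i] = pred[:i], True
            fused = model.fuse(model.encode_pv(values, known, causal=True),
                               s_feats, causal=True)
            pred[i] = float(model.npp_head(fused[:, i]).data[0, 0])
    expect = pred * stats.std + stats.mean
    np.testing.assert_allclose(got, expect, atol=1e-8)


def test_generate_pv_invalid_smiles_errors(tiny_ckpt):
    with pytest.raises(ValueError):
        generate_pv("Z$Z", tiny_ckpt)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def test_validity_uniqueness_novelty_exact_fractions():
    valid8 = ["CCO", "OCC", "CCN", "NCC", "CCC", "CC", "C", "CO"]  # 8 parse
    generated = valid8 + ["xx(", "notasmiles"]  # 10 generated, 8 valid
    # canonical forms: CCO==OCC, CCN==NCC -> 6 unique
    pretraining = {Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in ["CCO", "CCN", "CCC"]}
    m = generation_metrics(generated, pretraining)
    assert m.validity == pytest.approx(0.8)
    assert m.uniqueness == pytest.approx(0.75)
    assert m.novelty == pytest.approx(0.5)


def test_adding_invalid_string_lowers_only_validity():
    generated = ["CCO", "CCN"]
    m1 = generation_metrics(generated, set())
    m2 = generation_metrics(generated + ["(((bad"], set())
    assert m2.validity < m1.validity
    assert m2.uniqueness == m1.uniqueness
    assert m2.novelty == m1.novelty


def test_metrics_empty_list_errors():
    with pytest.raises(ValueError):
        generation_metrics([], set())


# ---------------------------------------------------------------------------
# normalized RMSE
# ---------------------------------------------------------------------------
def test_normalized_rmse_zero_on_exact_match(registry, stats):
    target = normalize(registry.compute("CCO"), stats)
    assert normalized_rmse(target, ["CCO", "OCC"], stats, registry) == pytest.approx(0.0, abs=1e-9)


def test_normalized_rmse_single_unit_residual(registry, stats):
    raw = registry.compute("CCO")
    pv = normalize(raw, stats)
    # control only MolWt and shift the target one std away from the molecule
    i = list(registry.names).index("MolWt")
    single = PropertyVector(values=np.where(np.arange(len(pv)) == i, pv.values + 1.0, 0.0),
                            known=np.arange(len(pv)) == i)
    assert normalized_rmse(single, ["CCO"], stats, registry) == pytest.approx(1.0, rel=1e-6)


def test_normalized_rmse_mean_over_controlled_properties(registry, stats):
    # construct residuals 0.2 and 0.4 on two controlled properties -> mean 0.3
    raw = registry.compute("CCO")
    pv = normalize(raw, stats)
    i, j = (list(registry.names).index(n) for n in ("MolWt", "TPSA"))
    values = pv.values.copy()
    values[i] += 0.2
    values[j] += 0.4
    known = np.zeros(len(pv), dtype=bool)
    known[[i, j]] = True
    target = PropertyVector(values=values, known=known)
    assert normalized_rmse(target, ["CCO"], stats, registry) == pytest.approx(0.3, rel=1e-6)


def test_normalized_rmse_requires_controlled_property(registry, stats):
    with pytest.raises(ValueError):
        normalized_rmse(PropertyVector.all_unknown(len(registry)), ["CCO"], stats, registry)


def test_normalized_rmse_all_invalid_errors(registry, stats):
    pv = normalize(registry.compute("CCO"), stats)
    with pytest.raises(ValueError):
        normalized_rmse(pv, ["((("], stats, registry)


# ---------------------------------------------------------------------------
# attention maps
# ---------------------------------------------------------------------------
def test_attention_map_rows_sum_to_one(tiny_ckpt, registry, stats):
    pv = normalize(registry.compute("CCO"), stats)
    mat, tokens = attention_map("CCO", pv, tiny_ckpt)
    assert mat.shape == (len(registry), len(tokens))
    np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-6)


def test_attention_map_is_mean_over_heads(tiny_ckpt, registry, stats):
    pv = normalize(registry.compute("CCOc1ccccc1"), stats)
    mat, _ = attention_map("CCOc1ccccc1", pv, tiny_ckpt)
    per_head = tiny_ckpt.model.fusion_encoder.last_cross_attention[0]  # (H, P+1, T)
    assert per_head.shape[0] == tiny_ckpt.model.config.n_heads
    np.testing.assert_allclose(mat, per_head.mean(axis=0)[1:], atol=1e-12)


# ---------------------------------------------------------------------------
# condition files
# ---------------------------------------------------------------------------
def test_pv_from_conditions(registry, stats):
    i = list(registry.names).index("MolWt")
    pv = pv_from_conditions({"MolWt": 100.0, "TPSA": "UNK"}, registry, stats)
    assert pv.known[i]
    assert pv.known.sum() == 1
    expected = (100.0 - stats.mean[i]) / stats.std[i]
    assert pv.values[i] == pytest.approx(expected)


def test_pv_from_conditions_unknown_name_errors(registry, stats):
    with pytest.raises(ValueError, match="nonexistent"):
        pv_from_conditions({"nonexistent": 1.0}, registry, stats)
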