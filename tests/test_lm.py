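"""Language model contracts: determinism, closed-form likelihoods, the
Markov-chain scoring oracle, padding invariance, memorization, sampling."""

import numpy as np
import pytest

from rnagen.lm import (
    GenerationConfig,
    LMConfig,
    RnaLM,
    TrainConfig,
    evaluate_nll,
    finetune,
    generate,
    init_model,
    sequence_log_probabilities,
    sequence_log_probability,
    train,
)
from rnagen.tokenizer import build_vocab, encode


@pytest.fixture(scope="module")
def tiny_cfg():
    return LMConfig(context_window=40, n_layers=2, n_heads=2, d_embed=32)


@pytest.fixture(scope="module")
def spec3():
    return build_vocab(3)


class TestInit:
    def test_forward_smoke(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        ids = np.array([encode("ACGUA", spec3).ids])
        out = m.forward(ids)
        assert out.shape == (1, len(ids[0]), spec3.vocab_size)

    def test_same_seed_identical_params(self, tiny_cfg, spec3):
        a = init_model(tiny_cfg, spec3, rng_seed=7)
        b = init_model(tiny_cfg, spec3, rng_seed=7)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_bad_head_division(self):
        with pytest.raises(ValueError):
            LMConfig(context_window=10, n_layers=1, n_heads=4, d_embed=30)

    def test_inference_path_matches_autograd_forward(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=1)
        ids = np.random.default_rng(0).integers(0, 64, (3, 12))
        assert np.allclose(m.forward(ids).data, m.logits_np(ids), atol=2e-4)

    def test_kv_cache_matches_full_forward(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=1)
        ids = np.random.default_rng(1).integers(0, 64, (2, 10))
        full = m.logits_np(ids)[:, -1]
        logits, cache = m._prefill(ids[:, :-1])
        step = m._decode_step(ids[:, -1], 9, cache)
        assert np.allclose(step, full, atol=2e-4)


class TestLikelihood:
    def test_uniform_model_closed_form(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        m.params["tok_emb"].data[:] = 0.0  # tied head -> uniform logits
        V = spec3.vocab_size
        res = sequence_log_probability(m, "ACGUACG")
        L_body = 7 - 3 + 1
        assert not res.windowed
        assert res.n_scored_tokens == L_body + 1  # body after BOS-token + EOS
        # BOS conditions the first body token, so body + EOS are scored
        assert abs(res.logp - (L_body + 1) * np.log(1 / V)) < 1e-5

    def test_uniform_model_perplexity_equals_vocab_size(self, tiny_cfg):
        for n in (1, 3):
            spec = build_vocab(n)
            m = init_model(LMConfig(context_window=40, n_layers=1, n_heads=2,
                                    d_embed=16), spec, rng_seed=0)
            m.params["tok_emb"].data[:] = 0.0
            toks = [encode("ACGUACGUAC", spec).ids]
            nll = evaluate_nll(m, toks)
            assert abs(np.exp(nll) - spec.vocab_size) < 1e-3

    def test_markov_oracle_with_windowing(self):
        """Scoring matches brute-force chain enumeration, even when the
        sequence is longer than the context window (chunked scoring)."""
        spec = build_vocab(1)
        rng = np.random.default_rng(4)
        V = spec.vocab_size
        T_mat = rng.dirichlet(np.ones(V), size=V)  # row-stochastic

        class MarkovStub:
            """Position-independent first-order chain with the LM interface."""

            def __init__(self, cw):
                from dataclasses import dataclass

                @dataclass
                class C:
                    context_window: int

                self.cfg = C(cw)
                self.spec = spec

            def logits_np(self, ids):
                return np.log(T_mat[ids] + 1e-30).astype(np.float32)

        seq = "".join(rng.choice(list("ACGU"), 30))
        ids = encode(seq, spec).ids
        expect = sum(np.log(T_mat[a, b]) for a, b in zip(ids, ids[1:]))

        short = sequence_log_probability(MarkovStub(60), seq)
        assert not short.windowed
        assert abs(short.logp - expect) < 1e-4

        windowed = sequence_log_probability(MarkovStub(12), seq)
        assert windowed.windowed
        assert abs(windowed.logp - expect) < 1e-4
        assert windowed.n_scored_tokens == short.n_scored_tokens

    def test_skip_seed_excludes_leading_tokens(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=2)
        seq = "ACGUACGUGGCC"
        full = sequence_log_probabilities(m, [seq])[0]
        skipped = sequence_log_probabilities(m, [seq], skip_seed_tokens=3)[0]
        assert skipped.n_scored_tokens == full.n_scored_tokens - 3
        # skipped sum equals full sum minus the first three token scores
        import numpy as _np
        from rnagen.lm import _token_logps
        from rnagen.tokenizer import encode as _enc

        ids = _np.array([_enc(seq, spec3).ids])
        lead = _token_logps(m, ids)[0, :3].sum()
        assert abs((full.logp - lead) - skipped.logp) < 1e-6

    def test_additive_over_batch(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=2)
        seqs = ["ACGUACGU", "GGGCCCAAA"]
        singles = [sequence_log_probability(m, s).logp for s in seqs]
        batched = [r.logp for r in sequence_log_probabilities(m, seqs)]
        assert np.allclose(singles, batched, atol=1e-6)


class TestTraining:
    def test_padding_excluded_from_loss(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        ids = np.array([encode("ACGUACGUAC", spec3).ids])
        padded = np.concatenate(
            [ids, np.full((1, 5), spec3.pad_id, dtype=np.int64)], axis=1
        )
        l1, n1 = m.loss(ids)
        l2, n2 = m.loss(padded)
        assert n1 == n2
        assert abs(float(l1.data) - float(l2.data)) < 1e-5

    def test_memorization_drives_perplexity_to_one(self, spec3):
        # a deterministic corpus has zero entropy
        cfg = LMConfig(context_window=26, n_layers=2, n_heads=2, d_embed=32)
        m = init_model(cfg, spec3, rng_seed=0)
        toks = [encode("GCGAUUCGCGGCAUUACGCGAUCG", spec3).ids] * 50
        tc = TrainConfig(lr_start=3e-3, lr_end=3e-4, decay_iters=400,
                         batch_size=8, max_iters=400, eval_interval=100,
                         eval_batches=2, early_stop_patience=10, rng_seed=0)
        m, rep = train(m, toks, toks[:4], tc)
        assert rep.best_val_perplexity < 1.1

    def test_triplet_tokens_beat_single_under_tight_budget(self):
        """At a matched small parameter and iteration budget on a
        structured family, overlapping triplet tokens reach lower
        per-nucleotide validation perplexity than single-nucleotide
        tokens: the trigram context is free in the token itself."""
        from rnagen.synthetic import SyntheticFamilySpec, sample_family

        spec = SyntheticFamilySpec.default(n_sequences=600, delta=0.9,
                                           rng_seed=3, mutation_rate=0.08)
        seqs = sample_family(spec).family.ungapped()
        ppl = {}
        for n in (1, 3):
            tok = build_vocab(n)
            toks = [encode(s, tok).ids for s in seqs]
            m = RnaLM(LMConfig(context_window=204, n_layers=1, n_heads=2,
                               d_embed=32), tok, rng_seed=0)
            tc = TrainConfig(lr_start=2e-3, lr_end=2e-4, decay_iters=300,
                             batch_size=16, max_iters=300, eval_interval=150,
                             eval_batches=4, early_stop_patience=6, rng_seed=0)
            m, rep = train(m, toks[:540], toks[540:], tc)
            ppl[n] = rep.best_val_perplexity
        assert ppl[3] < ppl[1], ppl

    def test_empty_dataset_errors(self, tiny_cfg, spec3):
        with pytest.raises(ValueError):
            train(init_model(tiny_cfg, spec3), [], [], TrainConfig())

    def test_finetune_zero_iters_returns_parent(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        toks = [encode("ACGUACGU", spec3).ids] * 4
        child, rep = finetune(m, toks, toks, TrainConfig(max_iters=0))
        for k in m.params:
            assert np.array_equal(m.params[k].data, child.params[k].data)

    def test_finetune_partition_violation_recorded(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        toks = [encode("ACGUACGU", spec3).ids] * 4
        _, rep = finetune(m, toks, toks, TrainConfig(max_iters=0),
                          train_ids=["a", "b"], pretrain_val_ids={"b"})
        assert any("partition violation" in n for n in rep.notes)


class TestGeneration:
    def test_outputs_start_with_seed(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=3)
        res = generate(m, GenerationConfig(seed_prefix="GCGAU", temperature=1.0,
                                           n_sequences=8, max_nucleotides=20,
                                           rng_seed=0))
        assert len(res.sequences) == 8
        for s in res.sequences:
            assert s.residues.startswith("GCGAU")
            assert len(s.residues) <= 20

    def test_bit_reproducible(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=3)
        g = GenerationConfig(seed_prefix="GCGAU", temperature=0.8,
                             n_sequences=5, max_nucleotides=15, rng_seed=9)
        a = generate(m, g)
        b = generate(m, g)
        assert [s.residues for s in a.sequences] == [s.residues for s in b.sequences]

    def test_low_temperature_limit_is_greedy(self, tiny_cfg, spec3):
        m = init_model(tiny_cfg, spec3, rng_seed=3)
        res = generate(m, GenerationConfig(seed_prefix="GCGAU", temperature=1e-6,
                                           n_sequences=3, max_nucleotides=15,
                                           rng_seed=0))
        # greedy: all samples identical, and equal to argmax rollout
        outs = {s.residues for s in res.sequences}
        assert len(outs) == 1

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            GenerationConfig(seed_prefix="ACG", temperature=0.0)

    def test_sampling_matches_model_conditionals(self):
        """Empirical next-token frequencies match the model's own softmax
        within 3-sigma binomial error (checks the sampling machinery)."""
        spec1 = build_vocab(1)
        cfg = LMConfig(context_window=10, n_layers=1, n_heads=1, d_embed=16)
        m = init_model(cfg, spec1, rng_seed=5)
        seed = "ACGUA"
        n = 4000
        res = generate(m, GenerationConfig(seed_prefix=seed, temperature=1.0,
                                           n_sequences=n, max_nucleotides=6,
                                           rng_seed=1))
        # model probabilities for the first sampled token (PAD/BOS masked)
        ids = np.array([encode(seed, spec1).ids[:-1]])
        logits = m.logits_np(ids)[0, -1].astype(np.float64)
        logits[spec1.pad_id] = -np.inf
        logits[spec1.bos_id] = -np.inf
        probs = np.exp(logits - np.logaddexp.reduce(logits))
        counts = np.zeros(spec1.vocab_size)
        for s in res.sequences:
            if len(s.residues) >= 6:
                counts[spec1.vocab[s.residues[5]]] += 1
            else:
                counts[spec1.eos_id] += 1  # stopped at the seed
        for v in range(spec1.vocab_size):
            sigma = np.sqrt(n * probs[v] * (1 - probs[v]))
            assert abs(counts[v] - n * probs[v]) <= 3 * sigma + 3


class TestPersistence:
    def test_save_load_round_trip(self, tiny_cfg, spec3, tmp_path):
        m = init_model(tiny_cfg, spec3, rng_seed=0)
        p = tmp_path / "m.npz"
        m.save(p)
        back = RnaLM.load(p)
        ids = np.random.default_rng(0).integers(0, 64, (2, 8))
        assert np.allclose(m.logits_np(ids), back.logits_np(ids))
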