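"""Two-sentence encoding, static masking and the transformer pipeline."""

import numpy as np
import pytest

from photorank.lm import (
    IGNORE,
    LMConfig,
    MaskedBatch,
    PretrainedLM,
    TransformerRecommender,
    apply_static_mask,
    build_masked_corpus,
    encode_two_sentence,
    pretrain_mlm,
)
from photorank.synthetic import GeneratorConfig, corpus_for_pretraining
from photorank.tokenizer import CLS, MASK, PAD, SEP, ByteBPETokenizer

SMALL = dict(max_len=96, n_layers=2, n_heads=2, embed_dim=48, learning_rate=1e-3)


@pytest.fixture(scope="module")
def corpus():
    train_pairs, heldout = corpus_for_pretraining(
        GeneratorConfig(n_records=150, imbalance_exponent=0.5, seed=100)
    )
    return train_pairs, heldout


@pytest.fixture(scope="module")
def tok(corpus):
    train_pairs, _ = corpus
    return ByteBPETokenizer.train([c + r for c, r in train_pairs], 300)


class TestEncodeTwoSentence:
    def test_layout_and_padding(self, tok):
        ids = encode_two_sentence("CBr>>CO", "CCBr.O>>CCO", tok, 64)
        assert len(ids) == 64
        assert ids[0] == CLS
        assert list(ids).count(SEP) == 2
        assert ids[-1] == PAD

    def test_empty_core_degenerates(self, tok):
        ids = encode_two_sentence("", "CCO>>CCO", tok, 64)
        assert ids[0] == CLS and ids[1] == SEP
        assert list(ids).count(SEP) == 2

    def test_always_padded_to_max_len(self, tok, corpus):
        for core, rxn in corpus[0][:20]:
            assert len(encode_two_sentence(core, rxn, tok, 96)) == 96

    def test_truncation_clips_sentence_b_only(self, tok):
        core, rxn = "CBr>>CO", "C" * 300 + ">>" + "C" * 300
        ids = encode_two_sentence(core, rxn, tok, 32)
        assert len(ids) == 32
        assert list(ids).count(SEP) == 2
        # sentence A survives verbatim
        a_len = len(tok.encode(core))
        assert list(ids[1 : 1 + a_len]) == tok.encode(core)

    def test_oversized_core_rejected(self, tok):
        with pytest.raises(ValueError):
            encode_two_sentence("C" * 500, "C>>C", tok, 32)

    def test_paper_scale_length_configurable(self, tok):
        ids = encode_two_sentence("CBr>>CO", "CCBr.O>>CCO", tok, 1024)
        assert len(ids) == 1024


class TestStaticMask:
    def test_rate_zero_masks_nothing(self, tok):
        ids = encode_two_sentence("CBr>>CO", "CCBr.O>>CCO", tok, 64)
        batch = apply_static_mask(ids, tok, mask_rate=0.0, seed=0)
        assert batch.n_masked == 0
        assert (batch.labels == IGNORE).all()

    def test_same_seed_reproduces_positions(self, tok, corpus):
        ids = np.stack(
            [encode_two_sentence(c, r, tok, 96) for c, r in corpus[0][:30]]
        )
        a = apply_static_mask(ids, tok, 0.15, seed=3)
        b = apply_static_mask(ids, tok, 0.15, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.mask_positions, b.mask_positions))
        assert np.array_equal(a.input_ids, b.input_ids)

    def test_special_positions_never_masked(self, tok, corpus):
        ids = np.stack(
            [encode_two_sentence(c, r, tok, 96) for c, r in corpus[0][:30]]
        )
        batch = apply_static_mask(ids, tok, 0.5, seed=1)
        special = np.isin(ids, [PAD, CLS, SEP, MASK])
        assert (batch.labels[special] == IGNORE).all()
        # masked inputs carry the mask token exactly at labeled positions
        labeled = batch.labels != IGNORE
        assert (batch.input_ids[labeled] == MASK).all()

    def test_labels_only_at_masked_positions(self, tok):
        ids = encode_two_sentence("CBr>>CO", "CCBr.O>>CCO", tok, 64)
        batch = apply_static_mask(ids, tok, 0.3, seed=5)
        labeled = np.where(batch.labels[0] != IGNORE)[0]
        assert set(labeled) == set(batch.mask_positions[0])
        assert np.array_equal(batch.labels[0][labeled], np.atleast_2d(ids)[0][labeled])


class TestPretraining:
    @pytest.fixture(scope="class")
    def pretrained(self, corpus, tok):
        train_pairs, heldout = corpus
        config = LMConfig(pretrain_epochs=2, seed=0, **SMALL)
        return pretrain_mlm(train_pairs, heldout, tok, config), config

    def test_heldout_loss_below_untrained_baseline(self, pretrained):
        model, _ = pretrained
        assert model.history[-1]["heldout_loss"] < model.history[0]["heldout_loss"]

    def test_masked_recovery_beats_chance(self, pretrained, corpus, tok):
        model, config = pretrained
        _, heldout = corpus
        batch = build_masked_corpus(heldout, tok, config, seed=config.seed + 1)
        assert model.masked_accuracy(batch) > 1.0 / tok.vocab_size

    def test_checkpoint_reload_identical_loss(self, pretrained, corpus, tok, tmp_path):
        model, config = pretrained
        _, heldout = corpus
        batch = build_masked_corpus(heldout, tok, config, seed=config.seed + 1)
        path = tmp_path / "lm.npz"
        model.save(path)
        clone = PretrainedLM.load(path)
        assert clone.masked_loss(batch) == model.masked_loss(batch)

    def test_empty_corpus_rejected(self, tok):
        with pytest.raises(ValueError):
            pretrain_mlm([], [], tok, LMConfig(**SMALL))


class TestClassifier:
    @pytest.fixture(scope="class")
    def scarce(self, registry):
        from photorank.reaction_core import core_from_mapped_smiles
        from photorank.synthetic import generate_dataset

        records, _ = generate_dataset(
            GeneratorConfig(
                n_records=80,
                n_templates=6,
                imbalance_exponent=0.3,
                label_noise=0.0,
                seed=200,
            )
        )
        pairs = [
            (core_from_mapped_smiles(r.mapped_smiles).core_smiles, r.reaction_smiles)
            for r in records
        ]
        y = np.array([registry.encode(r.catalyst_label) for r in records])
        return pairs, y

    def test_probability_vector_shape_and_normalization(self, scarce, tok, registry):
        pairs, y = scarce
        config = LMConfig(finetune_epochs=2, seed=0, **SMALL)
        model = TransformerRecommender(
            tokenizer=tok, registry_size=registry.size, config=config
        ).fit(pairs[:60], y[:60])
        proba = model.predict_proba(pairs[60:])
        assert proba.shape == (20, registry.size)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_determinism(self, scarce, tok, registry):
        pairs, y = scarce
        config = LMConfig(finetune_epochs=1, seed=0, **SMALL)

        def run():
            model = TransformerRecommender(
                tokenizer=tok,
                registry_size=registry.size,
                config=config,
                random_state=3,
            ).fit(pairs[:40], y[:40])
            return model.predict_proba(pairs[40:50])

        assert np.array_equal(run(), run())

    def test_checkpoint_round_trip(self, scarce, tok, registry, tmp_path):
        pairs, y = scarce
        config = LMConfig(finetune_epochs=1, seed=0, **SMALL)
        model = TransformerRecommender(
            tokenizer=tok, registry_size=registry.size, config=config
        ).fit(pairs[:40], y[:40])
        path = tmp_path / "clf.npz"
        model.save(path)
        clone = TransformerRecommender.load(path)
        assert np.allclose(
            clone.predict_proba(pairs[40:50]), model.predict_proba(pairs[40:50])
        )

    def test_missing_tokenizer_rejected(self, scarce):
        pairs, y = scarce
        with pytest.raises(ValueError):
            TransformerRecommender().fit(pairs[:40], y[:40])
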