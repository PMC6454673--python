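"""Training loop: determinism, convergence, checkpoints, cross-validation."""

import numpy as np
import pytest

from rannote import DictSegmenter, GeneratorConfig, generate_corpus
from rannote.model import (
    BiLstmCrfTagger,
    TaggerResults,
    TrainConfig,
    clip_gradients,
    cross_validate,
)
from rannote.pipeline import document_to_sequences


def tiny_config(**overrides):
    base = dict(word_dim=12, char_dim=6, lstm_hidden=8, gate_hidden=6,
                dropout=0.0, max_epochs=3, seed=13)
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def train_sequences():
    config = GeneratorConfig(n_documents=4, sentences_per_doc=4, seed=23)
    seg = DictSegmenter(config.dictionary())
    corpus = generate_corpus(config)
    return [s for d in corpus for s in document_to_sequences(d, seg)]


class TestTrainConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            TrainConfig.from_dict({"learning_rate_warmup": 5})

    def test_gate_requires_matching_char_dim(self):
        with pytest.raises(ValueError, match="word_dim"):
            TrainConfig(word_dim=48, char_filters=10, combiner="gate")

    def test_ablation_switches_accepted(self):
        for combiner, char_encoder in [("concat", "cnn"), ("gate", "lstm"),
                                       ("concat", "none")]:
            cfg = TrainConfig(combiner=combiner, char_encoder=char_encoder)
            assert cfg.combiner == combiner

    def test_invalid_choices_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(combiner="sum")
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.0)
        with pytest.raises(ValueError):
            TrainConfig(gradient_clip=0.0)


class TestFit:
    def test_same_seed_identical_parameters(self, train_sequences):
        runs = []
        for _ in range(2):
            model = BiLstmCrfTagger(train_sequences[:8], tiny_config())
            model.fit()
            runs.append({k: p.value.copy() for k, p in model.net.params().items()})
        for key in runs[0]:
            assert np.array_equal(runs[0][key], runs[1][key]), key

    def test_initial_loss_near_uniform_baseline(self, train_sequences):
        """Before any update the CRF is uniform over paths, so the mean NLL
        per sentence is about n_tokens * log(n_tags)."""
        model = BiLstmCrfTagger(train_sequences, tiny_config())
        encoded = model._encode(train_sequences)
        nll = np.mean([model.sentence_nll(*row) for row in encoded])
        n_tags = len(model.vocab.tag_to_index)
        baseline = np.mean([len(row[0]) for row in encoded]) * np.log(n_tags)
        assert nll == pytest.approx(baseline, rel=0.1)

    def test_loss_decreases_over_first_epochs(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences, tiny_config(max_epochs=5))
        results = model.fit()
        losses = results.history["loss"].tolist()
        assert losses[-1] < losses[0]
        assert losses == sorted(losses, reverse=True) or losses[4] < losses[0] * 0.9

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BiLstmCrfTagger([], tiny_config())

    def test_early_stopping_needs_dev(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences[:6],
                                tiny_config(early_stopping=True))
        with pytest.raises(ValueError, match="development"):
            model.fit()

    def test_early_stopping_tracks_dev_f(self, train_sequences):
        model = BiLstmCrfTagger(
            train_sequences[:10],
            tiny_config(early_stopping=True, patience=1, max_epochs=6),
        )
        results = model.fit(dev=train_sequences[10:14])
        assert "dev_f" in results.history.columns
        assert results.best_epoch >= 0

    def test_summary_mentions_key_facts(self, train_sequences):
        results = BiLstmCrfTagger(train_sequences[:6], tiny_config()).fit()
        text = results.summary()
        assert "parameters" in text and "final train NLL" in text


class TestEmissions:
    def test_rows_are_log_probabilities(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences, tiny_config())
        words, chars, _ = model._encode(train_sequences[:1])[0]
        E = model.emissions(words, chars)
        assert np.exp(E).sum(axis=1) == pytest.approx(np.ones(len(words)),
                                                      abs=1e-6)

    def test_zeroed_network_gives_uniform_emissions(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences, tiny_config())
        for p in model.net.params().values():
            p.value[...] = 0.0
        words, chars, _ = model._encode(train_sequences[:1])[0]
        E = model.emissions(words, chars)
        n_tags = len(model.vocab.tag_to_index)
        assert np.exp(E) == pytest.approx(
            np.full((len(words), n_tags), 1.0 / n_tags), abs=1e-12
        )


class TestGradientClipping:
    def test_large_gradients_scaled_to_max_norm(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences[:4], tiny_config())
        params = model.net.params()
        for p in params.values():
            p.grad[...] = 10.0
        norm_before = np.sqrt(sum((p.grad ** 2).sum() for p in params.values()))
        clip_gradients(params, 5.0)
        norm_after = np.sqrt(sum((p.grad ** 2).sum() for p in params.values()))
        assert norm_before > 5.0
        assert norm_after == pytest.approx(5.0, abs=1e-9)

    def test_small_gradients_untouched(self, train_sequences):
        model = BiLstmCrfTagger(train_sequences[:4], tiny_config())
        params = model.net.params()
        for p in params.values():
            p.grad[...] = 1e-6
        before = {k: p.grad.copy() for k, p in params.items()}
        clip_gradients(params, 5.0)
        for k, p in params.items():
            assert np.array_equal(p.grad, before[k])


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, train_sequences, tmp_path):
        results = BiLstmCrfTagger(train_sequences[:10], tiny_config()).fit()
        path = tmp_path / "model.npz"
        results.save(path)
        loaded = TaggerResults.load(path)
        pred_a = results.predict(train_sequences)
        pred_b = loaded.predict(train_sequences)
        assert [s.tags for s in pred_a] == [s.tags for s in pred_b]
        for k, p in results.model.net.params().items():
            assert np.array_equal(p.value, loaded.model.net.params()[k].value)


class TestAblations:
    @pytest.mark.parametrize("combiner,char_encoder", [
        ("concat", "cnn"),   # no attention
        ("gate", "lstm"),    # LSTM char encoder
        ("concat", "none"),  # no char embeddings
    ])
    def test_ablation_variants_train_and_predict(self, train_sequences,
                                                 combiner, char_encoder):
        cfg = tiny_config(max_epochs=1, combiner=combiner,
                          char_encoder=char_encoder)
        results = BiLstmCrfTagger(train_sequences[:6], cfg).fit()
        pred = results.predict(train_sequences[:3])
        assert all(len(p.tags) == len(s.tokens)
                   for p, s in zip(pred, train_sequences))

    def test_char_features_help_on_oov_words(self):
        """When entity type is carried by a shared character of words unseen
        in training, the char-CNN model beats the word-only ablation."""
        med = ["坦药", "平药", "宁药", "清药", "康药", "欣药"]
        trt = ["针疗", "灸疗", "推疗", "拔疗", "贴疗", "熏疗"]
        def lexicons(items_med, items_trt):
            from rannote import EntityType
            lex = {t: list(v) for t, v in
                   GeneratorConfig().lexicons.items()}
            lex[EntityType.MEDICATION] = items_med
            lex[EntityType.TREATMENT] = items_trt
            return lex
        from rannote import EntityType
        weights = {t: 0.0 for t in EntityType}
        weights[EntityType.MEDICATION] = 0.5
        weights[EntityType.TREATMENT] = 0.5
        templates = [("予以", "<*>", "。")]  # type not inferable from context
        def corpus(lex, seed, n_docs):
            cfg = GeneratorConfig(
                n_documents=n_docs, sentences_per_doc=6,
                entity_type_weights=weights, templates=templates,
                lexicons=lex, seed=seed,
            )
            seg = DictSegmenter(cfg.dictionary())
            return [s for d in generate_corpus(cfg)
                    for s in document_to_sequences(d, seg)]
        train = corpus(lexicons(med[:4], trt[:4]), seed=1, n_docs=10)
        test = corpus(lexicons(med[4:], trt[4:]), seed=2, n_docs=5)
        scores = {}
        for char_encoder in ("cnn", "none"):
            cfg = tiny_config(max_epochs=40, char_encoder=char_encoder,
                              combiner="gate" if char_encoder == "cnn"
                              else "concat")
            results = BiLstmCrfTagger(train, cfg).fit()
            from rannote import conll_evaluate
            scores[char_encoder] = conll_evaluate(
                test, results.predict(test)).overall_f
        assert scores["cnn"] > scores["none"]


class TestCrossValidate:
    def test_each_document_predicted_exactly_once(self):
        config = GeneratorConfig(n_documents=4, sentences_per_doc=3, seed=2)
        corpus = generate_corpus(config)
        seg = DictSegmenter(config.dictionary())
        n_seqs = sum(len(document_to_sequences(d, seg)) for d in corpus)
        result = cross_validate(corpus, tiny_config(max_epochs=1), k=2,
                                segmenter=seg)
        total = result.report.row("Total")
        n_gold = sum(len(d.entities) for d in corpus)
        assert total["n_gold"] == n_gold
        assert len(result.fold_losses) == 2

    def test_too_few_documents_rejected(self):
        config = GeneratorConfig(n_documents=3, sentences_per_doc=2, seed=2)
        corpus = generate_corpus(config)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(corpus, tiny_config(), k=5)
        with pytest.raises(ValueError, match="k must"):
            cross_validate(corpus, tiny_config(), k=1)
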