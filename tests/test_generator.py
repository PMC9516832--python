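"""Temperature softmax, cross-entropy, training and sampling contracts."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molbias import (
    GeneratorConfig,
    GeneratorResults,
    SamplingConfig,
    SmilesGenerator,
    cross_entropy,
    temperature_softmax,
)
from molbias.corpus import Corpus
from molbias.metrics import validity_filter


class TestTemperatureSoftmax:
    def test_equal_logits_give_uniform(self):
        for T in (0.1, 1.0, 5.0):
            p = temperature_softmax(np.full(7, 3.2), T)
            assert np.allclose(p, 1 / 7, atol=1e-12)

    def test_two_class_closed_form(self):
        p = temperature_softmax(np.array([2.0, 0.0]), T=1.0)
        expected = np.array([math.e**2 / (math.e**2 + 1), 1 / (math.e**2 + 1)])
        assert np.allclose(p, expected, atol=1e-12)
        assert p[0] == pytest.approx(0.8808, abs=1e-4)

    def test_low_temperature_sharpens_to_argmax(self):
        p = temperature_softmax(np.array([2.0, 0.0]), T=0.01)
        assert p[0] > 0.999

    def test_temperature_one_reduces_to_plain_softmax(self):
        logits = np.array([0.3, -1.2, 2.0])
        direct = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(temperature_softmax(logits, 1.0), direct, atol=1e-12)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        k=st.integers(min_value=1, max_value=200),
        seed=st.integers(min_value=0, max_value=2**16),
        T=st.floats(min_value=0.05, max_value=10.0),
    )
    def test_sums_to_one(self, k, seed, T):
        logits = np.random.default_rng(seed).normal(0, 5, size=k)
        p = temperature_softmax(logits, T)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p > 0)

    def test_entropy_nondecreasing_in_temperature(self):
        logits = np.array([3.0, 1.0, 0.0, -2.0])
        entropies = []
        for T in (0.2, 0.5, 1.0, 2.0, 5.0):
            p = temperature_softmax(logits, T)
            entropies.append(float(-(p * np.log(p)).sum()))
        assert all(b >= a - 1e-12 for a, b in zip(entropies, entropies[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            temperature_softmax(np.array([1.0]), T=0.0)
        with pytest.raises(ValueError):
            temperature_softmax(np.array([np.inf, 0.0]), T=1.0)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy([0.0, 1.0, 0.0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_two_class_uniform_closed_form(self):
        expected = -0.5 * math.log(0.5)
        assert cross_entropy([0.5, 0.5], [1, 0], k=2) == pytest.approx(expected, abs=1e-12)
        assert cross_entropy([0.5, 0.5], [0, 1], k=2) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(k=st.integers(min_value=2, max_value=20), seed=st.integers(0, 2**16))
    def test_matches_brute_force_formula(self, k, seed):
        rng = np.random.default_rng(seed)
        yp = rng.dirichlet(np.ones(k))
        true = int(rng.integers(0, k))
        yr = np.zeros(k)
        yr[true] = 1.0
        brute = -sum(yr[i] * math.log(max(yp[i], 1e-12)) for i in range(k)) / k
        assert cross_entropy(yp, yr, k) == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_true_class_probability(self):
        hi = cross_entropy([0.9, 0.1], [1, 0], 2)
        lo = cross_entropy([0.1, 0.9], [1, 0], 2)
        assert hi < lo

    def test_zero_probability_is_clamped_finite(self):
        val = cross_entropy([1.0, 0.0], [0, 1], 2)
        assert math.isfinite(val) and val > 0


class TestTraining:
    def test_memorizes_single_molecule(self):
        corpus = Corpus.from_smiles(["CCO"] * 4)
        cfg = GeneratorConfig(
            embedding_dim=8, recurrent_layers=1, hidden_units=16,
            epochs=200, batch_size=4, seed=1,
        )
        res = SmilesGenerator(corpus, cfg).fit()
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_loss_trace_deterministic_for_fixed_seed(self, tiny_corpus):
        cfg = GeneratorConfig(
            embedding_dim=8, recurrent_layers=1, hidden_units=16,
            epochs=4, batch_size=16, seed=42,
        )
        a = SmilesGenerator(tiny_corpus, cfg).fit()
        b = SmilesGenerator(tiny_corpus, cfg).fit()
        assert np.array_equal(a.loss_trace, b.loss_trace)
        assert np.array_equal(a.network.parameter_vector(), b.network.parameter_vector())

    def test_training_improves_sampled_validity(self, fixture_corpus, trained_g):
        from tests.conftest import small_config

        untrained = SmilesGenerator(fixture_corpus, small_config(101)).fit(epochs=0)
        samp = SamplingConfig(temperature=0.5, n_samples=200, seed=3)
        v_before, _ = validity_filter(untrained.sample(samp))
        v_after, _ = validity_filter(trained_g[101].sample(samp))
        assert v_after > v_before

    def test_empty_corpus_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            SmilesGenerator(
                Corpus(records=[], vocabulary=tiny_corpus.vocabulary, max_length=100)
            )


class TestSampling:
    def test_zero_samples(self, tiny_g):
        assert tiny_g.sample(SamplingConfig(n_samples=0, seed=0)) == []

    def test_deterministic_for_fixed_seed(self, tiny_g):
        cfg = SamplingConfig(n_samples=50, seed=9)
        assert tiny_g.sample(cfg) == tiny_g.sample(cfg)

    def test_respects_max_length(self, tiny_g):
        samples = tiny_g.sample(SamplingConfig(n_samples=50, seed=9, max_length=12))
        assert all(len(s) <= 12 for s in samples)

    def test_untrained_model_less_valid_than_trained(self, fixture_corpus, trained_g):
        from tests.conftest import small_config

        untrained = SmilesGenerator(fixture_corpus, small_config(101)).fit(epochs=0)
        samp = SamplingConfig(temperature=0.5, n_samples=500, seed=5)
        v_untrained, _ = validity_filter(untrained.sample(samp))
        v_trained, _ = validity_filter(trained_g[101].sample(samp))
        assert v_untrained < v_trained


def test_results_checkpoint_roundtrip(tmp_path, tiny_g):
    path = tmp_path / "ckpt.npz"
    tiny_g.save(path)
    loaded = GeneratorResults.load(path)
    cfg = SamplingConfig(n_samples=20, seed=4)
    assert loaded.sample(cfg) == tiny_g.sample(cfg)
    assert loaded.config == tiny_g.config
    assert np.array_equal(loaded.loss_trace, tiny_g.loss_trace)


def test_summary_mentions_architecture(tiny_g):
    text = tiny_g.summary()
    assert "1 x 24" in text and "epochs trained" in text
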