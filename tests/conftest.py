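"""Shared fixtures: the fixture corpus, desk-scale trained generators and
the two biassing experiments.

Experiment A (comparative): a moderately trained G (60 epochs, validity
around 0.55) biased toward "at most 1 rotatable bond" — rare enough in
what G generates that both methods have headroom over the unbiased count.

Experiment B (CRLV dynamics): a half-trained G (30 epochs, validity around
0.15) biased toward "no aromatic ring" — large validity headroom, which is
the lever CRLV's conditional loss reduction works through.

Everything is seeded; the suite is deterministic.
"""
import pytest

from molbias import (
    CRLVBias,
    CrlvConfig,
    GeneratorConfig,
    ReinforceBias,
    RlConfig,
    SamplingConfig,
    SmilesGenerator,
    generate_fixture_corpus,
)
from molbias.metrics import run_funnel
from molbias.objectives import Objective

SEEDS = (101, 202, 303)
BENCH_SAMPLING = SamplingConfig(temperature=0.5, n_samples=500, seed=1)

RIGID = Objective("rigid", lambda d: d.rot_bonds <= 1, "at most one rotatable bond")
NO_AROMATIC = Objective("no_aromatic", lambda d: d.aromatic_rings == 0, "no aromatic ring")


def small_config(seed: int, epochs: int = 60) -> GeneratorConfig:
    return GeneratorConfig(
        embedding_dim=32, recurrent_layers=1, hidden_units=64,
        epochs=epochs, batch_size=64, seed=seed,
    )


@pytest.fixture(scope="session")
def fixture_corpus():
    return generate_fixture_corpus(500, seed=11, template_set="simple")


@pytest.fixture(scope="session")
def trained_g(fixture_corpus):
    """Experiment-A generators: trained but not saturated."""
    return {s: SmilesGenerator(fixture_corpus, small_config(s)).fit() for s in SEEDS}


@pytest.fixture(scope="session")
def weak_g(fixture_corpus):
    """Experiment-B generators: half-trained, large validity headroom."""
    return {s: SmilesGenerator(fixture_corpus, small_config(s, epochs=30)).fit() for s in SEEDS}


@pytest.fixture(scope="session")
def crlv_rigid(trained_g, fixture_corpus):
    return {
        s: CRLVBias(trained_g[s], fixture_corpus, RIGID, CrlvConfig(epochs=50, seed=s)).fit()
        for s in SEEDS
    }


@pytest.fixture(scope="session")
def rl_rigid(trained_g):
    return {
        s: ReinforceBias(
            trained_g[s], RIGID,
            RlConfig(epochs=50, seed=s, learning_rate=2e-4, batch_episodes=32),
        ).fit()
        for s in SEEDS
    }


@pytest.fixture(scope="session")
def crlv_no_aromatic(weak_g, fixture_corpus):
    return {
        s: CRLVBias(weak_g[s], fixture_corpus, NO_AROMATIC, CrlvConfig(epochs=50, seed=s)).fit()
        for s in SEEDS
    }


@pytest.fixture(scope="session")
def experiment_funnels(fixture_corpus, trained_g, crlv_rigid, rl_rigid):
    """Benchmark funnels (500 samples, T=0.5) for every experiment-A model."""
    out = {}
    for s in SEEDS:
        out[s] = {
            "g": run_funnel(trained_g[s].sample(BENCH_SAMPLING), fixture_corpus, RIGID),
            "crlv_best": run_funnel(crlv_rigid[s].best_model.sample(BENCH_SAMPLING), fixture_corpus, RIGID),
            "crlv_final": run_funnel(crlv_rigid[s].final_model.sample(BENCH_SAMPLING), fixture_corpus, RIGID),
            "rl_best": run_funnel(rl_rigid[s].best_model.sample(BENCH_SAMPLING), fixture_corpus, RIGID),
            "rl_final": run_funnel(rl_rigid[s].final_model.sample(BENCH_SAMPLING), fixture_corpus, RIGID),
        }
    return out


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 60-molecule corpus for fast unit tests."""
    return generate_fixture_corpus(60, seed=5)


@pytest.fixture(scope="session")
def tiny_g(tiny_corpus):
    """A very small, briefly trained generator for contract tests."""
    cfg = GeneratorConfig(
        embedding_dim=12, recurrent_layers=1, hidden_units=24,
        epochs=8, batch_size=16, seed=0,
    )
    return SmilesGenerator(tiny_corpus, cfg).fit()
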