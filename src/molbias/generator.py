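"""The general model G: an autoregressive character-level SMILES generator.

``SmilesGenerator`` is the model object (corpus + configuration); ``fit``
runs teacher-forced cross-entropy training and returns a
``GeneratorResults`` carrying the trained network, the per-epoch loss
trace, sampling, checkpointing and a summary table.

Sampling draws one character at a time from a temperature-scaled softmax
(T < 1 sharpens the distribution, T > 1 flattens it); training always uses
T = 1.  Generation starts from the reserved start token and stops at the
end token or at ``max_length`` characters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import Corpus, Vocabulary, detokenize
from .nn import Adam, GRUNetwork, log_softmax, weighted_nll

__all__ = [
    "GeneratorConfig",
    "SamplingConfig",
    "SmilesGenerator",
    "GeneratorResults",
    "temperature_softmax",
    "cross_entropy",
    "train_general_model",
    "sample_smiles",
]

EPS_LOG = 1e-12  # floor inside log() so a zero probability is never infinite


def temperature_softmax(logits: np.ndarray, T: float = 1.0) -> np.ndarray:
    """Softmax of logits / T over the last axis, max-shifted for stability.

    T = 1 is the plain softmax; entries are positive and sum to 1.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0 or not np.all(np.isfinite(logits)):
        raise ValueError("logits must be a non-empty finite array")
    scaled = logits / T
    scaled = scaled - scaled.max(axis=-1, keepdims=True)
    exps = np.exp(scaled)
    return exps / exps.sum(axis=-1, keepdims=True)


def cross_entropy(yp: np.ndarray, yr: np.ndarray, k: int | None = None) -> float:
    """Cross-entropy between a predicted distribution and a one-hot target,
    with the 1/k prefactor: CE = -(1/k) * sum_i yr_i * log(yp_i).

    The 1/k prefactor makes this a rescaling of the conventional
    -log(yp[true]); the training loop uses the conventional per-token mean
    (the constant only rescales the learning rate).  Probabilities are
    floored at 1e-12 inside the log so the result is never infinite.
    """
    yp = np.asarray(yp, dtype=float)
    yr = np.asarray(yr, dtype=float)
    if k is None:
        k = yp.shape[-1]
    if yp.shape != yr.shape or yp.shape[-1] != k:
        raise ValueError("yp and yr must both have length k")
    if np.any(yp < -1e-9) or abs(yp.sum() - 1.0) > 1e-6:
        raise ValueError("yp must be a probability vector")
    return float(-(1.0 / k) * (yr * np.log(np.clip(yp, EPS_LOG, None))).sum())


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture and optimization settings of the general model.

    Defaults follow the reference pipeline: 3 GRU layers of 512 units,
    Adam at learning rate 5e-4.  The embedding width is a free choice
    (default 128).  Desk-scale experiments shrink layers/units via replace().
    """

    embedding_dim: int = 128
    recurrent_layers: int = 3
    hidden_units: int = 512
    learning_rate: float = 5e-4
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if min(self.embedding_dim, self.recurrent_layers, self.hidden_units,
               self.epochs + 1, self.batch_size) < 1:
            raise ValueError("all dimensions must be >= 1 and epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SamplingConfig:
    temperature: float = 0.50
    max_length: int = 100
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.max_length < 1 or self.n_samples < 0:
            raise ValueError("max_length >= 1 and n_samples >= 0 required")

    def replace(self, **kw) -> "SamplingConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------- #
def _pad_batch(seqs: list[np.ndarray], pad_id: int):
    """Stack variable-length (start...end) sequences into X (inputs),
    Y (next-token targets) and a loss mask over real target positions."""
    T = max(len(s) for s in seqs) - 1
    B = len(seqs)
    X = np.full((B, T), pad_id, dtype=np.int64)
    Y = np.full((B, T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        n = len(s) - 1
        X[i, :n] = s[:-1]
        Y[i, :n] = s[1:]
    mask = (Y != pad_id).astype(float)
    return X, Y, mask


def train_epoch(
    net: GRUNetwork,
    optimizer: Adam,
    encoded: list[np.ndarray],
    batch_size: int,
    rng: np.random.Generator,
    pad_id: int,
    loss_scale: float = 1.0,
) -> float:
    """One shuffled pass over the corpus; returns the mean (unscaled)
    per-token loss.

    ``loss_scale`` multiplies the loss that is backpropagated — the CRLV
    mechanism.  At loss_scale == 0 the optimizer step is skipped entirely
    (not merely given zero gradients), so parameters are exactly unchanged.
    """
    order = rng.permutation(len(encoded))
    total = 0.0
    total_tokens = 0
    for start in range(0, len(order), batch_size):
        batch = [encoded[i] for i in order[start:start + batch_size]]
        X, Y, mask = _pad_batch(batch, pad_id)
        n_tok = mask.sum()
        weights = mask / n_tok
        loss, grads = weighted_nll(net, X, Y, weights, grad_scale=loss_scale)
        if not np.isfinite(loss):
            raise RuntimeError("training diverged: non-finite loss")
        if grads is not None:
            optimizer.step(net.params, grads)
        total += loss * n_tok
        total_tokens += n_tok
    return total / total_tokens


def _sample_tokens(
    net: GRUNetwork,
    vocab: Vocabulary,
    sampling: SamplingConfig,
    rng: np.random.Generator,
    return_logprobs: bool = False,
):
    """Batched autoregressive sampling.  Returns a list of action arrays
    (token ids, including the terminating end token when emitted) and,
    optionally, the matching per-action log-probabilities under T=1
    (the policy REINFORCE optimizes)."""
    n = sampling.n_samples
    if n == 0:
        return ([], []) if return_logprobs else []
    state = net.init_state(n)
    x = np.full(n, vocab.start_id, dtype=np.int64)
    finished = np.zeros(n, dtype=bool)
    actions = [[] for _ in range(n)]
    logps = [[] for _ in range(n)]
    forbidden = [vocab.pad_id, vocab.start_id]
    for _ in range(sampling.max_length):
        logits = net.step(x, state)
        logits[:, forbidden] = -1e9
        probs = temperature_softmax(logits, sampling.temperature)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        ids = (u[:, None] > cum).sum(axis=1).astype(np.int64)
        ids = np.minimum(ids, net.vocab_size - 1)
        if return_logprobs:
            lp = log_softmax(logits)
        for i in range(n):
            if finished[i]:
                continue
            actions[i].append(int(ids[i]))
            if return_logprobs:
                logps[i].append(float(lp[i, ids[i]]))
        finished |= ids == vocab.end_id
        if finished.all():
            break
        ids[finished] = vocab.end_id
        x = ids
    actions = [np.array(a, dtype=np.int64) for a in actions]
    if return_logprobs:
        return actions, [np.array(l) for l in logps]
    return actions


def sample_smiles(net: GRUNetwork, vocab: Vocabulary, sampling: SamplingConfig) -> list[str]:
    """Draw ``n_samples`` SMILES strings (possibly chemically invalid) from
    the model at the configured temperature; deterministic for a fixed seed."""
    rng = np.random.default_rng(sampling.seed)
    actions = _sample_tokens(net, vocab, sampling, rng)
    return [detokenize(a, vocab) for a in actions]


# --------------------------------------------------------------------- #
class SmilesGenerator:
    """The general model G, bound to a training corpus.

    Examples
    --------
    >>> corpus = generate_fixture_corpus(500, seed=11)          # doctest: +SKIP
    >>> res = SmilesGenerator(corpus, GeneratorConfig()).fit()  # doctest: +SKIP
    >>> res.sample(SamplingConfig(n_samples=100, seed=1))       # doctest: +SKIP
    """

    def __init__(self, corpus: Corpus, config: GeneratorConfig | None = None):
        if len(corpus) == 0:
            raise ValueError("corpus is empty")
        self.corpus = corpus
        self.config = config or GeneratorConfig()
        self._encoded = corpus.encoded()

    def fit(self, epochs: int | None = None) -> "GeneratorResults":
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        vocab = self.corpus.vocabulary
        net = GRUNetwork(
            vocab_size=vocab.size_k,
            embedding_dim=cfg.embedding_dim,
            hidden_units=cfg.hidden_units,
            num_layers=cfg.recurrent_layers,
            rng=np.random.default_rng([cfg.seed, 3]),
        )
        optimizer = Adam(lr=cfg.learning_rate)
        losses = []
        for epoch in range(epochs):
            rng = np.random.default_rng([cfg.seed, 7, epoch])
            losses.append(
                train_epoch(net, optimizer, self._encoded, cfg.batch_size, rng,
                            vocab.pad_id)
            )
        return GeneratorResults(
            network=net, vocabulary=vocab, config=cfg,
            loss_trace=np.array(losses), model=self,
        )


@dataclass
class GeneratorResults:
    """A trained (or freshly initialized) generator with its loss trace."""

    network: GRUNetwork
    vocabulary: Vocabulary
    config: GeneratorConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    model: SmilesGenerator | None = None

    def sample(self, sampling: SamplingConfig | None = None, **kw) -> list[str]:
        sampling = (sampling or SamplingConfig()).replace(**kw) if kw else (sampling or SamplingConfig())
        return sample_smiles(self.network, self.vocabulary, sampling)

    def sequence_logprob(self, smiles: str) -> float:
        """log p(smiles) under the model at T=1 (sum over characters and the
        terminating end token)."""
        from .corpus import tokenize

        ids = np.array(tokenize(smiles, self.vocabulary))
        return self.token_logprob(ids[1:])  # actions: chars + end

    def token_logprob(self, actions: np.ndarray) -> float:
        """log-probability of an action sequence (ids, ending in end_id)."""
        X = np.concatenate([[self.vocabulary.start_id], actions[:-1]])[None, :]
        logits, _ = self.network.forward(X)
        lp = log_softmax(logits[0])
        return float(lp[np.arange(len(actions)), actions].sum())

    def spawn(self) -> "GeneratorResults":
        """Deep-copied results (fresh network) for biassing runs."""
        return GeneratorResults(
            network=self.network.copy(), vocabulary=self.vocabulary,
            config=self.config, loss_trace=self.loss_trace.copy(), model=self.model,
        )

    def summary(self) -> str:
        lines = [
            "SMILES generator (character-level GRU)",
            f"  vocabulary size (k): {self.vocabulary.size_k}",
            f"  layers x units:      {self.config.recurrent_layers} x {self.config.hidden_units}",
            f"  embedding dim:       {self.config.embedding_dim}",
            f"  parameters:          {self.network.n_parameters()}",
            f"  epochs trained:      {len(self.loss_trace)}",
        ]
        if len(self.loss_trace):
            lines.append(f"  loss first -> last:  {self.loss_trace[0]:.4f} -> {self.loss_trace[-1]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        path = Path(path)
        self.network.save(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "format": "molbias-checkpoint-v1",
            "config": self.config.__dict__,
            "vocabulary": self.vocabulary.to_dict(),
            "loss_trace": [float(x) for x in self.loss_trace],
        }, indent=2))

    @classmethod
    def load(cls, path) -> "GeneratorResults":
        path = Path(path)
        net = GRUNetwork.load(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            network=net,
            vocabulary=Vocabulary.from_dict(meta["vocabulary"]),
            config=GeneratorConfig(**meta["config"]),
            loss_trace=np.array(meta["loss_trace"]),
        )


def train_general_model(corpus: Corpus, config: GeneratorConfig | None = None) -> GeneratorResults:
    """Functional entry point: train G on a corpus and return the results."""
    return SmilesGenerator(corpus, config).fit()
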