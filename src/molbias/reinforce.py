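"""REINFORCE policy-gradient biassing (the comparison baseline).

The generator is treated as a policy over characters: an episode is one
sampled SMILES (the end token included as the final action), the reward is
terminal and depends only on the finished molecule, and one update step
performs gradient ascent on the batch mean of

    sum_t log p(a_t | s_t) * r

with the terminal reward broadcast to every step — plain REINFORCE, no
discounting and no baseline subtraction.  Episodes are sampled from the
policy itself (temperature 1); the best-epoch probe uses the benchmark
temperature so the selected checkpoint is the one that scores best under
the evaluation conditions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biasing import BiasedModelResult, is_desirable, probe_count
from .corpus import detokenize
from .generator import GeneratorResults, SamplingConfig, _sample_tokens
from .nn import Adam, GRUNetwork, weighted_nll
from .objectives import Objective
from rdkit import Chem

__all__ = ["RlConfig", "Episode", "episode_reward", "reinforce_update", "ReinforceBias", "run_reinforce"]


@dataclass(frozen=True)
class RlConfig:
    reward_desirable: float = 1.0
    reward_valid_undesirable: float = 0.0
    reward_invalid: float = -0.1
    epochs: int = 50
    batch_episodes: int = 32
    learning_rate: float = 5e-4
    checkpoint_probe_k: int = 20
    seed: int = 0
    use_baseline: bool = False  # optional moving-average baseline, OFF by default
    sampling: SamplingConfig = field(default_factory=lambda: SamplingConfig(temperature=1.0))
    probe_sampling: SamplingConfig = field(default_factory=lambda: SamplingConfig(temperature=0.50))

    def __post_init__(self):
        if not (self.reward_desirable > self.reward_valid_undesirable >= self.reward_invalid):
            raise ValueError(
                "rewards must satisfy desirable > valid_undesirable >= invalid"
            )
        if self.epochs < 0 or self.batch_episodes < 1 or self.learning_rate <= 0:
            raise ValueError("invalid RL configuration")

    def replace(self, **kw) -> "RlConfig":
        return replace(self, **kw)


@dataclass
class Episode:
    """One sampled molecule: the action sequence (token ids, terminating end
    token included when emitted), per-action log-probabilities at sampling
    time, the detokenized SMILES and the terminal reward."""

    actions: np.ndarray
    logprobs: np.ndarray
    smiles: str
    reward: float = 0.0

    @property
    def states(self) -> list[np.ndarray]:
        """Token-id prefix (state) preceding each action."""
        return [self.actions[:t] for t in range(len(self.actions))]


def episode_reward(smiles: str, objective: Objective, config: RlConfig) -> float:
    """Terminal reward: desirable / valid-but-undesirable / invalid."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return config.reward_invalid
    if is_desirable(smiles, objective):
        return config.reward_desirable
    return config.reward_valid_undesirable


def sample_episodes(
    results: GeneratorResults,
    n: int,
    sampling: SamplingConfig,
    seed,
) -> list[Episode]:
    rng = np.random.default_rng(seed)
    actions, logps = _sample_tokens(
        results.network, results.vocabulary,
        sampling.replace(n_samples=n), rng, return_logprobs=True,
    )
    return [
        Episode(actions=a, logprobs=lp, smiles=detokenize(a, results.vocabulary))
        for a, lp in zip(actions, logps)
    ]


def reinforce_update(
    net: GRUNetwork,
    optimizer: Adam,
    episodes: list[Episode],
    pad_id: int,
    start_id: int,
) -> float:
    """One gradient-ascent step on the batch objective; returns the mean
    reward.  A batch whose rewards are all zero leaves the parameters
    exactly unchanged (the optimizer step is skipped)."""
    B = len(episodes)
    if B == 0:
        return 0.0
    T = max(len(ep.actions) for ep in episodes)
    X = np.full((B, T), pad_id, dtype=np.int64)
    Y = np.full((B, T), pad_id, dtype=np.int64)
    W = np.zeros((B, T))
    for i, ep in enumerate(episodes):
        a = ep.actions
        if len(a) == 0:
            continue
        X[i, 0] = start_id
        X[i, 1:len(a)] = a[:-1]
        Y[i, :len(a)] = a
        # terminal reward broadcast over all steps; ascent on r*logp ==
        # descent on r*(-logp), so the NLL weight is +r
        W[i, :len(a)] = ep.reward / B
    loss, grads = weighted_nll(net, X, Y, W)
    if grads is not None:
        for g in grads.values():
            if not np.all(np.isfinite(g)):
                raise RuntimeError("REINFORCE diverged: non-finite gradient")
        optimizer.step(net.params, grads)
    return float(np.mean([ep.reward for ep in episodes]))


class ReinforceBias:
    """Bias a pretrained generator with REINFORCE; ``fit()`` returns a
    :class:`BiasedModelResult` with the mean-reward trace."""

    def __init__(
        self,
        pretrained: GeneratorResults,
        objective: Objective,
        config: RlConfig | None = None,
    ):
        self.pretrained = pretrained
        self.objective = objective
        self.config = config or RlConfig()

    def fit(self) -> BiasedModelResult:
        cfg = self.config
        current = self.pretrained.spawn()
        optimizer = Adam(lr=cfg.learning_rate)
        best = current.spawn()
        best_epoch = -1
        best_count = -1
        baseline = 0.0
        rows = []
        for epoch in range(cfg.epochs):
            episodes = sample_episodes(
                current, cfg.batch_episodes, cfg.sampling, seed=[cfg.seed, 17, epoch]
            )
            for ep in episodes:
                ep.reward = episode_reward(ep.smiles, self.objective, cfg)
            raw_mean = float(np.mean([ep.reward for ep in episodes]))
            if cfg.use_baseline:
                for ep in episodes:
                    ep.reward -= baseline
                baseline = 0.9 * baseline + 0.1 * raw_mean
            reinforce_update(
                current.network, optimizer, episodes,
                current.vocabulary.pad_id, current.vocabulary.start_id,
            )
            k_count = probe_count(
                current, self.objective, cfg.checkpoint_probe_k,
                cfg.probe_sampling, seed=[cfg.seed, 13, epoch],
            )
            if k_count > best_count:
                best = current.spawn()
                best_epoch = epoch
                best_count = k_count
            n_desirable = sum(ep.reward == cfg.reward_desirable for ep in episodes) if not cfg.use_baseline else None
            rows.append({
                "epoch": epoch, "mean_reward": raw_mean,
                "n_desirable": n_desirable, "probe_count": k_count,
            })
        trace = pd.DataFrame(rows, columns=["epoch", "mean_reward", "n_desirable", "probe_count"])
        return BiasedModelResult(
            final_model=current, best_model=best,
            best_epoch=best_epoch if best_epoch >= 0 else 0,
            trace=trace, method="REINFORCE", objective_name=self.objective.name,
        )


def run_reinforce(
    pretrained: GeneratorResults,
    objective: Objective,
    config: RlConfig | None = None,
) -> BiasedModelResult:
    """Functional entry point mirroring :class:`ReinforceBias`."""
    return ReinforceBias(pretrained, objective, config).fit()
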