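"""Conditional reduction of the loss value (CRLV).

CRLV biasses a pretrained generator by re-running its ordinary
teacher-forced cross-entropy training loop on the general corpus, but
scaling the backpropagated loss by a factor conditioned on how often the
current model already produces molecules inside the desired chemical
space.  Each epoch first samples ``n_probe`` molecules and measures the
desirable fraction d; the default rule then multiplies the loss by
(1 - d):

* d = 0 — the model generates nothing desirable: the full general-training
  loss is backpropagated, so the model keeps learning (and keeps knowing)
  how valid molecules look while drifting through chemical space;
* d = 1 — everything generated is desirable: the backpropagated loss is
  zero and parameters stay exactly where they are.

Because the loss is the same one used to train G, the biased model retains
validity/novelty/diversity far better than policy-gradient fine-tuning
(negligible catastrophic forgetting); the best-epoch checkpoint captures
the most desirable intermediate model.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biasing import BiasedModelResult, count_desirable, probe_count
from .corpus import Corpus
from .generator import GeneratorResults, SamplingConfig, sample_smiles, train_epoch
from .nn import Adam
from .objectives import Objective

__all__ = ["CrlvConfig", "CRLVBias", "crlv_loss_scale", "desirable_fraction", "run_crlv"]

from .biasing import desirable_fraction  # re-export at the method's surface

STEP_EPSILON = 1e-6


def crlv_loss_scale(d: float, rule: str = "linear") -> float:
    """Loss-scale factor as a function of the desirable fraction d.

    "linear"   -> 1 - d  (default; full loss at d=0, zero loss at d=1)
    "step@TAU" -> 1 if d < TAU else a negligible epsilon
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"desirable fraction must be in [0, 1], got {d}")
    if rule == "linear":
        return 1.0 - d
    if rule.startswith("step@"):
        tau = float(rule.split("@", 1)[1])
        return 1.0 if d < tau else STEP_EPSILON
    raise ValueError(f"unknown scale rule {rule!r}")


@dataclass(frozen=True)
class CrlvConfig:
    n_probe: int = 20
    scale_rule: str = "linear"
    epochs: int = 50
    checkpoint_probe_k: int = 20
    learning_rate: float = 5e-4
    batch_size: int = 64
    seed: int = 0
    require_validity: bool = True
    sampling: SamplingConfig = field(default_factory=lambda: SamplingConfig(temperature=0.50))

    def __post_init__(self):
        if self.n_probe < 1 or self.checkpoint_probe_k < 1:
            raise ValueError("n_probe and checkpoint_probe_k must be >= 1")
        if self.learning_rate <= 0 or self.epochs < 0:
            raise ValueError("learning_rate > 0 and epochs >= 0 required")

    def replace(self, **kw) -> "CrlvConfig":
        return replace(self, **kw)


class CRLVBias:
    """Bias a pretrained generator toward an objective by conditional loss
    reduction; ``fit()`` returns a :class:`BiasedModelResult`."""

    def __init__(
        self,
        pretrained: GeneratorResults,
        corpus: Corpus,
        objective: Objective,
        config: CrlvConfig | None = None,
    ):
        self.pretrained = pretrained
        self.corpus = corpus
        self.objective = objective
        self.config = config or CrlvConfig()
        self._encoded = corpus.encoded()

    def fit(self) -> BiasedModelResult:
        cfg = self.config
        vocab = self.pretrained.vocabulary
        current = self.pretrained.spawn()
        optimizer = Adam(lr=cfg.learning_rate)
        best = current.spawn()
        best_epoch = -1
        best_count = -1
        rows = []
        for epoch in range(cfg.epochs):
            # 1. probe the current model for the desirable fraction d
            probe = sample_smiles(
                current.network, vocab,
                cfg.sampling.replace(n_samples=cfg.n_probe, seed=[cfg.seed, 11, epoch]),
            )
            d = count_desirable(probe, self.objective, cfg.require_validity) / cfg.n_probe
            scale = crlv_loss_scale(d, cfg.scale_rule)
            # 2. one ordinary training pass with the scaled loss
            rng = np.random.default_rng([cfg.seed, 7, epoch])
            mean_loss = train_epoch(
                current.network, optimizer, self._encoded, cfg.batch_size, rng,
                vocab.pad_id, loss_scale=scale,
            )
            # 3. best-epoch probe (strict improvement keeps the earlier model)
            k_count = probe_count(
                current, self.objective, cfg.checkpoint_probe_k,
                cfg.sampling, seed=[cfg.seed, 13, epoch],
                require_validity=cfg.require_validity,
            )
            if k_count > best_count:
                best = current.spawn()
                best_epoch = epoch
                best_count = k_count
            rows.append({
                "epoch": epoch, "desirable_fraction": d, "loss_scale": scale,
                "mean_loss": mean_loss, "probe_count": k_count,
            })
        trace = pd.DataFrame(rows, columns=["epoch", "desirable_fraction", "loss_scale", "mean_loss", "probe_count"])
        return BiasedModelResult(
            final_model=current, best_model=best,
            best_epoch=best_epoch if best_epoch >= 0 else 0,
            trace=trace, method="CRLV", objective_name=self.objective.name,
        )


def run_crlv(
    pretrained: GeneratorResults,
    corpus: Corpus,
    objective: Objective,
    config: CrlvConfig | None = None,
) -> BiasedModelResult:
    """Functional entry point mirroring :class:`CRLVBias`."""
    return CRLVBias(pretrained, corpus, objective, config).fit()
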