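"""Shared machinery for the two biassing methods.

Both CRLV and REINFORCE fine-tune a pretrained general model toward an
objective and track the best-epoch checkpoint: after every epoch the
current model generates k probe molecules (k = 20 by default) and the
checkpoint is replaced only when the desirable count *strictly* surpasses
the best seen so far (ties keep the earlier epoch).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .generator import GeneratorResults, SamplingConfig, sample_smiles
from .objectives import Objective, descriptors_from_mol

__all__ = ["BiasedModelResult", "is_desirable", "count_desirable", "desirable_fraction"]


def is_desirable(smiles: str, objective: Objective, require_validity: bool = True) -> bool:
    """Valid (parses and sanitizes) AND objective-satisfying.

    With ``require_validity=False`` the objective predicate is applied
    regardless of validity and receives None as its descriptor set for
    unparsable strings (useful only for validity-free predicates)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False if require_validity else bool(objective.predicate(None))
    return bool(objective.predicate(descriptors_from_mol(mol)))


def count_desirable(smiles_list, objective: Objective, require_validity: bool = True) -> int:
    return sum(is_desirable(s, objective, require_validity) for s in smiles_list)


def desirable_fraction(
    results: GeneratorResults,
    objective: Objective,
    n: int,
    sampling: SamplingConfig,
    seed: int | None = None,
    require_validity: bool = True,
) -> float:
    """Sample n molecules and return (valid AND desirable) / n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampling = sampling.replace(n_samples=n, **({"seed": seed} if seed is not None else {}))
    samples = sample_smiles(results.network, results.vocabulary, sampling)
    return count_desirable(samples, objective, require_validity) / n


def probe_count(
    results: GeneratorResults,
    objective: Objective,
    k: int,
    sampling: SamplingConfig,
    seed,
    require_validity: bool = True,
) -> int:
    samples = sample_smiles(
        results.network, results.vocabulary,
        sampling.replace(n_samples=k, seed=seed),
    )
    return count_desirable(samples, objective, require_validity)


@dataclass
class BiasedModelResult:
    """Outcome of a biassing run: the last-epoch model, the best-epoch model
    under the strict-improvement probe rule, and the per-epoch trace."""

    final_model: GeneratorResults
    best_model: GeneratorResults
    best_epoch: int
    trace: pd.DataFrame
    method: str = ""
    objective_name: str = ""

    def summary(self) -> str:
        lines = [
            f"{self.method} biassing toward {self.objective_name!r}",
            f"  epochs run:  {len(self.trace)}",
            f"  best epoch:  {self.best_epoch}",
        ]
        if len(self.trace):
            cols = ", ".join(
                f"{c}={self.trace[c].iloc[-1]:.4g}" for c in self.trace.columns if c != "epoch"
            )
            lines.append(f"  last epoch:  {cols}")
        return "\n".join(lines)
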