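"""The evaluation funnel for generated molecules.

Generated strings pass through four sequential stages, each fraction taken
relative to the previous stage:

validity    — fraction of generated strings that parse and sanitize;
novelty     — fraction of valid molecules whose canonical form is absent
              from the training set;
uniqueness  — fraction of novel molecules remaining after canonical-form
              deduplication;
desirability — fraction (and, importantly, integer count) of unique
              molecules satisfying the objective.

Internal diversity (intDiv) of the unique set is 1 minus the mean pairwise
Tanimoto similarity of 1024-bit radius-2 circular fingerprints over the
full |S| x |S| matrix (diagonal included, which makes the singleton case
well defined and exactly 0).

Desirability is always reported both as a percentage and as a count:
percentages can mislead when only a handful of molecules survive the
funnel, so a model can win on percentage while losing badly on count.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .corpus import Corpus
from .generator import GeneratorResults, SamplingConfig
from .objectives import Objective, descriptors_from_mol

__all__ = [
    "FunnelResult",
    "BenchmarkReport",
    "validity_filter",
    "novelty_filter",
    "uniqueness_filter",
    "internal_diversity",
    "desirability",
    "run_funnel",
    "run_benchmark",
    "temperature_sweep",
]


def validity_filter(generated: list[str]) -> tuple[float, list[str]]:
    """Keep strings that parse AND sanitize; return (fraction, canonical
    forms in input order).  Empty input yields fraction 0 with a warning."""
    if not generated:
        warnings.warn("validity_filter called on an empty list", stacklevel=2)
        return 0.0, []
    valid = []
    for s in generated:
        mol = Chem.MolFromSmiles(s)  # sanitizes by default
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    return len(valid) / len(generated), valid


def novelty_filter(valid: list[str], training: Corpus | set) -> tuple[float, list[str]]:
    """Novel = canonical form absent from the training set's canonical
    forms.  Fraction is relative to the valid list."""
    train_set = training.canonical_set() if isinstance(training, Corpus) else set(training)
    novel = [s for s in valid if s not in train_set]
    return (len(novel) / len(valid) if valid else 0.0), novel


def uniqueness_filter(novel: list[str]) -> tuple[float, list[str]]:
    """Deduplicate by canonical form, first occurrence kept."""
    seen: set[str] = set()
    unique = []
    for s in novel:
        if s not in seen:
            seen.add(s)
            unique.append(s)
    return (len(unique) / len(novel) if novel else 0.0), unique


def _fingerprints(smiles_list: list[str], radius: int, n_bits: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES in fingerprint input: {s!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def internal_diversity(unique: list[str], radius: int = 2, n_bits: int = 1024) -> float:
    """1 - mean pairwise Tanimoto over the full matrix (diagonal included)."""
    if not unique:
        raise ValueError("internal diversity is undefined for an empty set")
    fps = _fingerprints(unique, radius, n_bits)
    n = len(fps)
    total = 0.0
    for fp in fps:
        total += sum(DataStructs.BulkTanimotoSimilarity(fp, fps))
    return 1.0 - total / (n * n)


def desirability(unique: list[str], objective: Objective) -> tuple[float, int, list[str]]:
    """Fraction AND integer count of objective-passing molecules."""
    passing = []
    for s in unique:
        mol = Chem.MolFromSmiles(s)
        if mol is not None and objective.predicate(descriptors_from_mol(mol)):
            passing.append(s)
    frac = len(passing) / len(unique) if unique else 0.0
    return frac, len(passing), passing


@dataclass
class FunnelResult:
    """All stages of the funnel for one generated batch.  Fractions are in
    [0, 1]; ``summary()`` and reports display percentages."""

    n_generated: int
    validity: float
    valid_set: list[str]
    novelty: float
    novel_set: list[str]
    uniqueness: float
    unique_set: list[str]
    int_div: float
    desirability_fraction: float = 0.0
    desirability_count: int = 0
    desirable_set: list[str] = field(default_factory=list)

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.n_generated, len(self.valid_set), len(self.novel_set),
                len(self.unique_set), self.desirability_count)

    def to_row(self) -> dict:
        return {
            "validity": self.validity, "novelty": self.novelty,
            "uniqueness": self.uniqueness, "int_div": self.int_div,
            "desirability_pct": 100.0 * self.desirability_fraction,
            "desirability_count": self.desirability_count,
        }


def run_funnel(
    generated: list[str],
    training: Corpus | set,
    objective: Objective | None = None,
    radius: int = 2,
    n_bits: int = 1024,
) -> FunnelResult:
    v_frac, valid = validity_filter(generated)
    n_frac, novel = novelty_filter(valid, training)
    u_frac, unique = uniqueness_filter(novel)
    int_div = internal_diversity(unique, radius, n_bits) if unique else 0.0
    d_frac, d_count, d_set = desirability(unique, objective) if objective else (0.0, 0, [])
    return FunnelResult(
        n_generated=len(generated), validity=v_frac, valid_set=valid,
        novelty=n_frac, novel_set=novel, uniqueness=u_frac, unique_set=unique,
        int_div=int_div, desirability_fraction=d_frac,
        desirability_count=d_count, desirable_set=d_set,
    )


@dataclass
class BenchmarkReport:
    """Per-seed funnel results plus mean +/- sd, in the shape used to report
    generator benchmarks (validity / novelty / uniqueness / intDiv /
    desirability % and count)."""

    model_id: str
    objective_id: str
    temperature: float
    n: int
    seeds: list
    per_seed: pd.DataFrame
    funnels: list[FunnelResult]

    @property
    def summary(self) -> pd.DataFrame:
        agg = self.per_seed.drop(columns=["seed"]).agg(["mean", "std"])
        return agg

    def summary_text(self) -> str:
        m = self.per_seed.mean(numeric_only=True)
        s = self.per_seed.std(numeric_only=True)
        parts = [f"benchmark of {self.model_id} (objective={self.objective_id}, "
                 f"T={self.temperature}, n={self.n}, {len(self.seeds)} seed(s))"]
        for col in ("validity", "novelty", "uniqueness"):
            parts.append(f"  {col:<12} {100*m[col]:6.1f} % +/- {100*(s[col] if len(self.seeds) > 1 else 0):.1f}")
        parts.append(f"  {'intDiv':<12} {m['int_div']:6.3f}")
        parts.append(f"  desirability {m['desirability_pct']:6.2f} % = {m['desirability_count']:.0f} molecules")
        return "\n".join(parts)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "model_id": self.model_id, "objective": self.objective_id,
            "temperature": self.temperature, "n": self.n,
            "seeds": [int(s) for s in self.seeds],
            "rows": self.per_seed.to_dict(orient="records"),
        }, indent=2))

    def to_csv(self, path) -> None:
        self.per_seed.to_csv(path, index=False)


def run_benchmark(
    results: GeneratorResults,
    training: Corpus | set,
    objective: Objective | None = None,
    n: int = 1000,
    sampling: SamplingConfig | None = None,
    seeds=(0,),
    model_id: str = "model",
) -> BenchmarkReport:
    """Sample n molecules per seed, run the funnel, report mean +/- sd."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampling = sampling or SamplingConfig()
    rows = []
    funnels = []
    for seed in seeds:
        generated = results.sample(sampling.replace(n_samples=n, seed=seed))
        funnel = run_funnel(generated, training, objective)
        funnels.append(funnel)
        rows.append({"seed": seed, **funnel.to_row()})
    per_seed = pd.DataFrame(rows)
    return BenchmarkReport(
        model_id=model_id,
        objective_id=objective.name if objective else "none",
        temperature=sampling.temperature, n=n, seeds=list(seeds),
        per_seed=per_seed, funnels=funnels,
    )


def temperature_sweep(
    results: GeneratorResults,
    training: Corpus | set,
    temps,
    n: int = 1000,
    seeds=(0,),
    objective: Objective | None = None,
) -> pd.DataFrame:
    """One benchmark row per temperature, same seeds across rows."""
    if any(t <= 0 for t in temps):
        raise ValueError("all temperatures must be > 0")
    rows = []
    for T in temps:
        report = run_benchmark(
            results, training, objective, n=n,
            sampling=SamplingConfig(temperature=T), seeds=seeds,
        )
        mean = report.per_seed.mean(numeric_only=True)
        rows.append({
            "temperature": T,
            "validity": mean["validity"], "novelty": mean["novelty"],
            "uniqueness": mean["uniqueness"], "int_div": mean["int_div"],
        })
    return pd.DataFrame(rows)
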