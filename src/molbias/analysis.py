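"""Cross-model comparisons and difficulty diagnostics.

* intersection of two generated sets (canonical-form overlap after
  deduplication) — low overlap between two biassing methods means they can
  be used jointly to enlarge the desirable library;
* per-molecule descriptor distributions for property-shift comparisons;
* fingerprint matrices for external projection (UMAP etc. — the projection
  itself is out of scope, only the matrix export lives here);
* objective difficulty profiles: how often a reference corpus satisfies an
  objective, and the structural-variance distribution of the satisfying
  molecules.  Difficulty grows as corpus frequency falls and as the SV of
  the satisfying molecules rises.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .corpus import Corpus
from .objectives import Objective, descriptors_from_mol, structural_variance

__all__ = [
    "IntersectionResult",
    "DifficultyProfile",
    "intersection_percentage",
    "property_distribution",
    "fingerprint_matrix",
    "difficulty_profile",
]


@dataclass(frozen=True)
class IntersectionResult:
    set_a_size: int
    set_b_size: int
    n_overlap: int
    pct_overlap: float


def _canonical_dedup(smiles_list) -> set[str]:
    out = set()
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            out.add(Chem.MolToSmiles(mol))
    return out


def intersection_percentage(set_a, set_b) -> IntersectionResult:
    """Canonicalize and deduplicate each side, count the canonical overlap.

    The headline percentage is overlap / the smaller deduplicated set (the
    most conservative denominator); both set sizes and the raw overlap are
    reported so any other convention can be recovered.
    """
    a = _canonical_dedup(set_a)
    b = _canonical_dedup(set_b)
    if not a or not b:
        raise ValueError("both sets must be non-empty after canonical deduplication")
    overlap = len(a & b)
    return IntersectionResult(
        set_a_size=len(a), set_b_size=len(b), n_overlap=overlap,
        pct_overlap=100.0 * overlap / min(len(a), len(b)),
    )


_SV_NAMES = {"sv", "structural_variance"}


def property_distribution(molecules, descriptor: str) -> list[float]:
    """One descriptor value per molecule, order preserved.

    ``descriptor`` is any DescriptorSet field name or "sv"."""
    descriptor = descriptor.lower()
    if descriptor in _SV_NAMES:
        return [structural_variance(s).raw for s in molecules]
    from .objectives import DescriptorSet

    valid_names = set(DescriptorSet.__dataclass_fields__)
    if descriptor not in valid_names:
        raise ValueError(
            f"unknown descriptor {descriptor!r}; valid names: "
            f"{sorted(valid_names | _SV_NAMES)}"
        )
    out = []
    for s in molecules:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES in property_distribution input: {s!r}")
        out.append(float(getattr(descriptors_from_mol(mol), descriptor)))
    return out


def fingerprint_matrix(molecules, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Binary circular-fingerprint matrix, one row per input molecule."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mat = np.zeros((len(molecules), n_bits), dtype=np.uint8)
    for i, s in enumerate(molecules):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES in fingerprint input: {s!r}")
        fp = gen.GetFingerprint(mol)
        mat[i, list(fp.GetOnBits())] = 1
    return mat


@dataclass
class DifficultyProfile:
    objective_name: str
    corpus_frequency: float
    sv_values: list[float]

    @property
    def sv_mean(self) -> float:
        return float(np.mean(self.sv_values)) if self.sv_values else float("nan")

    @property
    def sv_median(self) -> float:
        return float(np.median(self.sv_values)) if self.sv_values else float("nan")


def difficulty_profile(corpus: Corpus, objective: Objective) -> DifficultyProfile:
    """Fraction of the corpus satisfying the objective, plus the SV
    distribution over the satisfying molecules.  Zero satisfying molecules
    yields frequency 0 with an empty SV list and a warning."""
    satisfying = []
    for rec in corpus.records:
        if rec.canonical is None:
            continue
        mol = Chem.MolFromSmiles(rec.canonical)
        if mol is not None and objective.predicate(descriptors_from_mol(mol)):
            satisfying.append(rec.raw)
    freq = len(satisfying) / len(corpus)
    if not satisfying:
        warnings.warn(
            f"no corpus molecule satisfies objective {objective.name!r}", stacklevel=2
        )
    return DifficultyProfile(
        objective_name=objective.name,
        corpus_frequency=freq,
        sv_values=[structural_variance(s, corpus.max_length).raw for s in satisfying],
    )
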