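"""SMILES corpus handling: ingest, length filtering, character-level
tokenization, vocabulary construction, and a programmatic fixture-corpus
generator so every experiment in the package can run without any download.

SMILES are treated strictly per character: two-letter element symbols such
as Cl or Br become two tokens.  Three reserved special tokens (pad, start,
end) are added to the alphabet; they are multi-character strings and so can
never collide with a SMILES character.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

PAD_TOKEN = "<pad>"
START_TOKEN = "<s>"
END_TOKEN = "</s>"

#: optional multi-character tokenizer (two-letter elements, bracket atoms)
#: offered behind a flag but OFF by default: the default is per-character.
MULTI_CHAR_PATTERN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|@@|[^ ])"
)


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SmilesRecord:
    raw: str
    canonical: str | None
    length: int


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional token <-> integer map with three reserved specials.

    ``size_k`` is the number of classes k of the softmax / cross-entropy.
    """

    token_to_id: dict[str, int]
    id_to_token: dict[int, str]

    @classmethod
    def from_texts(cls, texts) -> "Vocabulary":
        chars = sorted({ch for text in texts for ch in text})
        tokens = [PAD_TOKEN, START_TOKEN, END_TOKEN] + chars
        t2i = {tok: i for i, tok in enumerate(tokens)}
        return cls(token_to_id=t2i, id_to_token={i: t for t, i in t2i.items()})

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START_TOKEN]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END_TOKEN]

    @property
    def size_k(self) -> int:
        return len(self.token_to_id)

    def to_dict(self) -> dict:
        return {"tokens": [self.id_to_token[i] for i in range(self.size_k)]}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        t2i = {tok: i for i, tok in enumerate(d["tokens"])}
        return cls(token_to_id=t2i, id_to_token={i: t for t, i in t2i.items()})


def tokenize(smiles: str, vocab: Vocabulary) -> list[int]:
    """start_id, one id per character, end_id.

    Raises ValueError naming the offending character and its position if the
    string contains a character outside the vocabulary.
    """
    ids = [vocab.start_id]
    for pos, ch in enumerate(smiles):
        try:
            ids.append(vocab.token_to_id[ch])
        except KeyError:
            raise ValueError(
                f"character {ch!r} at position {pos} is not in the vocabulary"
            ) from None
    ids.append(vocab.end_id)
    return ids


def detokenize(ids, vocab: Vocabulary) -> str:
    """Inverse of tokenize: drop specials, truncate at the first end token."""
    out: list[str] = []
    specials = (vocab.pad_id, vocab.start_id)
    for i in ids:
        i = int(i)
        if i not in vocab.id_to_token:
            raise ValueError(f"token id {i} outside vocabulary range")
        if i == vocab.end_id:
            break
        if i in specials:
            continue
        out.append(vocab.id_to_token[i])
    return "".join(out)


@dataclass
class Corpus:
    """An ordered, length-filtered collection of SMILES records plus the
    vocabulary derived from them."""

    records: list[SmilesRecord]
    vocabulary: Vocabulary
    max_length: int = 100
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def raw_strings(self) -> list[str]:
        return [r.raw for r in self.records]

    def canonical_set(self) -> set[str]:
        return {r.canonical for r in self.records if r.canonical is not None}

    def encoded(self) -> list[np.ndarray]:
        """Token-id sequences (start ... end) for every record."""
        return [np.array(tokenize(r.raw, self.vocabulary)) for r in self.records]

    @classmethod
    def from_smiles(cls, smiles_list, max_length: int = 100) -> "Corpus":
        if max_length < 1:
            raise ValueError("max_length must be >= 1")
        records = []
        dropped = 0
        for raw in smiles_list:
            raw = "".join(raw.split())
            if not raw:
                continue
            if len(raw) > max_length:
                dropped += 1
                continue
            records.append(SmilesRecord(raw=raw, canonical=canonicalize(raw), length=len(raw)))
        if not records:
            raise ValueError("empty corpus: no SMILES survived ingest/length filtering")
        vocab = Vocabulary.from_texts(r.raw for r in records)
        if dropped:
            logger.info("dropped %d molecules longer than %d characters", dropped, max_length)
        return cls(records=records, vocabulary=vocab, max_length=max_length, n_dropped=dropped)

    def manifest(self) -> dict:
        return {
            "n_loaded": len(self.records),
            "n_dropped": self.n_dropped,
            "max_length": self.max_length,
            "vocabulary": self.vocabulary.to_dict()["tokens"],
        }

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def load_corpus(path, max_length: int = 100) -> Corpus:
    """Read a .smi file (one SMILES per line, optional tab-separated id
    ignored), strip all whitespace inside each SMILES, drop records longer
    than ``max_length`` characters, and build the vocabulary from survivors.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    smiles = [line.split("\t")[0] for line in lines if line.strip()]
    try:
        return Corpus.from_smiles(smiles, max_length=max_length)
    except ValueError as exc:
        raise ValueError(f"empty corpus after filtering {path}") from exc


# --------------------------------------------------------------------- #
# Synthetic fixture corpus
# --------------------------------------------------------------------- #
_AROMATIC_RINGS = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1cc[nH]c1"]
_ALIPHATIC_RINGS = ["C1CCCCC1", "C1CCCC1", "C1CCOC1", "C1CCNC1"]
_TAILS = ["", "O", "N", "C(=O)O", "C(=O)OC", "C(=O)N", "C#N"]


def _random_chain(rng: np.random.Generator, min_len: int = 1, max_len: int = 6) -> str:
    """A short acyclic heavy-atom chain; mostly carbon with O/N sprinkled in,
    occasionally a C=C unit or a methyl branch."""
    n = int(rng.integers(min_len, max_len + 1))
    atoms = []
    for _ in range(n):
        u = rng.random()
        atoms.append("C" if u < 0.7 else ("O" if u < 0.85 else "N"))
    chain = "".join(atoms)
    if n >= 2 and rng.random() < 0.25:
        chain = "CC=C" + chain  # double bond between carbons only
    if n >= 3 and rng.random() < 0.3:
        chain = chain[:2] + "(C)" + chain[2:]  # methyl branch
    return chain


def _assemble(rng: np.random.Generator, ring_prob: float) -> str:
    chain = _random_chain(rng)
    tail = _TAILS[rng.integers(0, len(_TAILS))]
    if rng.random() < ring_prob:
        if rng.random() < 0.6:
            ring = _AROMATIC_RINGS[rng.integers(0, len(_AROMATIC_RINGS))]
        else:
            ring = _ALIPHATIC_RINGS[rng.integers(0, len(_ALIPHATIC_RINGS))]
        # substituted ring: chain hangs off the first ring atom
        smi = chain + ring + tail if rng.random() < 0.5 else ring[:-1] + f"({chain}{tail})" + ring[-1]
    else:
        smi = chain + tail
    return smi


def generate_fixture_corpus(
    n: int, seed: int, template_set: str = "simple", max_length: int = 100
) -> Corpus:
    """Deterministically emit ``n`` chemically valid SMILES from parametric
    templates (chains, branches, double bonds, aromatic/aliphatic rings,
    O/N substitution, simple functional-group tails).

    ``template_set="simple"`` mixes acyclic and ring-bearing molecules
    (ring probability 0.45); ``"ring-rich"`` makes every molecule carry at
    least one ring.  Every emitted string parses and sanitizes under RDKit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if template_set not in ("simple", "ring-rich"):
        raise ValueError(f"unknown template_set {template_set!r}")
    ring_prob = 0.45 if template_set == "simple" else 1.0
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        smi = _assemble(rng, ring_prob)
        if len(smi) <= max_length and Chem.MolFromSmiles(smi) is not None:
            out.append(smi)
    return Corpus.from_smiles(out, max_length=max_length)
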