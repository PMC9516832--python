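"""Molecular descriptors, desirability objectives, and structural variance.

The five built-in objectives define progressively harder target chemical
spaces for biassing a SMILES generator:

1. logP <= 3 (one component of the rule of three for oral bioavailability);
2. a structural profile: exactly 2 aromatic and 1 non-aromatic ring, at
   least one of -OH / -COOR / -COOH / -NH2, and an R-value in [0.05, 0.50];
3. the full rule of three: logP <= 3, MW <= 480 g/mol, <= 3 H-bond
   acceptors, <= 3 H-bond donors, <= 3 rotatable bonds;
4. objectives 2 and 3 simultaneously;
5. objective 2 with *all four* functional groups required at once.

All boundary comparisons are inclusive.  Descriptors come from RDKit's
standard implementations (Crippen logP, Lipinski H-bond counts, strict
rotatable-bond count, SSSR ring perception).

Structural variance (SV) of a SMILES string is the number of distinct
characters divided by a global maximum length (default 100, the corpus
length cap), giving a common reference scale across molecules.  A variant
dividing by the molecule's own length is provided for diagnostics only;
it destroys cross-molecule comparability and is not used anywhere else.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

__all__ = [
    "DescriptorSet",
    "Objective",
    "compute_descriptors",
    "objective_1",
    "objective_2",
    "objective_3",
    "objective_4",
    "objective_5",
    "BUILTIN_OBJECTIVES",
    "get_objective",
    "objective_from_yaml",
    "structural_variance",
    "structural_variance_per_length",
]

# Substructure definitions for the four functional groups.  Kept as visible
# module constants so a chemist can amend them.
FG_SMARTS = {
    "hydroxyl": "[OX2H][#6]",
    "ester": "[CX3](=O)[OX2][#6]",
    "carboxylic_acid": "[CX3](=O)[OX2H]",
    "primary_amine": "[NX3;H2]",
}
_FG_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in FG_SMARTS.items()}

#: The R-value of objective 2 is a pluggable descriptor slot.  PLACEHOLDER:
#: the shipped implementation returns rotatable-bond count / heavy-atom
#: count, a cheap flexibility ratio on the right [0, ~0.5] scale.  Replace
#: via ``set_r_value_fn`` if a specific R-value definition is required.
_r_value_fn: Callable[[Chem.Mol], float] | None = None


def set_r_value_fn(fn: Callable[[Chem.Mol], float] | None) -> None:
    global _r_value_fn
    _r_value_fn = fn


def _default_r_value(mol: Chem.Mol) -> float:
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        return 0.0
    return Lipinski.NumRotatableBonds(mol) / heavy


@dataclass(frozen=True)
class DescriptorSet:
    logp: float
    mol_weight: float
    hba: int
    hbd: int
    rot_bonds: int
    aromatic_rings: int
    non_aromatic_rings: int
    fg_hydroxyl: bool
    fg_ester: bool
    fg_carboxylic_acid: bool
    fg_primary_amine: bool
    r_value: float

    @property
    def fg_flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.fg_hydroxyl, self.fg_ester, self.fg_carboxylic_acid, self.fg_primary_amine)


@dataclass(frozen=True)
class Objective:
    """A named, pure predicate over molecular descriptors."""

    name: str
    predicate: Callable[[DescriptorSet], bool]
    description: str = ""

    def __call__(self, descriptors: DescriptorSet) -> bool:
        return bool(self.predicate(descriptors))


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Descriptors for a valid SMILES.  Raises ValueError on parse failure;
    callers evaluating generated output must pre-filter with the validity
    check."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return descriptors_from_mol(mol)


def descriptors_from_mol(mol: Chem.Mol) -> DescriptorSet:
    ring_info = mol.GetRingInfo()
    aromatic = 0
    non_aromatic = 0
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            aromatic += 1
        else:
            non_aromatic += 1
    r_fn = _r_value_fn or _default_r_value
    return DescriptorSet(
        logp=Crippen.MolLogP(mol),
        mol_weight=Descriptors.MolWt(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
        aromatic_rings=aromatic,
        non_aromatic_rings=non_aromatic,
        fg_hydroxyl=mol.HasSubstructMatch(_FG_PATTERNS["hydroxyl"]),
        fg_ester=mol.HasSubstructMatch(_FG_PATTERNS["ester"]),
        fg_carboxylic_acid=mol.HasSubstructMatch(_FG_PATTERNS["carboxylic_acid"]),
        fg_primary_amine=mol.HasSubstructMatch(_FG_PATTERNS["primary_amine"]),
        r_value=r_fn(mol),
    )


# --------------------------------------------------------------------- #
R_BOUNDS_DEFAULT = (0.05, 0.50)


def objective_1(d: DescriptorSet) -> bool:
    return d.logp <= 3.0


def _structural_clauses(d: DescriptorSet, r_bounds, require_r: bool) -> bool:
    if d.aromatic_rings != 2 or d.non_aromatic_rings != 1:
        return False
    if require_r and not (r_bounds[0] <= d.r_value <= r_bounds[1]):
        return False
    return True


def objective_2(d: DescriptorSet, r_bounds=R_BOUNDS_DEFAULT, require_r: bool = True) -> bool:
    return _structural_clauses(d, r_bounds, require_r) and any(d.fg_flags)


def objective_3(d: DescriptorSet) -> bool:
    return (
        d.logp <= 3.0
        and d.mol_weight <= 480.0
        and d.hba <= 3
        and d.hbd <= 3
        and d.rot_bonds <= 3
    )


def objective_4(d: DescriptorSet, r_bounds=R_BOUNDS_DEFAULT, require_r: bool = True) -> bool:
    return objective_2(d, r_bounds, require_r) and objective_3(d)


def objective_5(d: DescriptorSet, r_bounds=R_BOUNDS_DEFAULT, require_r: bool = True) -> bool:
    return _structural_clauses(d, r_bounds, require_r) and all(d.fg_flags)


BUILTIN_OBJECTIVES: dict[str, Objective] = {
    "obj1": Objective("obj1", objective_1, "logP <= 3"),
    "obj2": Objective("obj2", objective_2, "2 aromatic + 1 non-aromatic ring, >=1 of -OH/-COOR/-COOH/-NH2, R-value in [0.05, 0.50]"),
    "obj3": Objective("obj3", objective_3, "full rule of three"),
    "obj4": Objective("obj4", objective_4, "objectives 2 and 3 simultaneously"),
    "obj5": Objective("obj5", objective_5, "objective 2 with all four functional groups required"),
}


def get_objective(name: str) -> Objective:
    try:
        return BUILTIN_OBJECTIVES[name]
    except KeyError:
        raise ValueError(
            f"unknown objective {name!r}; built-ins are {sorted(BUILTIN_OBJECTIVES)}"
        ) from None


_NUMERIC_FIELDS = {
    "logp", "mol_weight", "hba", "hbd", "rot_bonds", "aromatic_rings",
    "non_aromatic_rings", "r_value",
}


def objective_from_config(cfg: dict) -> Objective:
    """Build an Objective from a config mapping.

    Schema::

        name: my_objective
        clauses:
          - {descriptor: logp, max: 3}
          - {descriptor: aromatic_rings, equals: 2}
        functional_groups: any   # or: all, or omitted
        r_bounds: [0.05, 0.50]   # optional
    """
    name = cfg.get("name", "custom")
    clauses = cfg.get("clauses", [])
    fg_mode = cfg.get("functional_groups")
    r_bounds = cfg.get("r_bounds")
    checks: list[Callable[[DescriptorSet], bool]] = []
    for clause in clauses:
        desc = clause.get("descriptor")
        if desc not in _NUMERIC_FIELDS:
            raise ValueError(f"unknown descriptor {desc!r}; valid: {sorted(_NUMERIC_FIELDS)}")
        lo = clause.get("min")
        hi = clause.get("max")
        eq = clause.get("equals")
        def check(d, desc=desc, lo=lo, hi=hi, eq=eq):
            v = getattr(d, desc)
            if eq is not None and v != eq:
                return False
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
            return True
        checks.append(check)
    if fg_mode == "any":
        checks.append(lambda d: any(d.fg_flags))
    elif fg_mode == "all":
        checks.append(lambda d: all(d.fg_flags))
    elif fg_mode is not None:
        raise ValueError("functional_groups must be 'any' or 'all'")
    if r_bounds is not None:
        lo, hi = float(r_bounds[0]), float(r_bounds[1])
        checks.append(lambda d: lo <= d.r_value <= hi)
    return Objective(name, lambda d: all(c(d) for c in checks), cfg.get("description", ""))


def objective_from_yaml(path) -> Objective:
    with open(path) as fh:
        return objective_from_config(yaml.safe_load(fh))


# --------------------------------------------------------------------- #
class StructuralVariance(NamedTuple):
    raw: float
    rounded: float


def _distinct_chars(smiles: str) -> int:
    stripped = "".join(smiles.split())
    if not stripped:
        raise ValueError("structural variance is undefined for an empty SMILES")
    return len(set(stripped))


def structural_variance(smiles: str, global_max_length: int = 100) -> StructuralVariance:
    """Distinct-character count / global maximum length.

    Dividing by a *global* maximum (default 100, the corpus length cap)
    rather than each molecule's own length puts all molecules on a common
    reference scale, so SV values are comparable across molecules.
    """
    if global_max_length < 1:
        raise ValueError("global_max_length must be >= 1")
    raw = _distinct_chars(smiles) / global_max_length
    return StructuralVariance(raw=raw, rounded=round(raw, 2))


def structural_variance_per_length(smiles: str) -> StructuralVariance:
    """Diagnostic variant: distinct-character count / the molecule's own
    length.  NON-CANONICAL — this normalization removes the common reference
    scale and inverts the intended ordering for long diverse molecules; it
    exists only so the two normalizations can be compared."""
    stripped = "".join(smiles.split())
    raw = _distinct_chars(smiles) / len(stripped)
    return StructuralVariance(raw=raw, rounded=round(raw, 2))
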