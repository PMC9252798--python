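"""Structure parsing, standardization, validation, identity keys and descriptors.

Every other module works with :class:`Molecule` records produced here. A
Molecule is an immutable snapshot of a standardized structure: canonical
SMILES, InChI/InChIKey identity, an element-count formula, monoisotopic and
average masses, and a Wildman–Crippen ALogP estimate.

Standardization is deterministic and applied in a fixed order: parse →
sanitize → neutralize charges where a neutral form exists → remove explicit
hydrogens → canonicalize. Input stereochemistry is preserved through
parsing; rule application (see :mod:`biotx.rule_engine`) may drop stereo at
reacting centers only.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements accepted by the input gate: CHNOPS plus the halogens.
ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I"})

#: Default molecular-weight cutoff (average mass, Da) for query molecules.
DEFAULT_MAX_MASS = 1500.0

_CHNOPS_ORDER = ("C", "H", "N", "O", "P", "S")

_uncharger = rdMolStandardize.Uncharger()


class StructureError(ValueError):
    """Raised when an input structure cannot be parsed or standardized."""

    def __init__(self, message: str, code: str = "PARSE_ERROR"):
        super().__init__(message)
        self.code = code


class MultiRecordError(StructureError):
    """Raised when an SDF input contains more than one structure."""

    def __init__(self, message: str):
        super().__init__(message, code="MULTI_RECORD")


class FailureCode(str, enum.Enum):
    """Coded reasons an input molecule fails the submission gate."""

    NON_ORGANIC = "NON_ORGANIC"
    DISALLOWED_ELEMENT = "DISALLOWED_ELEMENT"
    OVERWEIGHT = "OVERWEIGHT"
    MIXTURE = "MIXTURE"
    PARSE_ERROR = "PARSE_ERROR"


@dataclass(frozen=True)
class Molecule:
    """A standardized structure with identity keys and descriptors.

    Attributes
    ----------
    structure:
        Canonical isomeric SMILES of the standardized structure.
    inchi / identity_key:
        InChI string and InChIKey. ``identity_key`` is the deduplication
        key used throughout the metabolic network.
    formula:
        Element → count map including implicit hydrogens.
    monoisotopic_mass / average_mass:
        Masses in Da; monoisotopic uses each element's most abundant isotope.
    alogp:
        Wildman–Crippen atom-contribution log P estimate.
    n_components:
        Number of disconnected fragments (1 for a single connected molecule).
    """

    structure: str
    inchi: str
    identity_key: str
    formula: Mapping[str, int]
    monoisotopic_mass: float
    average_mass: float
    alogp: float
    n_components: int
    _rdmol: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)

    def to_rdkit(self) -> Chem.Mol:
        """Return an RDKit Mol for this molecule (cached from construction)."""
        if self._rdmol is not None:
            return self._rdmol
        return Chem.MolFromSmiles(self.structure)

    @property
    def formula_string(self) -> str:
        return format_formula(self.formula)

    @property
    def heavy_atom_formula(self) -> Mapping[str, int]:
        return {el: n for el, n in self.formula.items() if el != "H"}

    def __hash__(self) -> int:  # identity_key fully determines equality use
        return hash(self.identity_key)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the input gate; ``accepted`` iff ``failures`` is empty."""

    accepted: bool
    failures: tuple[FailureCode, ...]


def _standardize(mol: Chem.Mol) -> Chem.Mol:
    """Fixed standardization order: sanitize → uncharge → remove explicit H."""
    Chem.SanitizeMol(mol)
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)
    return mol


def _count_formula(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def from_rdkit(mol: Chem.Mol) -> Molecule:
    """Build a standardized :class:`Molecule` from an RDKit Mol.

    Raises :class:`StructureError` if sanitization fails.
    """
    try:
        mol = _standardize(Chem.Mol(mol))
    except Exception as exc:  # rdkit raises several sanitization error types
        raise StructureError(f"structure failed standardization: {exc}") from exc
    smiles = Chem.MolToSmiles(mol)
    # Re-parse so descriptors are computed on the canonical form.
    canon = Chem.MolFromSmiles(smiles)
    if canon is None:
        raise StructureError(f"canonical SMILES did not re-parse: {smiles!r}")
    inchi = Chem.MolToInchi(canon, treatWarningAsError=False)
    if not inchi:
        raise StructureError(f"InChI generation failed for {smiles!r}")
    return Molecule(
        structure=smiles,
        inchi=inchi,
        identity_key=Chem.InchiToInchiKey(inchi),
        formula=_count_formula(canon),
        monoisotopic_mass=round(Descriptors.ExactMolWt(canon), 6),
        average_mass=round(Descriptors.MolWt(canon), 4),
        alogp=round(Crippen.MolLogP(canon), 4),
        n_components=len(Chem.GetMolFrags(canon)),
        _rdmol=canon,
    )


def parse_structure(text: str, format: str = "smiles") -> Molecule:
    """Parse one structure from a SMILES string or a single-record SDF block.

    Parameters
    ----------
    text:
        The SMILES string or the full text of an SDF/MOL file.
    format:
        ``"smiles"`` or ``"sdf"``.

    Raises
    ------
    StructureError
        If the input is empty or unparseable (``code == "PARSE_ERROR"``).
    MultiRecordError
        If an SDF block contains more than one structure.
    """
    if not text or not text.strip():
        raise StructureError("empty structure input")
    if format == "smiles":
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise StructureError(f"could not parse SMILES {text!r}")
        return from_rdkit(mol)
    if format == "sdf":
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text, sanitize=False, removeHs=False)
        mols = [m for m in supplier]
        if len(mols) > 1:
            raise MultiRecordError(f"SDF contains {len(mols)} structures; exactly one expected")
        if not mols or mols[0] is None:
            raise StructureError("could not parse SDF structure")
        return from_rdkit(mols[0])
    raise ValueError(f"unknown input format {format!r}")


def validate_input(mol: Molecule, max_mass: float = DEFAULT_MAX_MASS) -> ValidationReport:
    """Apply the submission gate: organic, CHNOPS+halogens only, single
    component, average mass below ``max_mass`` Da.

    Failures are reported, never raised.
    """
    failures: list[FailureCode] = []
    if mol.formula.get("C", 0) < 1:
        failures.append(FailureCode.NON_ORGANIC)
    if set(mol.formula) - ALLOWED_ELEMENTS:
        failures.append(FailureCode.DISALLOWED_ELEMENT)
    if mol.average_mass >= max_mass:
        failures.append(FailureCode.OVERWEIGHT)
    if mol.n_components != 1:
        failures.append(FailureCode.MIXTURE)
    return ValidationReport(accepted=not failures, failures=tuple(failures))


def format_formula(formula: Mapping[str, int]) -> str:
    """Format an element-count map in CHNOPS order, remaining elements
    alphabetically; a count of 1 is omitted (e.g. ``C8H9NO2``)."""
    parts: list[str] = []
    rest = sorted(el for el in formula if el not in _CHNOPS_ORDER)
    for el in (*_CHNOPS_ORDER, *rest):
        n = formula.get(el, 0)
        if n <= 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a plain formula string such as ``C6H10O7`` into a count map."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"bad formula {text!r}")
        pos = match.end()
        el, num = match.group(1), match.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"bad formula {text!r}")
    return counts


def monoisotopic_mass(mol: Molecule) -> float:
    """Major-isotope mass in Da (sum over all atoms incl. implicit H)."""
    return mol.monoisotopic_mass


def compute_alogp(mol: Molecule) -> float:
    """Wildman–Crippen atom-contribution log P; deterministic for a fixed
    contribution table (the one shipped with RDKit)."""
    return mol.alogp
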