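"""Reaction-rule knowledgebase: loading, validation, indexing, linting.

Rules live in a YAML file (one document, a list of rule mappings) with the
schema described in :class:`ReactionRule`. Each rule couples a SMARTS
substrate precondition with a SMIRKS transform, enzyme annotations, a
biosystem and a phase category, plus optional reagent/leaving-group formula
deltas used by the heavy-atom conservation check. The bundled starter set
is a curated subset spanning the major reaction classes; engine correctness
is testable independently of rule-set completeness.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from biotx.chem_core import parse_formula

logger = logging.getLogger(__name__)

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class Phase(str, enum.Enum):
    """The five single transformation modules."""

    PHASE1_CYP = "phase1_cyp"
    PHASE2 = "phase2"
    EC_BASED = "ec_based"
    GUT_MICROBIAL = "gut_microbial"
    ENV_MICROBIAL = "env_microbial"


class Biosystem(str, enum.Enum):
    HUMAN = "human"
    HUMAN_GUT = "human_gut"
    ENVIRONMENT = "environment"


class RulebaseError(ValueError):
    """Schema or pattern error in a rule file; message names the rule_id."""


@dataclass(frozen=True)
class EnzymeDescriptor:
    """An enzyme annotation: a name plus optional EC number / CYP isoform."""

    name: str
    ec: str | None = None
    cyp: str | None = None

    def label(self) -> str:
        if self.cyp:
            return f"CYP{self.cyp}"
        if self.ec:
            return f"{self.name} (EC {self.ec})"
        return self.name


@dataclass(frozen=True)
class ReactionRule:
    """One knowledgebase entry.

    ``substrate_smarts`` gates applicability; ``transform_smirks`` is the
    mapped reaction applied at every matching site. ``reagent_delta`` /
    ``leaving_delta`` are element-count maps declaring what an implicit
    co-substrate contributes (e.g. ``H2O`` for a hydrolysis) and what leaves
    without being reported (e.g. a halide ion); they are used only by the
    conservation check, never by SMIRKS application.
    """

    rule_id: str
    name: str
    substrate_smarts: str
    transform_smirks: str
    enzymes: tuple[EnzymeDescriptor, ...]
    reaction_type: str
    biosystem: Biosystem
    phase: Phase
    priority: int = 100
    citations: tuple[str, ...] = ()
    reagent_delta: Mapping[str, int] = field(default_factory=dict)
    leaving_delta: Mapping[str, int] = field(default_factory=dict)

    def substrate_query(self) -> Chem.Mol:
        return _compile_smarts(self.substrate_smarts)

    def reaction(self) -> AllChem.ChemicalReaction:
        return _compile_smirks(self.transform_smirks)

    @property
    def cyp_isoforms(self) -> tuple[str, ...]:
        return tuple(e.cyp for e in self.enzymes if e.cyp)

    def enzyme_info(self) -> str:
        return "; ".join(e.label() for e in self.enzymes)

    def to_dict(self) -> dict:
        out: dict = {
            "rule_id": self.rule_id,
            "name": self.name,
            "substrate_smarts": self.substrate_smarts,
            "transform_smirks": self.transform_smirks,
            "enzymes": [
                {k: v for k, v in (("name", e.name), ("ec", e.ec), ("cyp", e.cyp)) if v}
                for e in self.enzymes
            ],
            "reaction_type": self.reaction_type,
            "biosystem": self.biosystem.value,
            "phase": self.phase.value,
            "priority": self.priority,
            "citations": list(self.citations),
        }
        if self.reagent_delta:
            out["reagent_delta"] = _format_delta(self.reagent_delta)
        if self.leaving_delta:
            out["leaving_delta"] = _format_delta(self.leaving_delta)
        return out


_smarts_cache: dict[str, Chem.Mol] = {}
_smirks_cache: dict[str, AllChem.ChemicalReaction] = {}


def _compile_smarts(pattern: str) -> Chem.Mol:
    query = _smarts_cache.get(pattern)
    if query is None:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise RulebaseError(f"unparseable SMARTS: {pattern!r}")
        _smarts_cache[pattern] = query
    return query


def _compile_smirks(smirks: str) -> AllChem.ChemicalReaction:
    rxn = _smirks_cache.get(smirks)
    if rxn is None:
        try:
            rxn = AllChem.ReactionFromSmarts(smirks)
        except Exception as exc:
            raise RulebaseError(f"unparseable SMIRKS: {smirks!r}: {exc}") from exc
        if rxn is None:
            raise RulebaseError(f"unparseable SMIRKS: {smirks!r}")
        rxn.Initialize()
        _smirks_cache[smirks] = rxn
    return rxn


def _format_delta(delta: Mapping[str, int]) -> str:
    order = ("C", "H", "N", "O", "P", "S")
    rest = sorted(el for el in delta if el not in order)
    parts = []
    for el in (*order, *rest):
        n = delta.get(el, 0)
        if n:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def _atom_maps(rxn: AllChem.ChemicalReaction) -> tuple[set[int], set[int]]:
    reactant_maps: set[int] = set()
    product_maps: set[int] = set()
    for i in range(rxn.GetNumReactantTemplates()):
        for atom in rxn.GetReactantTemplate(i).GetAtoms():
            if atom.GetAtomMapNum():
                reactant_maps.add(atom.GetAtomMapNum())
    for i in range(rxn.GetNumProductTemplates()):
        for atom in rxn.GetProductTemplate(i).GetAtoms():
            if atom.GetAtomMapNum():
                product_maps.add(atom.GetAtomMapNum())
    return reactant_maps, product_maps


def lint_rule(rule: ReactionRule) -> list[str]:
    """Static checks on one rule; returns human-readable issue strings.

    Flags unparseable patterns, product-side atom maps absent from the
    reactant side, and substrate SMARTS that can never co-match the SMIRKS
    reactant template (gate and transform disagree).
    """
    issues: list[str] = []
    try:
        query = rule.substrate_query()
    except RulebaseError as exc:
        return [str(exc)]
    try:
        rxn = rule.reaction()
    except RulebaseError as exc:
        return [str(exc)]
    reactant_maps, product_maps = _atom_maps(rxn)
    orphan = product_maps - reactant_maps
    if orphan:
        issues.append(f"unmapped product atom map(s) {sorted(orphan)} in {rule.rule_id}")
    if rxn.GetNumReactantTemplates() != 1:
        issues.append(f"{rule.rule_id}: expected exactly one reactant template")
    # The gate must imply the transform can fire: every probe the SMARTS
    # matches must also match the SMIRKS reactant template.
    template = rxn.GetReactantTemplate(0)
    probes = _lint_probes()
    for probe in probes:
        if probe.HasSubstructMatch(query) and not probe.HasSubstructMatch(template):
            issues.append(
                f"{rule.rule_id}: substrate_smarts matches a probe the SMIRKS "
                f"reactant template does not ({Chem.MolToSmiles(probe)})"
            )
            break
    return issues


_LINT_PROBE_SMILES = (
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "COc1ccccc1",
    "CC(=O)Nc1ccc(O)cc1", "CCOC(C)=O", "CCO", "CC(C)O", "CC=O",
    "OC(=O)c1ccccc1", "CN(C)c1ccccc1", "CSc1ccccc1", "C=Cc1ccccc1",
    "C1OC1c1ccccc1", "O=[N+]([O-])c1ccccc1", "c1ccc(N=Nc2ccccc2)cc1",
    "Clc1ccccc1", "ClCCc1ccccc1", "N#Cc1ccccc1", "Oc1ccccc1O",
    "OCC1OC(O)C(O)C(O)C1O", "NCC(=O)O", "CC(N)C(=O)O",
    "Oc1ccc(OS(=O)(=O)O)cc1", "Oc1ccc(OC2OC(C(=O)O)C(O)C(O)C2O)cc1",
    "O=C(O)/C=C/c1ccccc1", "OCC1OC(O)C(O)C(O)C1OP(=O)(O)O",
)
_lint_probe_cache: list[Chem.Mol] | None = None


def _lint_probes() -> list[Chem.Mol]:
    global _lint_probe_cache
    if _lint_probe_cache is None:
        _lint_probe_cache = [Chem.MolFromSmiles(s) for s in _LINT_PROBE_SMILES]
    return _lint_probe_cache


class Rulebase:
    """An indexed, validated collection of reaction rules."""

    def __init__(self, rules: Iterable[ReactionRule]):
        self.rules: tuple[ReactionRule, ...] = tuple(rules)
        seen: set[str] = set()
        for rule in self.rules:
            if rule.rule_id in seen:
                raise RulebaseError(f"duplicate rule_id {rule.rule_id!r}")
            seen.add(rule.rule_id)
        self._by_phase: dict[Phase, list[ReactionRule]] = {p: [] for p in Phase}
        self._by_biosystem: dict[Biosystem, list[ReactionRule]] = {b: [] for b in Biosystem}
        self._by_enzyme: dict[str, list[ReactionRule]] = {}
        for rule in self.rules:
            self._by_phase[rule.phase].append(rule)
            self._by_biosystem[rule.biosystem].append(rule)
            for enzyme in rule.enzymes:
                self._by_enzyme.setdefault(enzyme.label(), []).append(rule)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def by_phase(self, phase: Phase) -> list[ReactionRule]:
        return list(self._by_phase[phase])

    def by_biosystem(self, biosystem: Biosystem) -> list[ReactionRule]:
        return list(self._by_biosystem[biosystem])

    def by_enzyme(self, label: str) -> list[ReactionRule]:
        return list(self._by_enzyme.get(label, []))

    def get(self, rule_id: str) -> ReactionRule:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(rule_id)

    def scoped(self, phases: Iterable[Phase]) -> list[ReactionRule]:
        wanted = set(phases)
        return [r for r in self.rules if r.phase in wanted]

    def save(self, path: str | Path) -> None:
        """Serialize back to the YAML rule schema (lossless round-trip)."""
        payload = [rule.to_dict() for rule in self.rules]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _parse_delta(value) -> dict[str, int]:
    if value is None or value == "":
        return {}
    if isinstance(value, Mapping):
        return {str(k): int(v) for k, v in value.items()}
    return parse_formula(str(value))


def _parse_rule(entry: Mapping, index: int) -> ReactionRule:
    rule_id = entry.get("rule_id")
    if not rule_id:
        raise RulebaseError(f"rule #{index}: missing rule_id")
    try:
        enzymes = tuple(
            EnzymeDescriptor(name=e["name"], ec=e.get("ec"), cyp=str(e["cyp"]) if e.get("cyp") else None)
            for e in entry.get("enzymes", [])
        )
        rule = ReactionRule(
            rule_id=str(rule_id),
            name=str(entry["name"]),
            substrate_smarts=str(entry["substrate_smarts"]),
            transform_smirks=str(entry["transform_smirks"]),
            enzymes=enzymes,
            reaction_type=str(entry["reaction_type"]),
            biosystem=Biosystem(entry["biosystem"]),
            phase=Phase(entry["phase"]),
            priority=int(entry.get("priority", 100)),
            citations=tuple(entry.get("citations", ())),
            reagent_delta=_parse_delta(entry.get("reagent_delta")),
            leaving_delta=_parse_delta(entry.get("leaving_delta")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise RulebaseError(f"rule {rule_id!r}: invalid schema: {exc}") from exc
    # compile eagerly so a bad pattern fails at load with rule context
    try:
        rule.substrate_query()
        rxn = rule.reaction()
    except RulebaseError as exc:
        raise RulebaseError(f"rule {rule_id!r}: {exc}") from exc
    reactant_maps, product_maps = _atom_maps(rxn)
    if product_maps - reactant_maps:
        raise RulebaseError(
            f"rule {rule_id!r}: product-side atom maps "
            f"{sorted(product_maps - reactant_maps)} missing on reactant side"
        )
    return rule


def load_rulebase(path: str | Path) -> Rulebase:
    """Load and validate a YAML rule file into an indexed :class:`Rulebase`.

    Raises :class:`RulebaseError` (naming the offending rule) on schema or
    pattern errors; an empty file yields an empty rulebase with a warning.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not raw:
        logger.warning("rule file %s is empty", path)
        return Rulebase(())
    if not isinstance(raw, list):
        raise RulebaseError("rule file must contain a list of rule mappings")
    return Rulebase(_parse_rule(entry, i) for i, entry in enumerate(raw))


def load_default_rulebase() -> Rulebase:
    """Load the bundled curated starter rule set."""
    with resources.as_file(resources.files("biotx.data") / "rules.yaml") as p:
        return load_rulebase(p)


def deduplicate_rules(rules: Sequence[ReactionRule]) -> list[ReactionRule]:
    """Drop duplicate biotransformations.

    Two rules are duplicates when they share (normalized SMIRKS, enzyme
    label set, biosystem); the first by (priority, rule_id) is kept.
    Output preserves the retained rules' original relative order.
    """

    def normalize(smirks: str) -> str:
        return re.sub(r"\s+", "", smirks)

    def key(rule: ReactionRule):
        return (
            normalize(rule.transform_smirks),
            frozenset(e.label() for e in rule.enzymes),
            rule.biosystem,
        )

    winners: dict = {}
    for rule in rules:
        k = key(rule)
        if k not in winners or (rule.priority, rule.rule_id) < (
            winners[k].priority,
            winners[k].rule_id,
        ):
            winners[k] = rule
    chosen = set(id(r) for r in winners.values())
    return [r for r in rules if id(r) in chosen]


@dataclass(frozen=True)
class EndogenousReactionEntry:
    """One row of the endogenous-metabolite reaction lookup table."""

    substrate_key: str
    products: tuple[str, ...]  # canonical SMILES
    reaction_name: str
    enzymes: tuple[EnzymeDescriptor, ...]


def load_endogenous_table(path: str | Path) -> list[EndogenousReactionEntry]:
    """Load the TSV endogenous reaction table.

    Columns: substrate_inchikey, product_smiles (semicolon-separated),
    reaction_name, enzymes (semicolon-separated names). Product SMILES are
    validated at load; a bad row raises :class:`RulebaseError`.
    """
    entries: list[EndogenousReactionEntry] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#") or line.startswith("substrate_inchikey"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise RulebaseError(f"endogenous table line {lineno}: expected 4 columns")
        key, product_field, reaction_name, enzyme_field = fields
        if not _INCHIKEY_RE.match(key):
            raise RulebaseError(f"endogenous table line {lineno}: malformed InChIKey {key!r}")
        products = tuple(s.strip() for s in product_field.split(";") if s.strip())
        for smi in products:
            if Chem.MolFromSmiles(smi) is None:
                raise RulebaseError(
                    f"endogenous table line {lineno}: unparseable product SMILES {smi!r}"
                )
        enzymes = tuple(
            EnzymeDescriptor(name=n.strip()) for n in enzyme_field.split(";") if n.strip()
        )
        entries.append(
            EndogenousReactionEntry(
                substrate_key=key,
                products=products,
                reaction_name=reaction_name,
                enzymes=enzymes,
            )
        )
    return entries


def load_default_endogenous_table() -> list[EndogenousReactionEntry]:
    """Load the bundled endogenous-reaction fixture table."""
    with resources.as_file(resources.files("biotx.data") / "endogenous.tsv") as p:
        return load_endogenous_table(p)
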