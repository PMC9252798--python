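"""The five single transformation modules and the endogenous-metabolite pass.

Phase I (CYP450) metabolism is gated per isoform: a rule annotated with a
CYP isoform fires on a molecule only if that molecule is a substrate of the
isoform under the rule-based structural predicate (`is_cyp_substrate`).
The other four modules (phase II, EC-based, gut microbial, environmental
microbial) are plain scoped passes. The endogenous pass is a pure lookup
against a reaction table keyed by InChIKey, independent of the rulebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from biotx.chem_core import Molecule
from biotx.rule_engine import Biotransformation, apply_rule, applicable_rules, transform_once
from biotx.rulebase import (
    Biosystem,
    EndogenousReactionEntry,
    Phase,
    Rulebase,
)
from biotx.chem_core import parse_structure

#: The nine major human cytochrome P450 isoforms.
CYP_ISOFORMS: tuple[str, ...] = ("1A2", "2A6", "2B6", "2C8", "2C9", "2C19", "2D6", "2E1", "3A4")


@dataclass(frozen=True)
class ModuleConfig:
    """Configuration for one transformation module run.

    ``cyp_isoforms`` applies to phase I only and must list exactly the nine
    major isoforms; ``cyp_mode`` accepts only ``"rule_based"``: modes backed
    by trained substrate/product models are not part of this engine and are
    rejected with a clear message.
    """

    phase: Phase
    cyp_isoforms: tuple[str, ...] = CYP_ISOFORMS
    cyp_mode: str = "rule_based"

    def __post_init__(self):
        if self.cyp_mode != "rule_based":
            raise ValueError(
                f"cyp_mode {self.cyp_mode!r} is not supported; only 'rule_based' "
                "prediction is available in this engine"
            )
        unknown = set(self.cyp_isoforms) - set(CYP_ISOFORMS)
        if unknown:
            raise ValueError(f"unknown CYP isoform label(s): {sorted(unknown)}")
        if self.phase is Phase.PHASE1_CYP and len(set(self.cyp_isoforms)) != len(CYP_ISOFORMS):
            raise ValueError("phase I config must list exactly the nine CYP isoforms")


def is_cyp_substrate(mol: Molecule, isoform: str, rulebase: Rulebase) -> bool:
    """Rule-based substrate gate: true iff any phase I rule annotated with
    ``isoform`` matches ``mol``.

    Raises ``ValueError`` for an isoform label outside the nine-label set.
    """
    if isoform not in CYP_ISOFORMS:
        raise ValueError(f"unknown CYP isoform label {isoform!r}")
    target = mol.to_rdkit()
    for rule in rulebase.by_phase(Phase.PHASE1_CYP):
        if isoform in rule.cyp_isoforms and target.HasSubstructMatch(rule.substrate_query()):
            return True
    return False


def run_module(
    mols: Sequence[Molecule],
    config: ModuleConfig,
    rulebase: Rulebase,
    iteration: int = 1,
    step_index: int = 1,
) -> list[Biotransformation]:
    """One pass of the configured module over ``mols``.

    For phase I, a rule fires only when at least one of its annotated
    isoforms both belongs to ``config.cyp_isoforms`` and gates true for the
    precursor; other phases delegate to :func:`transform_once`.
    """
    if config.phase is not Phase.PHASE1_CYP:
        return transform_once(mols, config.phase, rulebase, iteration, step_index)
    out: list[Biotransformation] = []
    seen: set[tuple] = set()
    allowed = set(config.cyp_isoforms)
    for mol in mols:
        open_gates = {
            iso for iso in CYP_ISOFORMS if iso in allowed and is_cyp_substrate(mol, iso, rulebase)
        }
        for rule in applicable_rules(mol, rulebase, (Phase.PHASE1_CYP,)):
            if not (set(rule.cyp_isoforms) & open_gates):
                continue
            for bt in apply_rule(mol, rule, iteration=iteration, step_index=step_index):
                k = bt.dedup_key()
                if k not in seen:
                    seen.add(k)
                    out.append(bt)
    return out


def endogenous_pass(
    mol: Molecule,
    table: Sequence[EndogenousReactionEntry],
    iteration: int = 1,
    step_index: int = 1,
) -> list[Biotransformation]:
    """Exact-match lookup of ``mol`` in the endogenous reaction table.

    If the molecule's identity key matches a substrate entry, one
    biotransformation is emitted per table reaction, annotated from the
    table; otherwise the result is empty. Pure lookup — the rulebase plays
    no part.
    """
    out: list[Biotransformation] = []
    for entry in table:
        if entry.substrate_key != mol.identity_key:
            continue
        products = tuple(parse_structure(smi) for smi in entry.products)
        # drop identity-duplicate products defensively (table is validated at load)
        unique: list[Molecule] = []
        seen: set[str] = set()
        for p in products:
            if p.identity_key not in seen:
                seen.add(p.identity_key)
                unique.append(p)
        out.append(
            Biotransformation(
                precursor=mol,
                products=tuple(unique),
                rule_id=f"endogenous:{entry.reaction_name}",
                enzymes=entry.enzymes,
                reaction_type=entry.reaction_name,
                biosystem=Biosystem.HUMAN,
                iteration=iteration,
                step_index=step_index,
            )
        )
    return out
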