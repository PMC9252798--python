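"""Application of one reaction rule to one molecule.

``apply_rule`` enumerates every symmetry-distinct reaction site, sanitizes
and canonicalizes the products, and merges sites that yield identical
product sets (by InChIKey). Small co-products — formaldehyde from a
dealkylation, CO2 from a decarboxylation, the acetate half of an ester —
are retained in the product list after the main product, never discarded.
Unsanitizable products are skipped with a warning; a bad site never aborts
the whole prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem

from biotx.chem_core import Molecule, StructureError, from_rdkit
from biotx.rulebase import Biosystem, Phase, ReactionRule, Rulebase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Biotransformation:
    """One applied reaction: precursor → products under a specific rule.

    ``products`` holds the main product first, co-products after it; no two
    products share an identity key. ``iteration`` and ``step_index`` locate
    the edge in the metabolic network (both 1-based).
    """

    precursor: Molecule
    products: tuple[Molecule, ...]
    rule_id: str
    enzymes: tuple
    reaction_type: str
    biosystem: Biosystem
    iteration: int = 1
    step_index: int = 1

    def __post_init__(self):
        if not self.products:
            raise ValueError("a biotransformation must have at least one product")
        keys = [p.identity_key for p in self.products]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate product identity keys in one biotransformation")
        if self.iteration < 1 or self.step_index < 1:
            raise ValueError("iteration and step_index must be positive")

    @property
    def product_keys(self) -> frozenset:
        return frozenset(p.identity_key for p in self.products)

    def dedup_key(self) -> tuple:
        return (self.precursor.identity_key, self.rule_id, tuple(sorted(self.product_keys)))


def applicable_rules(
    mol: Molecule, rulebase: Rulebase, scope: Iterable[Phase]
) -> list[ReactionRule]:
    """The in-scope rules whose substrate SMARTS matches ``mol`` at least
    once, ordered by (priority, rule_id)."""
    target = mol.to_rdkit()
    hits = [
        rule
        for rule in rulebase.scoped(scope)
        if target.HasSubstructMatch(rule.substrate_query())
    ]
    hits.sort(key=lambda r: (r.priority, r.rule_id))
    return hits


def _product_molecules(product_set) -> list[Molecule] | None:
    """Standardize one RunReactants product set; None if any product is
    unsanitizable. Disconnected products are split into fragments."""
    mols: list[Molecule] = []
    for product in product_set:
        try:
            frags = Chem.GetMolFrags(product, asMols=True, sanitizeFrags=False)
        except Exception:
            return None
        for frag in frags:
            try:
                mols.append(from_rdkit(frag))
            except StructureError:
                return None
    if not mols:
        return None
    # main product first: most heavy atoms, ties broken by canonical SMILES
    mols.sort(key=lambda m: (-sum(m.heavy_atom_formula.values()), m.structure))
    deduped: list[Molecule] = []
    seen: set[str] = set()
    for m in mols:
        if m.identity_key not in seen:
            seen.add(m.identity_key)
            deduped.append(m)
    return deduped


def apply_rule(
    mol: Molecule,
    rule: ReactionRule,
    iteration: int = 1,
    step_index: int = 1,
) -> list[Biotransformation]:
    """Apply ``rule`` at every matching site of ``mol``.

    Returns one :class:`Biotransformation` per symmetry-distinct site;
    sites yielding the same product set are merged. Output order is
    deterministic (sorted by product identity keys).
    """
    rxn = rule.reaction()
    target = mol.to_rdkit()
    results: dict[tuple, Biotransformation] = {}
    for product_set in rxn.RunReactants((target,)):
        products = _product_molecules(product_set)
        if products is None:
            logger.warning(
                "rule %s produced an unsanitizable structure on %s; site skipped",
                rule.rule_id,
                mol.structure,
            )
            continue
        key = tuple(sorted(p.identity_key for p in products))
        if key in results:
            continue
        results[key] = Biotransformation(
            precursor=mol,
            products=tuple(products),
            rule_id=rule.rule_id,
            enzymes=rule.enzymes,
            reaction_type=rule.reaction_type,
            biosystem=rule.biosystem,
            iteration=iteration,
            step_index=step_index,
        )
    return [results[k] for k in sorted(results)]


def transform_once(
    mols: Sequence[Molecule],
    module: Phase,
    rulebase: Rulebase,
    iteration: int = 1,
    step_index: int = 1,
) -> list[Biotransformation]:
    """One pass of a single transformation module over ``mols``.

    The union of ``apply_rule`` across each molecule's applicable in-scope
    rules, globally deduplicated on (precursor key, rule, product key set).
    Rules never fire on products created within the same pass; chaining
    happens only across iterations.
    """
    out: list[Biotransformation] = []
    seen: set[tuple] = set()
    for mol in mols:
        for rule in applicable_rules(mol, rulebase, (module,)):
            for bt in apply_rule(mol, rule, iteration=iteration, step_index=step_index):
                k = bt.dedup_key()
                if k not in seen:
                    seen.add(k)
                    out.append(bt)
    return out


def conservation_ok(bt: Biotransformation, rule: ReactionRule) -> bool:
    """Heavy-atom bookkeeping: precursor + declared reagent equals products
    + declared leaving group, ignoring hydrogens.

    Because structurally identical products are merged (a symmetric
    cleavage such as azo reduction yields one reported aniline, not two),
    each product may be counted with multiplicity 1 or 2 when balancing.
    """
    import itertools

    lhs: dict[str, int] = dict(bt.precursor.heavy_atom_formula)
    for el, n in rule.reagent_delta.items():
        if el != "H":
            lhs[el] = lhs.get(el, 0) + n
    lhs = {k: v for k, v in lhs.items() if v}
    base: dict[str, int] = {k: v for k, v in rule.leaving_delta.items() if k != "H"}
    formulas = [p.heavy_atom_formula for p in bt.products]
    for multiplicities in itertools.product((1, 2), repeat=len(formulas)):
        rhs = dict(base)
        for mult, formula in zip(multiplicities, formulas):
            for el, n in formula.items():
                rhs[el] = rhs.get(el, 0) + mult * n
        if lhs == {k: v for k, v in rhs.items() if v}:
            return True
    return False
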