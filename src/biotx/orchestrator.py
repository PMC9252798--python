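"""Iteration semantics, combination modes, explosion guards, depolymerization.

The orchestrator grows a :class:`MetabolismGraph` from a query molecule.
Each iteration applies the selected module(s) to the *frontier* — the
metabolites first seen in the previous iteration — and admits novel
products by InChIKey. Three combination modes are provided:

* AllHuman — each iteration is the deduplicated union of the phase I,
  phase II, EC-based and gut-microbial passes, plus the endogenous lookup
  when enabled.
* SuperBio — AllHuman run through four iterations or until no novel
  metabolite appears, whichever comes first.
* MultiBio — an ordered custom plan of up to four (module, iterations)
  steps with up to three iterations each; step k starts from everything
  step k-1 produced.

Two safety valves bound network growth: a global node cap (default 1000)
and a per-precursor product cap (default 64). A plausibility guard can
additionally abort any reaction whose main product falls outside
descriptor envelopes derived from reference urinary (renal/hepatic) or
fecal (gut) metabolite descriptor tables.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from biotx.chem_core import Molecule, from_rdkit
from biotx.rule_engine import Biotransformation
from biotx.rulebase import Biosystem, EndogenousReactionEntry, Phase, Rulebase
from biotx.transformers import ModuleConfig, endogenous_pass, run_module

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 3          # per-module / per-step web maximum
SUPERBIO_ITERATIONS = 4     # fixed AllHuman iteration count for SuperBio
MAX_SEQUENCE_STEPS = 4      # MultiBio plan length limit
DEFAULT_NODE_CAP = 1000
DEFAULT_PRODUCT_CAP = 64

#: modules combined by AllHuman / SuperBio
ALLHUMAN_PHASES = (Phase.PHASE1_CYP, Phase.PHASE2, Phase.EC_BASED, Phase.GUT_MICROBIAL)


class ConfigurationError(ValueError):
    """Invalid run configuration (iteration count, sequence shape, ...)."""


@dataclass(frozen=True)
class TransformationSequence:
    """An ordered MultiBio plan of (module, iterations) steps."""

    steps: tuple[tuple[Phase, int], ...]

    def __post_init__(self):
        if not 1 <= len(self.steps) <= MAX_SEQUENCE_STEPS:
            raise ConfigurationError(
                f"a sequence must have 1..{MAX_SEQUENCE_STEPS} steps, got {len(self.steps)}"
            )
        for phase, n in self.steps:
            if not isinstance(phase, Phase):
                raise ConfigurationError(f"step module must be a Phase, got {phase!r}")
            if n not in (1, 2, 3):
                raise ConfigurationError(
                    f"per-step iterations must be 1..{MAX_ITERATIONS}, got {n}"
                )
        total = sum(n for _, n in self.steps)
        if total > 4:
            logger.warning(
                "sequence requests %d total passes (>4); allowed, but large networks may result",
                total,
            )


class GuardDecision(str, enum.Enum):
    KEEP = "keep"
    ABORT = "abort"


_GUARD_DESCRIPTORS = ("average_mass", "alogp", "heteroatom_count", "ring_count")

_COMPARTMENT_FOR_BIOSYSTEM = {
    Biosystem.HUMAN: "renal_hepatic",
    Biosystem.HUMAN_GUT: "gut_fecal",
    # environmental products are not screened against human compartments
    Biosystem.ENVIRONMENT: None,
}


def guard_descriptors(mol: Molecule) -> dict[str, float]:
    """The four physico-chemical descriptors the plausibility guard screens."""
    rd = mol.to_rdkit()
    hetero = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return {
        "average_mass": mol.average_mass,
        "alogp": mol.alogp,
        "heteroatom_count": float(hetero),
        "ring_count": float(rd.GetRingInfo().NumRings()),
    }


@dataclass(frozen=True)
class GuardProfile:
    """Per-descriptor [min, max] envelopes for each excretion compartment.

    Envelopes are the [p1, p99] percentile bands of a reference descriptor
    table (one row per known metabolite, labelled by compartment). They are
    shipped as data so users can re-derive or swap them.
    """

    envelopes: dict  # compartment -> {descriptor: (lo, hi)}

    def __post_init__(self):
        for compartment, bands in self.envelopes.items():
            for descriptor, (lo, hi) in bands.items():
                if lo > hi:
                    raise ValueError(
                        f"envelope min>max for {compartment}/{descriptor}: {lo} > {hi}"
                    )

    @classmethod
    def from_reference_table(cls, path: str | Path) -> "GuardProfile":
        """Build envelopes from a CSV with columns
        compartment,smiles,average_mass,alogp,heteroatom_count,ring_count."""
        values: dict[str, dict[str, list[float]]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                comp = values.setdefault(row["compartment"], {d: [] for d in _GUARD_DESCRIPTORS})
                for d in _GUARD_DESCRIPTORS:
                    comp[d].append(float(row[d]))
        envelopes = {
            compartment: {
                d: (float(np.percentile(v, 1)), float(np.percentile(v, 99)))
                for d, v in bands.items()
            }
            for compartment, bands in values.items()
        }
        return cls(envelopes=envelopes)

    @classmethod
    def default(cls) -> "GuardProfile":
        """Envelopes from the bundled synthetic reference descriptor table."""
        with resources.as_file(
            resources.files("biotx.data") / "guard_reference_synthetic.csv"
        ) as p:
            return cls.from_reference_table(p)


def plausibility_guard(
    candidate: Molecule,
    precursor: Molecule,
    biosystem: Biosystem,
    guard: GuardProfile,
) -> GuardDecision:
    """Keep the candidate iff every screened descriptor lies inside the
    envelope of the biosystem-appropriate compartment.

    Environmental products have no human compartment and are always kept.
    On abort the caller drops the whole edge; the precursor remains a
    terminal node of the network.
    """
    compartment = _COMPARTMENT_FOR_BIOSYSTEM[biosystem]
    if compartment is None or compartment not in guard.envelopes:
        return GuardDecision.KEEP
    bands = guard.envelopes[compartment]
    values = guard_descriptors(candidate)
    for descriptor, (lo, hi) in bands.items():
        v = values[descriptor]
        if not (lo <= v <= hi):
            return GuardDecision.ABORT
    return GuardDecision.KEEP


@dataclass
class GraphNode:
    molecule: Molecule
    first_iteration: int  # 0 for the root
    first_step: int


@dataclass
class MetabolismGraph:
    """The predicted metabolic network.

    One node per identity key (global dedup); edges are biotransformations
    whose iteration strictly exceeds the precursor's first-seen iteration.
    ``truncated`` is set when a safety cap stopped expansion early.
    """

    root: str
    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: list[Biotransformation] = field(default_factory=list)
    truncated: bool = False

    @classmethod
    def rooted_at(cls, mol: Molecule) -> "MetabolismGraph":
        g = cls(root=mol.identity_key)
        g.nodes[mol.identity_key] = GraphNode(molecule=mol, first_iteration=0, first_step=0)
        return g

    @property
    def metabolite_keys(self) -> set[str]:
        return set(self.nodes) - {self.root}

    def __len__(self) -> int:
        return len(self.nodes)

    def to_networkx(self):
        """Export as a networkx MultiDiGraph (one arc per edge product)."""
        import networkx as nx

        g = nx.MultiDiGraph(root=self.root)
        for key, node in self.nodes.items():
            g.add_node(key, smiles=node.molecule.structure, iteration=node.first_iteration)
        for bt in self.edges:
            for product in bt.products:
                g.add_edge(
                    bt.precursor.identity_key,
                    product.identity_key,
                    rule_id=bt.rule_id,
                    reaction_type=bt.reaction_type,
                    iteration=bt.iteration,
                    step_index=bt.step_index,
                )
        return g


def _produce(
    frontier: Sequence[Molecule],
    config: ModuleConfig,
    rulebase: Rulebase,
    iteration: int,
    step_index: int,
    endogenous_table: Sequence[EndogenousReactionEntry] | None,
) -> list[Biotransformation]:
    bts = run_module(frontier, config, rulebase, iteration=iteration, step_index=step_index)
    if endogenous_table:
        seen = {bt.dedup_key() for bt in bts}
        for mol in frontier:
            for bt in endogenous_pass(mol, endogenous_table, iteration, step_index):
                if bt.dedup_key() not in seen:
                    seen.add(bt.dedup_key())
                    bts.append(bt)
    return bts


def _expand_one_iteration(
    graph: MetabolismGraph,
    frontier: list[Molecule],
    bts: list[Biotransformation],
    guard: GuardProfile | None,
    node_cap: int,
    product_cap: int,
) -> list[Molecule]:
    """Admit a batch of biotransformations into the graph; returns the new
    frontier (novel metabolites, deterministic order)."""
    new_frontier: list[Molecule] = []
    per_precursor: dict[str, int] = {}
    for bt in sorted(bts, key=lambda b: (b.precursor.identity_key, b.rule_id, tuple(sorted(b.product_keys)))):
        if guard is not None:
            main = bt.products[0]
            if plausibility_guard(main, bt.precursor, bt.biosystem, guard) is GuardDecision.ABORT:
                logger.info(
                    "guard aborted %s on %s (product %s outside envelope)",
                    bt.rule_id,
                    bt.precursor.structure,
                    main.structure,
                )
                continue
        count = per_precursor.get(bt.precursor.identity_key, 0)
        if count + len(bt.products) > product_cap:
            logger.warning(
                "per-precursor product cap (%d) hit for %s; further products dropped",
                product_cap,
                bt.precursor.structure,
            )
            graph.truncated = True
            continue
        per_precursor[bt.precursor.identity_key] = count + len(bt.products)
        if len(graph.nodes) >= node_cap:
            logger.warning("node cap (%d) reached; expansion stopped", node_cap)
            graph.truncated = True
            break
        graph.edges.append(bt)
        for product in bt.products:
            if product.identity_key not in graph.nodes:
                graph.nodes[product.identity_key] = GraphNode(
                    molecule=product,
                    first_iteration=bt.iteration,
                    first_step=bt.step_index,
                )
                new_frontier.append(product)
    return new_frontier


def _run(
    graph: MetabolismGraph,
    frontier: list[Molecule],
    configs: Sequence[ModuleConfig],
    n: int,
    rulebase: Rulebase,
    guard: GuardProfile | None,
    endogenous_table,
    step_index: int,
    iteration_offset: int,
    node_cap: int,
    product_cap: int,
) -> list[Molecule]:
    """Iterate the given module set n times from ``frontier``; returns the
    final frontier."""
    for i in range(1, n + 1):
        if not frontier or graph.truncated:
            break
        iteration = iteration_offset + i
        bts: list[Biotransformation] = []
        seen: set[tuple] = set()
        for config in configs:
            table = endogenous_table if config.phase in (Phase.EC_BASED,) else None
            for bt in _produce(frontier, config, rulebase, iteration, step_index, table):
                if bt.dedup_key() not in seen:
                    seen.add(bt.dedup_key())
                    bts.append(bt)
        frontier = _expand_one_iteration(graph, frontier, bts, guard, node_cap, product_cap)
    return frontier


def run_iterations(
    mol: Molecule,
    config: ModuleConfig,
    n: int,
    rulebase: Rulebase,
    guard: GuardProfile | None = None,
    endogenous_table: Sequence[EndogenousReactionEntry] | None = None,
    node_cap: int = DEFAULT_NODE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
    depolymerize_query: bool = True,
) -> MetabolismGraph:
    """Run one module for ``n`` iterations (1..3) from a query molecule.

    Iteration i transforms the frontier (metabolites first seen at i-1);
    the run stops early when the frontier empties.
    """
    if n not in (1, 2, 3):
        raise ConfigurationError(f"iterations must be 1..{MAX_ITERATIONS}, got {n}")
    graph, frontier = _rooted_frontier(mol, depolymerize_query)
    _run(graph, frontier, (config,), n, rulebase, guard, endogenous_table, 1, 0, node_cap, product_cap)
    return graph


def _rooted_frontier(mol: Molecule, depolymerize_query: bool):
    """Root the graph at the query; the starting frontier is the query's
    depolymerization fragments (or the query itself)."""
    graph = MetabolismGraph.rooted_at(mol)
    if not depolymerize_query:
        return graph, [mol]
    fragments = depolymerize(mol)
    if len(fragments) == 1 and fragments[0].identity_key == mol.identity_key:
        return graph, [mol]
    frontier = []
    bt = Biotransformation(
        precursor=mol,
        products=tuple(fragments),
        rule_id="depolymerization",
        enzymes=(),
        reaction_type="hydrolytic depolymerization",
        biosystem=Biosystem.HUMAN,
        iteration=1,
        step_index=1,
    )
    graph.edges.append(bt)
    for frag in fragments:
        if frag.identity_key not in graph.nodes:
            graph.nodes[frag.identity_key] = GraphNode(frag, first_iteration=1, first_step=1)
            frontier.append(frag)
    return graph, frontier


def _allhuman_configs() -> tuple[ModuleConfig, ...]:
    return tuple(ModuleConfig(phase=p) for p in ALLHUMAN_PHASES)


def run_allhuman(
    mol: Molecule,
    n: int,
    rulebase: Rulebase,
    guard: GuardProfile | None = None,
    endogenous_table: Sequence[EndogenousReactionEntry] | None = None,
    node_cap: int = DEFAULT_NODE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
) -> MetabolismGraph:
    """General human metabolism: each iteration is the deduplicated union
    of phase I, phase II, EC-based and gut-microbial passes (plus the
    endogenous lookup when a table is supplied)."""
    if n not in (1, 2, 3):
        raise ConfigurationError(f"iterations must be 1..{MAX_ITERATIONS}, got {n}")
    graph, frontier = _rooted_frontier(mol, True)
    _run(
        graph, frontier, _allhuman_configs(), n, rulebase, guard, endogenous_table,
        1, 0, node_cap, product_cap,
    )
    return graph


def run_superbio(
    mol: Molecule,
    rulebase: Rulebase,
    guard: GuardProfile | None = None,
    endogenous_table: Sequence[EndogenousReactionEntry] | None = None,
    node_cap: int = DEFAULT_NODE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
) -> MetabolismGraph:
    """AllHuman iterated exactly four times, or until no novel metabolite
    is produced, whichever comes first."""
    graph, frontier = _rooted_frontier(mol, True)
    _run(
        graph, frontier, _allhuman_configs(), SUPERBIO_ITERATIONS, rulebase, guard,
        endogenous_table, 1, 0, node_cap, product_cap,
    )
    return graph


def run_multibio(
    mol: Molecule,
    seq: TransformationSequence,
    rulebase: Rulebase,
    guard: GuardProfile | None = None,
    endogenous_table: Sequence[EndogenousReactionEntry] | None = None,
    node_cap: int = DEFAULT_NODE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
) -> MetabolismGraph:
    """Execute a custom (module, iterations) plan.

    Step k's input is every metabolite produced by step k-1 (the query, or
    its depolymerization fragments, for step 1); each step follows
    :func:`run_iterations` frontier semantics internally and stamps its
    ``step_index`` on every edge.
    """
    if not isinstance(seq, TransformationSequence):
        raise ConfigurationError("seq must be a TransformationSequence")
    graph, frontier = _rooted_frontier(mol, True)
    step_inputs = list(frontier)
    iteration_offset = 0
    for k, (phase, iters) in enumerate(seq.steps, start=1):
        if not step_inputs or graph.truncated:
            break
        nodes_before = set(graph.nodes)
        config = ModuleConfig(phase=phase)
        _run(
            graph, step_inputs, (config,), iters, rulebase, guard, endogenous_table,
            k, iteration_offset, node_cap, product_cap,
        )
        iteration_offset += iters
        produced = [graph.nodes[k2].molecule for k2 in sorted(set(graph.nodes) - nodes_before)]
        step_inputs = produced
    return graph


# --------------------------------------------------------------------------
# biopolymer depolymerization
# --------------------------------------------------------------------------

# peptide bond between two alpha carbons (amino on one side, carbonyl on the other)
_PEPTIDE_BOND = Chem.MolFromSmarts(
    "[CX3;$([CX3]([CX4;$([CX4][NX3])])=[OX1]):1](=[OX1])[NX3;H1;$([NX3][CX4;$([CX4][CX3]=[OX1])]):2]"
)
# anomeric carbon of a pyranose linked through an exocyclic oxygen to an aglycone
_GLYCOSIDIC_BOND = Chem.MolFromSmarts(
    "[CX4;R;$([CX4]([OX2;R])[#6;R]):1]([OX2;R])[OX2;!R:2][#6;!$([CX3]=[OX1]):3]"
)


def _sugar_ring_ok(mol: Chem.Mol, anomeric_idx: int) -> bool:
    """The anomeric carbon must sit in a 5/6-ring carrying >=2 exocyclic
    oxygens (a crude but serviceable sugar detector)."""
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if anomeric_idx not in ring or len(ring) not in (5, 6):
            continue
        exo_o = 0
        for idx in ring:
            atom = mol.GetAtomWithIdx(idx)
            for nbr in atom.GetNeighbors():
                if nbr.GetIdx() not in ring and nbr.GetAtomicNum() == 8:
                    exo_o += 1
        if exo_o >= 2:
            return True
    return False


def depolymerize(
    mol: Molecule,
    max_residues: int = 6,
    max_sugar_units: int = 4,
) -> list[Molecule]:
    """Cleave small biopolymers (peptides, glycosides) into monomer-level
    fragments by exhaustive hydrolysis of the detected linkages.

    Peptides up to ``max_residues`` residues are hydrolyzed at every
    backbone amide; glycosides up to ``max_sugar_units`` sugar units at
    every glycosidic bond. Anything else — including molecules above the
    size thresholds — passes through unchanged.
    """
    rd = Chem.RWMol(mol.to_rdkit())
    cleavages: list[tuple[int, int, str]] = []  # (a, b, kind)
    peptide_hits = rd.GetSubstructMatches(_PEPTIDE_BOND)
    if peptide_hits and len(peptide_hits) + 1 <= max_residues:
        for match in peptide_hits:
            cleavages.append((match[0], match[-1], "peptide"))
    glyco_hits = [
        m for m in rd.GetSubstructMatches(_GLYCOSIDIC_BOND) if _sugar_ring_ok(rd, m[0])
    ]
    if glyco_hits and len(glyco_hits) <= max_sugar_units:
        for match in glyco_hits:
            cleavages.append((match[0], match[2], "glycoside"))
    if not cleavages:
        return [mol]
    for a, b, kind in cleavages:
        bond = rd.GetBondBetweenAtoms(a, b)
        if bond is None:
            continue
        rd.RemoveBond(a, b)
        # hydrolysis: the carbonyl/anomeric carbon gains a hydroxyl,
        # the leaving nitrogen/oxygen is re-protonated implicitly
        oxygen = rd.AddAtom(Chem.Atom(8))
        rd.AddBond(a, oxygen, Chem.BondType.SINGLE)
    fragments: list[Molecule] = []
    seen: set[str] = set()
    try:
        for frag in Chem.GetMolFrags(rd.GetMol(), asMols=True, sanitizeFrags=False):
            m = from_rdkit(frag)
            if m.identity_key not in seen:
                seen.add(m.identity_key)
                fragments.append(m)
    except Exception:
        logger.warning("depolymerization of %s failed; passing through", mol.structure)
        return [mol]
    fragments.sort(key=lambda m: (-sum(m.heavy_atom_formula.values()), m.structure))
    return fragments or [mol]
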