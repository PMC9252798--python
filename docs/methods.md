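# Methods

## Model and scope

`biotx` is a deterministic, rule-based biotransformation engine. Its
working hypothesis is the standard one for expert-system metabolism
predictors: if a molecule presents a functional group that a
well-characterized enzyme class is known to transform, the corresponding
product is a *biologically feasible* (not certain) metabolite. The engine
therefore over-predicts by design and pairs prediction with filtering
(identification filters, plausibility guard) rather than with kinetic or
probabilistic ranking. Reaction likelihood scores, site-of-metabolism
models and trained substrate classifiers are out of scope; the CYP450
module is gated purely by structural predicates, and configuration
requests for model-backed CYP modes are rejected rather than silently
approximated.

## Structure standardization and identity

All structures pass one fixed pipeline: parse → RDKit sanitization →
charge neutralization (RDKit Uncharger; overall-neutral zwitterions such
as N-oxides are preserved) → explicit-hydrogen removal → canonical
SMILES. Identity everywhere is the InChIKey of the standardized
structure; two SMILES spellings of the same molecule always collapse to
one network node. Input stereochemistry is preserved through parsing;
SMIRKS application may drop stereo at mapped (reacting) atoms only.
ALogP is the Wildman–Crippen atom-contribution estimate as implemented
in RDKit; monoisotopic mass sums most-abundant-isotope masses including
implicit hydrogens; the 1500 Da input gate uses the *average* molecular
weight, the conventional reading of "molecular weight". Formulas are
printed in CHNOPS order with remaining elements alphabetical.

## The rule schema

Rules live in YAML (`src/biotx/data/rules.yaml`), one mapping per rule:
`rule_id`, `name`, `substrate_smarts`, `transform_smirks`, `enzymes`
(name + optional EC / CYP isoform), `reaction_type`, `biosystem`
(human / human_gut / environment), `phase` (phase1_cyp / phase2 /
ec_based / gut_microbial / env_microbial), `priority` (used only for
deterministic ordering and duplicate resolution), `citations`, and
optional `reagent_delta` / `leaving_delta` formula strings. The deltas
declare what an implicit co-substrate contributes (e.g. `O` for a
hydrolysis, `C6O7` for the glucuronosyl donor) and what leaves
unreported (e.g. `Cl` for a reductive dehalogenation); they feed only
the heavy-atom conservation audit, never the transform itself. Every
rule is compiled at load; a bad pattern, a duplicate id, or a
product-side atom map with no reactant-side partner fails the load with
the offending `rule_id` named. `lint_rule` additionally probes each
rule's substrate gate against a panel to catch gates that promise more
than the SMIRKS template can match.

The bundled starter set holds 64 rules: 21 phase I (aromatic, benzylic,
ω- and sub-terminal hydroxylation, N-/O-demethylation, epoxidation,
S-/N-oxidation, annotated across all nine major CYP isoforms), 13
phase II (O-/N-/acyl glucuronidation, O-sulfation, N-acetylation,
glycine conjugation, glutathione ring-opening of epoxides, catechol
O- and thiol S-methylation), 10 EC-based (ester/amide/phosphate/
glycoside hydrolysis, alcohol and aldehyde oxidation, epoxide
hydration, oxidative deamination, carbonyl reduction), 10 gut microbial
(nitro and azo reduction, glucuronide/sulfate deconjugation,
decarboxylation, enoate reduction, dehydroxylation, reductive
dechlorination, ester and glucoside hydrolysis) and 10 environmental
(hydrolytic dehalogenations, nitrile/ester/amide hydrolysis,
hydroxylation, O-demethylation, nitro reduction, alkene hydration).
It is a curated subset chosen so every engine behavior is exercisable,
not a complete reaction atlas; isoform annotations are editorial,
drawn from the cited reaction-class literature. Where the same
chemistry is catalyzed in two biosystems (e.g. ester hydrolysis), it
appears as two rules with distinct ids, so each rule belongs to exactly
one phase.

## Rule application

One rule application enumerates every substrate match site
independently (RDKit `RunReactants`), splits disconnected products into
fragments, standardizes each, and merges sites whose product sets are
identical by InChIKey — so phenol's five aromatic CH sites yield three
regio-isomeric diols. Within one biotransformation, products are
ordered main-product-first (most heavy atoms, canonical-SMILES
tie-break) and deduplicated by identity; co-products such as acetate,
CO₂ or formaldehyde are retained after the main product. An
unsanitizable product skips that site with a warning and never aborts
the prediction. Rules do not fire on products created within the same
pass; chaining happens only across iterations.

The conservation audit checks, for every fired transformation, that the
heavy-atom multiset of (precursor + reagent_delta) equals that of
(products + leaving_delta). Because identical products are merged, each
reported product may be counted with multiplicity 1 or 2 in the balance
(a symmetric cleavage such as azobenzene → 2 × aniline reports one
aniline).

## Iteration, combination modes, and caps

A run grows a graph rooted at the query: iteration *i* applies the
selected module(s) to the frontier (nodes first seen at *i* − 1), admits
novel products by identity key, and stops early when the frontier
empties. Single-module runs allow 1–3 iterations; SuperBio fixes the
AllHuman union at 4 iterations with early stop; MultiBio accepts at most
four steps of at most three iterations each. The wording of the
per-step versus overall iteration budget is ambiguous in common usage,
so the engine enforces ≤ 4 steps × ≤ 3 iterations and logs a warning
when a plan requests more than four total passes instead of guessing a
stricter intent. Step *k* of a MultiBio plan consumes *all* metabolites
produced by step *k* − 1, matching the worked semantics of custom
multi-step transformation (two CYP rounds, then gut, then phase II).
Edges record both their iteration and their step, and an edge's
iteration always exceeds its precursor's first-seen iteration, so the
network is acyclic in generation order.

The endogenous-metabolite pass is a pure exact lookup: if the query (or
a frontier metabolite) matches a table entry by InChIKey, the table's
reactions and products are emitted with their own annotations. It is
wired into the EC-based scope of AllHuman/SuperBio runs and into
single-module EC runs whenever a table is supplied; passing no table
disables it. The bundled 20-entry table covers common primary
metabolites (glycolysis/TCA acids, amino acids, glucose phosphates) and
stands in for a full endogenous reaction database.

Two safety valves bound growth: a global node cap (default 1000) and a
per-precursor product cap (default 64). Hitting either logs a warning,
marks the graph `truncated`, and stops expansion cleanly — a run can
never loop indefinitely because admission is keyed on a finite set of
identity keys and every iteration strictly consumes its frontier.

## The plausibility guard

The guard encodes the observation that real excreted metabolites occupy
a bounded physico-chemical envelope. For each compartment —
renal/hepatic (urine-like) and gut/fecal — it holds [p1, p99] percentile
bands over four descriptors: average mass, ALogP, heteroatom count and
ring count, computed from a bundled *synthetic* reference descriptor
table (`guard_reference_synthetic.csv`, a hand-curated stand-in for
real urinary/fecal metabolome descriptor sets; the derivation code is
`GuardProfile.from_reference_table`, so real tables drop in directly).
A reaction is aborted when its **main product** falls outside any band
of the compartment matching the rule's biosystem (human →
renal/hepatic, gut → gut/fecal); environmental products are not
screened against human compartments. Aborting removes the edge and its
products; the precursor remains a terminal node. Co-products are
deliberately not screened — they are small by nature and would
otherwise be rejected wholesale.

Caveat: the envelope table must contain conjugates, or phase II
products (systematically heavier than their precursors) would be
wrongly aborted. The bundled renal table therefore includes
glucuronide, sulfate, glycine and mercapturate conjugates; its p99 mass
(~410 Da) still rejects second-generation conjugates-of-conjugates,
which is the intended explosion control. On an acetaminophen SuperBio
run the guard cuts the network from the 1000-node cap to ~330 nodes.

## Biopolymer depolymerization

Before any module runs, the query is screened for small-biopolymer
linkages: backbone peptide bonds (carbonyl and amide nitrogen each
flanked by an α-carbon) and glycosidic bonds (pyranose anomeric carbon
with an exocyclic oxygen to a non-acyl aglycone, the ring carrying ≥ 2
exocyclic oxygens). Detected linkages are hydrolyzed exhaustively — all
at once, adding the water across each broken bond — and the
deduplicated fragments replace the query as the starting frontier,
recorded under a single depolymerization edge from the root. Peptides
above 6 residues and glycosides above 4 sugar units pass through
unchanged (thresholds configurable); so does everything without a
detected linkage, including ordinary amides like acetaminophen. The
detector is deliberately conservative: it aims never to shred a plain
drug-like molecule, at the cost of missing exotic polymer chemistry.

## Evaluation harness

`evaluate_cases` scores each (reactant, enzyme-or-module label) case by
running the designated module once, pooling all product identity keys,
and computing the Jaccard index against the reference set; scores are
averaged per enzyme label, per substrate–enzyme pair first (never
pooled across cases). Identity is compared on the first InChIKey block
by default — rule products often lack stereo, and skeleton-level
comparison avoids penalizing a correct structure for a missing stereo
bond — with full-key comparison available. A CYP isoform label runs
phase I restricted to rules carrying that isoform; a module label runs
the module.

The fixture generator writes a deterministic bundle per seed: the
50-molecule probe panel (every starter rule matches at least one panel
member), ten reference cases whose truths are the engine's own reachable
predictions plus 0–2 seeded decoy identifiers per case (so benchmark
scores are strictly between 0 and 1 and exactly recomputable), and
copies of the guard and endogenous tables. Because truths derive from
the starter rulebase, the benchmark validates the *harness and engine
plumbing*, not chemical accuracy against published metabolism data —
absolute benchmark scores on external reference sets depend on rulebase
completeness and are explicitly not a claim of this package.

## What the synthetic fixtures do and do not show

The probe panel spans the starter rules' functional groups with real,
well-known molecules (drugs, phenolics, sugars, amino acids), so green
tests demonstrate correct parsing, gating, site enumeration, atom
bookkeeping, iteration semantics, guard algebra and export fidelity on
realistic chemistry. They do not demonstrate coverage of the long tail
of xenobiotic chemistry (organophosphates, polyhalogenated aromatics,
N-heterocycle oxidations …), correctness of isoform assignment for any
particular drug, or quantitative agreement with in vivo metabolite
panels. The guard reference table is synthetic; its envelopes are
plausible but not estimates of real urinary/fecal descriptor
distributions.

## Numerical and determinism choices

Masses are rounded to 4 decimals in exports (6 internally), ALogP to 4;
CSV floats are formatted with fixed precision so identical runs are
byte-identical. All orderings are explicit: rules by (priority,
rule_id); biotransformations by (precursor key, rule_id, sorted product
keys); records by (iteration, step, rule_id, product key). There is no
randomness anywhere in the prediction path; the only seeded component
is the fixture generator's decoy injection. Degenerate inputs are
defined: empty rule files load as empty rulebases with a warning, a
molecule with no applicable rules yields a root-only graph, an empty
record list exports a header-only CSV / empty JSON array / empty SDF.

## Test problem sizes

The suite exercises the full 64-rule starter set against the 50-molecule
panel for gating, conservation and determinism; the brute-force oracle
comparison runs on a 30-molecule × all-rules grid; iteration-monotonicity
runs the phase II module at n = 1, 2, 3 across the panel (guarded) and a
12-molecule subset (unguarded); explosion tests use reduced node caps.
These sizes keep the whole suite under a minute while touching every
rule and every module at least once.

## Known limitations

* Rule coverage is a starter subset (64 rules vs. the >900 of a mature
  knowledgebase); absent chemistry is simply not predicted.
* CYP gating is structural, not learned: a molecule "is a substrate" of
  an isoform iff any rule annotated with that isoform matches it, which
  over-opens gates for promiscuous patterns like aromatic CH.
* The guard screens only the main product and only against two human
  compartments; blood-compartment envelopes and per-reaction-class
  envelopes are natural extensions.
* Stereochemistry at reaction centers is dropped; products are reported
  as flat skeletons (hence first-block identity in scoring).
* Synonyms/PubChem-ID fields are emitted empty; enrichment against
  external services is intentionally left to downstream tooling.
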