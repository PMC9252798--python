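# biotx

Rule-based prediction of metabolic transformation products for small
organic molecules.

Given one query structure (SMILES or single-record SDF), `biotx` applies a
curated knowledgebase of SMARTS/SMIRKS reaction rules spanning five
biotransformation modules — human phase I (CYP450) oxidation, human
phase II conjugation, EC-number-based enzymatic chemistry, human gut
microbial metabolism and environmental microbial degradation — and
iterates the resulting metabolic network under anti-explosion guards. It
is aimed at metabolomics and exposomics practitioners who need candidate
structures for unknown MS features, and at drug-metabolism scientists who
want fast, transparent, rule-level provenance for every predicted
metabolite.

## What it computes

Each knowledgebase rule couples a substrate precondition (a SMARTS
pattern) with a mapped molecular transform (a SMIRKS reaction), an enzyme
annotation (CYP isoform, EC number, or microbial process), a biosystem
and a reaction-phase category. For a query molecule *M* and module scope
*S*, one pass emits every biotransformation

&nbsp;&nbsp;&nbsp;&nbsp;*M* →<sub>r</sub> {*P*₁, …, *P*ₖ},&nbsp;&nbsp; r ∈ S, substrate(r) matches *M*,

with one edge per symmetry-distinct reaction site, products standardized
and deduplicated by InChIKey, and small co-products (acetate, CO₂,
formaldehyde, …) retained alongside the main product. Phase I rules are
additionally gated per CYP isoform (nine major isoforms: 1A2, 2A6, 2B6,
2C8, 2C9, 2C19, 2D6, 2E1, 3A4). Iterating *n* times (1–3) feeds each
round's novel products back into the selected scheme. Combination modes:

* **AllHuman** — union of phase I + phase II + EC + gut passes per
  iteration (plus an endogenous-metabolite lookup keyed on InChIKey);
* **SuperBio** — AllHuman for four iterations or until no novel
  metabolite appears;
* **MultiBio** — a custom plan of up to four (module, iterations ≤ 3)
  steps, each step consuming everything the previous step produced.

A plausibility guard can abort any reaction whose main product falls
outside per-descriptor [p1, p99] envelopes (average mass, ALogP,
heteroatom count, ring count) derived from reference renal/hepatic and
gut/fecal metabolite descriptor tables; a node cap (1000) and
per-precursor product cap (64) bound network growth. Prediction quality
against a reference set is scored with the Jaccard index
J = |predicted ∩ known| / |predicted ∪ known| per substrate–enzyme pair.

## Worked example

```bash
biotx predict --input-smiles "CC(=O)Nc1ccc(O)cc1" --mode allhuman \
      --iterations 1 --guard on --out apap.csv --format csv
# 16 prediction records (8 distinct metabolites) written to apap.csv
```

The first records of the table (acetaminophen query):

| reaction_type          | formula | monoisotopic_mass | product_smiles          |
|------------------------|---------|-------------------|-------------------------|
| amide hydrolysis       | C6H7NO  | 109.0528          | Nc1ccc(O)cc1            |
| amide hydrolysis       | C2H4O2  | 60.0211           | CC(=O)O                 |
| dehydroxylation        | C8H9NO  | 135.0684          | CC(=O)Nc1ccccc1         |
| aromatic hydroxylation | C8H9NO3 | 167.0582          | CC(=O)Nc1ccc(O)c(O)c1   |

Reading it: one AllHuman iteration deacetylates acetaminophen to
4-aminophenol *and keeps the acetate co-product*, proposes the gut
microbial dehydroxylation to acetanilide, and hydroxylates the ring
(e.g. to 3-hydroxyacetaminophen, monoisotopic mass 167.0582 Da — the
value an MS feature would be matched against). The full CSV/JSON/SDF
exports add InChI/InChIKey, both masses, enzyme annotations, biosystem,
precursor context and ALogP values; `filter_records` supports exact
SMILES/formula filters and a monoisotopic-mass window for metabolite
identification.

The same run from Python:

```python
from biotx import parse_structure, load_default_rulebase, run_allhuman
from biotx.reporting import graph_to_records

rulebase = load_default_rulebase()          # 64-rule curated starter set
mol = parse_structure("CC(=O)Nc1ccc(O)cc1")
graph = run_allhuman(mol, 1, rulebase)
records = graph_to_records(graph)           # 16 records, 8 metabolites
```

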