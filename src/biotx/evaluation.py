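"""Jaccard evaluation harness and deterministic fixture generation.

``evaluate_cases`` replicates the benchmark protocol used for rule-based
metabolism predictors: for each (reactant, enzyme) reference case, run the
designated module, deduplicate predictions by structural identity and
score them against the known product set with the Jaccard index; scores
are averaged per enzyme label. By default identity is compared on the
first InChIKey block (stereo-insensitive skeleton), since rule products
may lack stereo annotations; full-key comparison is available.

``generate_fixtures`` writes the self-contained test bundle (probe panel,
reference cases, guard descriptor table, endogenous table) so every module
is exercisable without any download.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from biotx.chem_core import Molecule, parse_structure
from biotx.rulebase import Phase, Rulebase
from biotx.transformers import CYP_ISOFORMS, ModuleConfig, run_module

#: 50-molecule probe panel spanning the starter rules' functional groups.
PROBE_PANEL: tuple[tuple[str, str], ...] = (
    ("CC(=O)Nc1ccc(O)cc1", "acetaminophen"),
    ("Oc1ccccc1", "phenol"),
    ("Cc1ccccc1", "toluene"),
    ("Nc1ccccc1", "aniline"),
    ("COc1ccccc1", "anisole"),
    ("c1ccccc1", "benzene"),
    ("OC(=O)c1ccccc1", "benzoic acid"),
    ("CN(C)c1ccccc1", "N,N-dimethylaniline"),
    ("CSc1ccccc1", "thioanisole"),
    ("C=Cc1ccccc1", "styrene"),
    ("C1OC1c1ccccc1", "styrene oxide"),
    ("O=[N+]([O-])c1ccccc1", "nitrobenzene"),
    ("c1ccc(/N=N/c2ccccc2)cc1", "azobenzene"),
    ("Clc1ccccc1", "chlorobenzene"),
    ("Brc1ccccc1", "bromobenzene"),
    ("ClCCc1ccccc1", "(2-chloroethyl)benzene"),
    ("N#Cc1ccccc1", "benzonitrile"),
    ("Oc1ccccc1O", "catechol"),
    ("CCO", "ethanol"),
    ("CC(C)O", "isopropanol"),
    ("CC=O", "acetaldehyde"),
    ("CCOC(C)=O", "ethyl acetate"),
    ("CCCC", "butane"),
    ("NCCc1ccccc1", "phenethylamine"),
    ("CCC(C)=O", "butanone"),
    ("OCC1OC(O)C(O)C(O)C1O", "glucose"),
    ("Oc1ccc(OS(=O)(=O)O)cc1", "hydroquinone sulfate"),
    ("Oc1ccc(OC2OC(C(=O)O)C(O)C(O)C2O)cc1", "hydroquinone glucuronide"),
    ("OCC1OC(Oc2ccccc2CO)C(O)C(O)C1O", "salicin"),
    ("O=C(O)/C=C/c1ccccc1", "cinnamic acid"),
    ("OC1OC(COP(=O)(O)O)C(O)C(O)C1O", "glucose 6-phosphate"),
    ("OC(=O)Cc1ccccc1", "phenylacetic acid"),
    ("CS", "methanethiol"),
    ("Cc1ccc(O)cc1", "p-cresol"),
    ("Oc1ccc(Cl)cc1", "4-chlorophenol"),
    ("CN1CCCC1c1cccnc1", "nicotine"),
    ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine"),
    ("CC(C)Cc1ccc(C(C)C(=O)O)cc1", "ibuprofen"),
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("NC(=O)c1ccccc1", "benzamide"),
    ("Nc1ccc(O)cc1", "4-aminophenol"),
    ("Oc1cccc(O)c1", "resorcinol"),
    ("COc1cc(C=O)ccc1O", "vanillin"),
    ("NCCc1ccc(O)cc1", "tyramine"),
    ("NCCc1ccc(O)c(O)c1", "dopamine"),
    ("CC(O)c1ccccc1", "1-phenylethanol"),
    ("NCC(=O)NC(C)C(=O)O", "glycylalanine"),
    ("NCC(=O)O", "glycine"),
    ("CC(N)C(=O)O", "alanine"),
    ("CCCCCC(=O)O", "hexanoic acid"),
)


@dataclass(frozen=True)
class ReferenceCase:
    """One benchmark case: a reactant, an enzyme or module label, and the
    set of known product InChIKeys (or first blocks)."""

    reactant: str
    enzyme_label: str
    true_products: frozenset[str]

    def __post_init__(self):
        if not self.true_products:
            raise ValueError("true_products must be non-empty")
        parse_structure(self.reactant)  # raises if the reactant is malformed


def jaccard_score(predicted: Iterable[str], truth: Iterable[str]) -> float:
    """|intersection| / |union| of two identifier sets; raises on empty
    truth, returns 0.0 for empty predictions."""
    predicted, truth = set(predicted), set(truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not predicted:
        return 0.0
    return len(predicted & truth) / len(predicted | truth)


_MODULE_LABELS = {
    "phase1_cyp": Phase.PHASE1_CYP,
    "phase2": Phase.PHASE2,
    "ec_based": Phase.EC_BASED,
    "gut_microbial": Phase.GUT_MICROBIAL,
    "env_microbial": Phase.ENV_MICROBIAL,
}


def _identity(key: str, key_mode: str) -> str:
    return key.split("-")[0] if key_mode == "first_block" else key


def predict_for_label(
    reactant: Molecule, enzyme_label: str, rulebase: Rulebase, key_mode: str = "first_block"
) -> set[str]:
    """One-pass predictions for a case label: a CYP isoform label runs
    phase I restricted to rules carrying that isoform; a module label runs
    that module."""
    if enzyme_label in CYP_ISOFORMS:
        from biotx.rule_engine import applicable_rules, apply_rule

        keys: set[str] = set()
        for rule in applicable_rules(reactant, rulebase, (Phase.PHASE1_CYP,)):
            if enzyme_label not in rule.cyp_isoforms:
                continue
            for bt in apply_rule(reactant, rule):
                keys.update(_identity(p.identity_key, key_mode) for p in bt.products)
        return keys
    if enzyme_label not in _MODULE_LABELS:
        raise ValueError(f"unknown enzyme/module label {enzyme_label!r}")
    bts = run_module([reactant], ModuleConfig(phase=_MODULE_LABELS[enzyme_label]), rulebase)
    return {
        _identity(p.identity_key, key_mode) for bt in bts for p in bt.products
    }


def evaluate_cases(
    cases: Sequence[ReferenceCase],
    rulebase: Rulebase,
    key_mode: str = "first_block",
) -> pd.DataFrame:
    """Run the engine per case and average Jaccard scores per enzyme label.

    Scoring is per substrate–enzyme pair, then arithmetic-mean aggregated
    per enzyme label. Returns a one-row DataFrame with enzyme labels as
    columns (benchmark-table shape); write it with ``to_csv``.
    """
    scores: dict[str, list[float]] = {}
    for case in cases:
        reactant = parse_structure(case.reactant)
        predicted = predict_for_label(reactant, case.enzyme_label, rulebase, key_mode)
        truth = {_identity(k, key_mode) for k in case.true_products}
        scores.setdefault(case.enzyme_label, []).append(jaccard_score(predicted, truth))
    row = {label: float(np.mean(vals)) for label, vals in scores.items()}
    return pd.DataFrame([row], index=["mean_jaccard"])


def load_reference_cases(path: str | Path) -> list[ReferenceCase]:
    """Read the TSV case format: reactant_smiles, enzyme_label,
    truth_inchikeys (semicolon-separated)."""
    cases: list[ReferenceCase] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("reactant_smiles") or line.startswith("#"):
            continue
        reactant, label, truths = line.split("\t")
        cases.append(
            ReferenceCase(
                reactant=reactant,
                enzyme_label=label,
                true_products=frozenset(t for t in truths.split(";") if t),
            )
        )
    return cases


_FIXTURE_CASE_SPECS: tuple[tuple[str, str], ...] = (
    ("Oc1ccccc1", "2E1"),
    ("Cc1ccccc1", "2D6"),
    ("CN(C)c1ccccc1", "3A4"),
    ("COc1ccccc1", "2C19"),
    ("C=Cc1ccccc1", "2E1"),
    ("CC(=O)Nc1ccc(O)cc1", "phase2"),
    ("Nc1ccccc1", "phase2"),
    ("CCOC(C)=O", "ec_based"),
    ("O=[N+]([O-])c1ccccc1", "gut_microbial"),
    ("Clc1ccccc1", "env_microbial"),
)


def generate_fixtures(seed: int, out_dir: str | Path, rulebase: Rulebase | None = None) -> Path:
    """Write the deterministic fixture bundle into ``out_dir``.

    Contents: ``panel.smi`` (the 50-molecule probe panel),
    ``reference_cases.tsv`` (10 cases whose truths are the engine's own
    reachable products plus seeded decoy identifiers),
    ``guard_reference_synthetic.csv`` and ``endogenous.tsv`` (copies of the
    bundled tables). Identical seeds produce byte-identical bundles.
    """
    from biotx.rulebase import load_default_rulebase

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rulebase = rulebase or load_default_rulebase()
    rng = np.random.RandomState(seed)

    with open(out_dir / "panel.smi", "w") as fh:
        for smiles, name in PROBE_PANEL:
            fh.write(f"{smiles}\t{name}\n")

    # decoy pool: panel molecules' own first blocks (guaranteed well-formed
    # identifiers that no single-step prediction will produce for the case)
    panel_keys = sorted({parse_structure(s).identity_key.split("-")[0] for s, _ in PROBE_PANEL})
    lines = ["reactant_smiles\tenzyme_label\ttruth_inchikeys"]
    for reactant_smiles, label in _FIXTURE_CASE_SPECS:
        mol = parse_structure(reactant_smiles)
        predicted = sorted(predict_for_label(mol, label, rulebase, key_mode="first_block"))
        decoy_pool = [k for k in panel_keys if k not in predicted]
        n_decoys = int(rng.randint(0, 3))
        decoys = list(rng.choice(decoy_pool, size=n_decoys, replace=False)) if n_decoys else []
        truths = predicted + sorted(decoys)
        lines.append(f"{reactant_smiles}\t{label}\t{';'.join(truths)}")
    (out_dir / "reference_cases.tsv").write_text("\n".join(lines) + "\n")

    for bundled in ("guard_reference_synthetic.csv", "endogenous.tsv"):
        with resources.as_file(resources.files("biotx.data") / bundled) as p:
            shutil.copy(p, out_dir / bundled)
    return out_dir
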