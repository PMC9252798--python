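"""Flattened prediction records, identification filters and CSV/JSON/SDF export.

Each (edge, product) pair of a metabolism graph becomes one
:class:`PredictionRecord` carrying the product's identity strings, its
CHNOPS-ordered formula, both masses, the reaction annotation and the
precursor context. Records order deterministically and all three export
formats round-trip the fields they carry.

The synonyms and PubChem-ID fields exist for interface parity with
annotation pipelines; they are emitted empty and can be filled by an
external enrichment hook.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from biotx.chem_core import format_formula, parse_structure
from biotx.orchestrator import MetabolismGraph

CSV_HEADER = (
    "product_smiles",
    "product_inchi",
    "product_inchikey",
    "formula",
    "molecular_weight",
    "monoisotopic_mass",
    "reaction_type",
    "enzyme_info",
    "biosystem",
    "precursor_smiles",
    "precursor_alogp",
    "product_alogp",
    "iteration",
    "step_index",
    "synonyms",
    "pubchem_id",
)


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted product with full annotation, ready for export."""

    product_smiles: str
    product_inchi: str
    product_inchikey: str
    formula: str
    molecular_weight: float
    monoisotopic_mass: float
    reaction_type: str
    enzyme_info: str
    biosystem: str
    precursor_smiles: str
    precursor_alogp: float
    product_alogp: float
    iteration: int
    step_index: int
    synonyms: str = ""
    pubchem_id: str = ""
    rule_id: str = ""  # provenance; not part of the fixed CSV header


def graph_to_records(graph: MetabolismGraph) -> list[PredictionRecord]:
    """One record per (edge, product) pair, deterministically ordered by
    (iteration, step_index, rule_id, product InChIKey)."""
    records: list[PredictionRecord] = []
    for bt in graph.edges:
        for product in bt.products:
            records.append(
                PredictionRecord(
                    product_smiles=product.structure,
                    product_inchi=product.inchi,
                    product_inchikey=product.identity_key,
                    formula=format_formula(product.formula),
                    molecular_weight=round(product.average_mass, 4),
                    monoisotopic_mass=round(product.monoisotopic_mass, 4),
                    reaction_type=bt.reaction_type,
                    enzyme_info="; ".join(e.label() for e in bt.enzymes),
                    biosystem=bt.biosystem.value,
                    precursor_smiles=bt.precursor.structure,
                    precursor_alogp=round(bt.precursor.alogp, 4),
                    product_alogp=round(product.alogp, 4),
                    iteration=bt.iteration,
                    step_index=bt.step_index,
                    rule_id=bt.rule_id,
                )
            )
    records.sort(
        key=lambda r: (r.iteration, r.step_index, r.rule_id, r.product_inchikey)
    )
    return records


def filter_records(
    records: Sequence[PredictionRecord],
    smiles: str | None = None,
    formula: str | None = None,
    mass_min: float | None = None,
    mass_max: float | None = None,
) -> list[PredictionRecord]:
    """Metabolite-identification filters; conditions compose as AND.

    The SMILES filter matches on structure identity (the filter string is
    canonicalized, not compared textually); the formula filter requires an
    exact match of the CHNOPS-ordered string; the mass window keeps
    ``mass_min <= monoisotopic_mass <= mass_max``.
    """
    if mass_min is not None and mass_max is not None and mass_min > mass_max:
        raise ValueError("mass_min must not exceed mass_max")
    out = list(records)
    if smiles is not None:
        target = parse_structure(smiles).identity_key  # raises on bad input
        out = [r for r in out if r.product_inchikey == target]
    if formula is not None:
        out = [r for r in out if r.formula == formula]
    if mass_min is not None:
        out = [r for r in out if r.monoisotopic_mass >= mass_min]
    if mass_max is not None:
        out = [r for r in out if r.monoisotopic_mass <= mass_max]
    return out


def _record_row(r: PredictionRecord) -> list[str]:
    return [
        r.product_smiles,
        r.product_inchi,
        r.product_inchikey,
        r.formula,
        f"{r.molecular_weight:.4f}",
        f"{r.monoisotopic_mass:.4f}",
        r.reaction_type,
        r.enzyme_info,
        r.biosystem,
        r.precursor_smiles,
        f"{r.precursor_alogp:.4f}",
        f"{r.product_alogp:.4f}",
        str(r.iteration),
        str(r.step_index),
        r.synonyms,
        r.pubchem_id,
    ]


def export(records: Sequence[PredictionRecord], format: str, path: str | Path) -> Path:
    """Write records as ``csv`` (fixed documented header), ``json`` (list of
    objects mirroring the record fields) or ``sdf`` (V2000, one entry per
    product with annotations as data fields)."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(CSV_HEADER)
            for r in records:
                writer.writerow(_record_row(r))
    elif format == "json":
        payload = []
        for r in records:
            d = asdict(r)
            d.pop("rule_id")
            d["molecular_weight"] = round(r.molecular_weight, 4)
            d["monoisotopic_mass"] = round(r.monoisotopic_mass, 4)
            payload.append(d)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in records:
                mol = Chem.MolFromSmiles(r.product_smiles)
                mol.SetProp("_Name", r.product_inchikey)
                for field, value in zip(CSV_HEADER, _record_row(r)):
                    mol.SetProp(field, value)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def read_csv_records(path: str | Path) -> list[PredictionRecord]:
    """Re-import a CSV export (field-for-field round trip)."""
    records: list[PredictionRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PredictionRecord(
                    product_smiles=row["product_smiles"],
                    product_inchi=row["product_inchi"],
                    product_inchikey=row["product_inchikey"],
                    formula=row["formula"],
                    molecular_weight=float(row["molecular_weight"]),
                    monoisotopic_mass=float(row["monoisotopic_mass"]),
                    reaction_type=row["reaction_type"],
                    enzyme_info=row["enzyme_info"],
                    biosystem=row["biosystem"],
                    precursor_smiles=row["precursor_smiles"],
                    precursor_alogp=float(row["precursor_alogp"]),
                    product_alogp=float(row["product_alogp"]),
                    iteration=int(row["iteration"]),
                    step_index=int(row["step_index"]),
                    synonyms=row["synonyms"],
                    pubchem_id=row["pubchem_id"],
                )
            )
    return records
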