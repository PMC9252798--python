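import dataclasses
import json

import pytest
from click.testing import CliRunner

from biotx.chem_core import parse_structure
from biotx.cli import main as cli_main
from biotx.orchestrator import run_allhuman, run_iterations
from biotx.reporting import (
    CSV_HEADER,
    export,
    filter_records,
    graph_to_records,
    read_csv_records,
)
from biotx.rulebase import Phase
from biotx.transformers import ModuleConfig


@pytest.fixture(scope="module")
def apap_records(rulebase):
    apap = parse_structure("CC(=O)Nc1ccc(O)cc1")
    return graph_to_records(run_allhuman(apap, 1, rulebase))


class TestGraphToRecords:
    def test_root_only_graph_empty(self, rulebase):
        graph = run_allhuman(parse_structure("C"), 1, rulebase)
        assert graph_to_records(graph) == []

    def test_one_record_per_edge_product(self, acetaminophen, rulebase):
        graph = run_allhuman(acetaminophen, 1, rulebase)
        assert len(graph_to_records(graph)) == sum(len(bt.products) for bt in graph.edges)

    def test_formula_consistent_with_smiles(self, apap_records):
        for r in apap_records:
            assert parse_structure(r.product_smiles).formula_string == r.formula
            assert abs(parse_structure(r.product_smiles).average_mass - r.molecular_weight) < 0.01


class TestFilters:
    def test_no_filters_identity(self, apap_records):
        assert filter_records(apap_records) == list(apap_records)

    def test_formula_exact_match(self, apap_records):
        hits = filter_records(apap_records, formula="C8H9NO3")  # hydroxylated parent
        assert hits and all(r.formula == "C8H9NO3" for r in hits)

    def test_smiles_filter_canonicalizes(self, apap_records):
        # non-canonical spelling of the O-sulfate conjugate
        raw = "O=S(=O)(O)Oc1ccc(NC(C)=O)cc1"
        hits = filter_records(apap_records, smiles=raw)
        assert hits and all(
            r.product_inchikey == parse_structure(raw).identity_key for r in hits
        )

    def test_mass_window(self, apap_records):
        hits = filter_records(apap_records, mass_min=151.0, mass_max=151.2)
        assert all(151.0 <= r.monoisotopic_mass <= 151.2 for r in hits)

    def test_bad_window_raises(self, apap_records):
        with pytest.raises(ValueError):
            filter_records(apap_records, mass_min=2.0, mass_max=1.0)

    def test_unparseable_smiles_filter_raises(self, apap_records):
        from biotx.chem_core import StructureError

        with pytest.raises(StructureError):
            filter_records(apap_records, smiles="C1CC")

    def test_composition_equals_intersection(self, apap_records):
        both = filter_records(apap_records, formula="C8H9NO3", mass_min=100.0)
        by_formula = set(map(id, filter_records(apap_records, formula="C8H9NO3")))
        by_mass = set(map(id, filter_records(apap_records, mass_min=100.0)))
        assert set(map(id, both)) == by_formula & by_mass


class TestExport:
    def test_empty_csv_is_header_only(self, tmp_path):
        p = export([], "csv", tmp_path / "empty.csv")
        assert p.read_text().strip() == ",".join(CSV_HEADER)

    def test_json_array_length(self, apap_records, tmp_path):
        p = export(apap_records[:3], "json", tmp_path / "r.json")
        assert len(json.loads(p.read_text())) == 3

    def test_csv_roundtrip_field_for_field(self, apap_records, tmp_path):
        p = export(apap_records, "csv", tmp_path / "r.csv")
        again = read_csv_records(p)
        assert [dataclasses.replace(r, rule_id="") for r in apap_records] == again

    def test_formats_agree_on_shared_fields(self, apap_records, tmp_path):
        from rdkit import Chem

        export(apap_records, "csv", tmp_path / "r.csv")
        export(apap_records, "json", tmp_path / "r.json")
        export(apap_records, "sdf", tmp_path / "r.sdf")
        csv_rows = read_csv_records(tmp_path / "r.csv")
        json_rows = json.loads((tmp_path / "r.json").read_text())
        sdf_mols = list(Chem.SDMolSupplier(str(tmp_path / "r.sdf")))
        assert len(csv_rows) == len(json_rows) == len(sdf_mols)
        for c, j, s in zip(csv_rows, json_rows, sdf_mols):
            assert c.product_inchikey == j["product_inchikey"] == s.GetProp("product_inchikey")
            assert c.formula == j["formula"] == s.GetProp("formula")


class TestCli:
    def test_predict_smiles_to_csv(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out.csv"
        result = runner.invoke(
            cli_main,
            ["predict", "--input-smiles", "Oc1ccccc1", "--mode", "phase2",
             "--guard", "off", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert len(read_csv_records(out)) > 0

    def test_validation_failure_exit_code_2(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["predict", "--input-smiles", "CC.O", "--mode", "phase2",
             "--out", str(tmp_path / "x.csv")],
        )
        assert result.exit_code == 2
        assert "MIXTURE" in result.output

    def test_unsupported_cyp_mode_rejected(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["predict", "--input-smiles", "Oc1ccccc1", "--mode", "cyp450",
             "--cyp-mode", "cyproduct", "--out", str(tmp_path / "x.csv")],
        )
        assert result.exit_code == 2

    def test_multibio_sequence(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "m.json"
        result = runner.invoke(
            cli_main,
            ["predict", "--input-smiles", "Oc1ccccc1", "--mode", "multibio",
             "--sequence", "phase2:1,gut:1", "--guard", "on",
             "--out", str(out), "--format", "json"],
        )
        assert result.exit_code == 0, result.output
        assert json.loads(out.read_text())
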