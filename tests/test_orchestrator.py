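import pytest

from biotx.chem_core import parse_structure
from biotx.orchestrator import (
    ConfigurationError,
    GuardDecision,
    GuardProfile,
    TransformationSequence,
    depolymerize,
    plausibility_guard,
    run_allhuman,
    run_iterations,
    run_multibio,
    run_superbio,
)
from biotx.rulebase import Biosystem, Phase, Rulebase
from biotx.transformers import ModuleConfig


@pytest.fixture(scope="module")
def phase2_config():
    return ModuleConfig(phase=Phase.PHASE2)


@pytest.fixture(scope="module")
def tight_guard():
    """A constructed guard whose mass ceiling excludes any conjugate."""
    return GuardProfile(
        envelopes={
            "renal_hepatic": {
                "average_mass": (40.0, 200.0),
                "alogp": (-5.0, 5.0),
                "heteroatom_count": (0.0, 20.0),
                "ring_count": (0.0, 5.0),
            },
            "gut_fecal": {
                "average_mass": (40.0, 200.0),
                "alogp": (-5.0, 5.0),
                "heteroatom_count": (0.0, 20.0),
                "ring_count": (0.0, 5.0),
            },
        }
    )


class TestRunIterations:
    def test_out_of_range_iteration_counts(self, acetaminophen, rulebase, phase2_config):
        for n in (0, 4, -1):
            with pytest.raises(ConfigurationError):
                run_iterations(acetaminophen, phase2_config, n, rulebase)

    def test_single_iteration_equals_single_pass(self, acetaminophen, rulebase, phase2_config):
        from biotx.rule_engine import transform_once

        graph = run_iterations(acetaminophen, phase2_config, 1, rulebase)
        bts = transform_once([acetaminophen], Phase.PHASE2, rulebase)
        expected = {k for bt in bts for k in bt.product_keys} | {acetaminophen.identity_key}
        assert set(graph.nodes) == expected

    def test_iteration2_conjugates_the_conjugates(self, phenol, rulebase, phase2_config):
        g1 = run_iterations(phenol, phase2_config, 1, rulebase)
        g2 = run_iterations(phenol, phase2_config, 2, rulebase)
        assert set(g1.nodes) <= set(g2.nodes)
        assert max(bt.iteration for bt in g2.edges) == 2

    def test_monotone_nodes_with_n(self, rulebase, guard, panel):
        config = ModuleConfig(phase=Phase.PHASE2)
        for mol in panel[:12]:
            previous: set = set()
            for n in (1, 2, 3):
                graph = run_iterations(mol, config, n, rulebase, guard=guard)
                assert previous <= set(graph.nodes), mol.structure
                previous = set(graph.nodes)

    def test_graph_nodes_unique_and_acyclic_in_generation(self, acetaminophen, rulebase, guard):
        graph = run_allhuman(acetaminophen, 2, rulebase, guard=guard)
        assert len(set(graph.nodes)) == len(graph.nodes)
        for bt in graph.edges:
            precursor_seen = graph.nodes[bt.precursor.identity_key].first_iteration
            assert bt.iteration > precursor_seen

    def test_node_cap_truncates(self, rulebase):
        benzene = parse_structure("c1ccccc1")
        graph = run_allhuman(benzene, 3, rulebase, node_cap=20)
        assert graph.truncated and len(graph) <= 20


class TestAllHumanAndSuperBio:
    def test_allhuman_superset_of_phase2(self, acetaminophen, rulebase):
        all_graph = run_allhuman(acetaminophen, 1, rulebase)
        p2_graph = run_iterations(
            acetaminophen, ModuleConfig(phase=Phase.PHASE2), 1, rulebase
        )
        assert set(p2_graph.nodes) <= set(all_graph.nodes)

    def test_allhuman_has_oxidative_and_conjugative_edges(self, acetaminophen, rulebase):
        graph = run_allhuman(acetaminophen, 1, rulebase)
        phases = {bt.rule_id.split("_")[0] for bt in graph.edges}
        assert "p1" in phases and "p2" in phases

    def test_no_applicable_rules_root_only(self, rulebase):
        methane = parse_structure("C")
        graph = run_superbio(methane, rulebase)
        assert len(graph) == 1 and graph.metabolite_keys == set()

    def test_superbio_early_stop_on_two_rule_chain(self, rulebase):
        """nitrobenzene -> aniline -> acetanilide exhausts a 2-rule
        knowledgebase before the fourth iteration."""
        chain = Rulebase(
            [rulebase.get("gut_nitroreduction"), rulebase.get("p2_n_acetylation_arylamine")]
        )
        nitrobenzene = parse_structure("O=[N+]([O-])c1ccccc1")
        graph = run_superbio(nitrobenzene, chain)
        assert max(bt.iteration for bt in graph.edges) == 2  # frontier empty before 4
        products = {graph.nodes[k].molecule.structure for k in graph.metabolite_keys}
        assert products == {"Nc1ccccc1", "CC(=O)Nc1ccccc1"}

    def test_superbio_at_least_allhuman_n1(self, acetaminophen, rulebase, guard):
        sb = run_superbio(acetaminophen, rulebase, guard=guard)
        ah = run_allhuman(acetaminophen, 1, rulebase, guard=guard)
        assert len(sb) >= len(ah)


class TestMultiBio:
    def test_sequence_bounds(self):
        with pytest.raises(ConfigurationError):
            TransformationSequence(steps=tuple([(Phase.PHASE2, 1)] * 5))
        with pytest.raises(ConfigurationError):
            TransformationSequence(steps=((Phase.PHASE2, 4),))
        with pytest.raises(ConfigurationError):
            TransformationSequence(steps=())

    def test_single_step_equals_run_iterations(self, phenol, rulebase):
        seq = TransformationSequence(steps=((Phase.PHASE2, 1),))
        multi = run_multibio(phenol, seq, rulebase)
        single = run_iterations(phenol, ModuleConfig(phase=Phase.PHASE2), 1, rulebase)
        assert set(multi.nodes) == set(single.nodes)

    def test_worked_plan_shape(self, acetaminophen, rulebase, guard):
        """CYP450 x2, then gut x1, then phase II x1: step indices stamp
        every edge and respect the plan order."""
        seq = TransformationSequence(
            steps=((Phase.PHASE1_CYP, 2), (Phase.GUT_MICROBIAL, 1), (Phase.PHASE2, 1))
        )
        graph = run_multibio(acetaminophen, seq, rulebase, guard=guard)
        steps_seen = {bt.step_index for bt in graph.edges}
        assert steps_seen <= {1, 2, 3} and 1 in steps_seen and 3 in steps_seen
        for bt in graph.edges:
            phase = rulebase.get(bt.rule_id).phase
            assert phase is seq.steps[bt.step_index - 1][0]


class TestGuard:
    def test_keep_inside_envelopes(self, acetaminophen, guard):
        assert (
            plausibility_guard(acetaminophen, acetaminophen, Biosystem.HUMAN, guard)
            is GuardDecision.KEEP
        )

    def test_mass_violation_aborts(self, tight_guard, acetaminophen, rulebase):
        from biotx.rule_engine import apply_rule

        gluc = apply_rule(acetaminophen, rulebase.get("p2_o_glucuronidation_aromatic"))[0]
        assert (
            plausibility_guard(gluc.products[0], acetaminophen, Biosystem.HUMAN, tight_guard)
            is GuardDecision.ABORT
        )

    def test_guard_never_adds_nodes(self, panel, rulebase, guard):
        config = ModuleConfig(phase=Phase.PHASE2)
        for mol in panel[:12]:
            guarded = run_iterations(mol, config, 1, rulebase, guard=guard)
            unguarded = run_iterations(mol, config, 1, rulebase)
            assert set(guarded.nodes) <= set(unguarded.nodes), mol.structure

    def test_aborted_edge_leaves_precursor_terminal(self, acetaminophen, rulebase, tight_guard):
        graph = run_iterations(
            acetaminophen, ModuleConfig(phase=Phase.PHASE2), 1, rulebase, guard=tight_guard
        )
        # every phase II conjugate exceeds 200 Da, so nothing is admitted
        assert set(graph.nodes) == {acetaminophen.identity_key}
        assert graph.edges == []

    def test_environment_products_not_screened(self, guard):
        big = parse_structure("C" * 60)
        assert (
            plausibility_guard(big, big, Biosystem.ENVIRONMENT, guard) is GuardDecision.KEEP
        )


class TestDepolymerize:
    def test_dipeptide_hydrolyzed_to_amino_acids(self):
        gly_ala = parse_structure("NCC(=O)NC(C)C(=O)O")
        frags = {m.structure for m in depolymerize(gly_ala)}
        assert frags == {"NCC(=O)O", "CC(N)C(=O)O"}

    def test_phenolic_glycoside_split(self):
        salicin = parse_structure("OCC1OC(Oc2ccccc2CO)C(O)C(O)C1O")
        frags = {m.structure for m in depolymerize(salicin)}
        assert "OCC1OC(O)C(O)C(O)C1O" in frags  # glucose
        assert "OCc1ccccc1O" in frags  # salicyl alcohol

    def test_simple_amide_passes_through(self, acetaminophen):
        assert [m.identity_key for m in depolymerize(acetaminophen)] == [
            acetaminophen.identity_key
        ]

    def test_oversized_peptide_passes_through(self):
        octaglycine = parse_structure("NCC(=O)" + "NCC(=O)" * 7 + "O")
        assert len(depolymerize(octaglycine, max_residues=6)) == 1

    def test_tripeptide_full_hydrolysis(self):
        gly_gly_gly = parse_structure("NCC(=O)NCC(=O)NCC(=O)O")
        frags = depolymerize(gly_gly_gly)
        assert [m.structure for m in frags] == ["NCC(=O)O"]
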