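"""The packaged CD8+ T-cell network: registry, presets, deviations."""

import pytest

from cd8net.cd8 import (
    ALIASES,
    DEVIATIONS,
    INPUT_ORDER,
    NODE_ORDER,
    RECONCILED_RULES,
    VERBATIM_RULES,
    build_cd8_network,
    calibration_suite,
    deviations_manifest,
    make_scenario,
    stat6_null_scenario,
)


class TestRegistry:
    @pytest.mark.parametrize("variant", ["verbatim", "reconciled"])
    def test_eighteen_regulated_nodes(self, variant):
        net = build_cd8_network(variant)
        assert net.n == 18
        assert set(net.names) == set(NODE_ORDER)

    def test_input_registry_covers_every_rule_leaf(self, cd8_reconciled):
        vocab = set(cd8_reconciled.names) | set(cd8_reconciled.input_nodes)
        for spec in cd8_reconciled.internal_nodes:
            assert spec.rule.leaves() <= vocab
        # right-hand-side-only signals are declared as inputs
        assert {"IL2s", "IL15s", "PD1", "aa", "GFs"} <= set(INPUT_ORDER)

    def test_ros_rule_leaves(self, cd8_reconciled):
        ros = dict(zip(cd8_reconciled.names, cd8_reconciled.internal_nodes))["ROS"]
        assert ros.rule.leaves() == {"Glucose", "FFAs", "Ceramide", "EtOH", "SOD"}

    def test_mtorc2_rule_leaves(self, cd8_reconciled):
        node = dict(zip(cd8_reconciled.names, cd8_reconciled.internal_nodes))["mTORC2"]
        assert node.rule.leaves() == {"GFs", "ROS", "mTORC1"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_cd8_network("fancy")


class TestScenarios:
    def test_diabetic_preset_combines_three_stressors(self):
        scen = make_scenario("diabetic")
        assert scen.input_clamps["Glucose"] == 1
        assert scen.input_clamps["FFAs"] == 1
        assert scen.input_clamps["Ceramide"] == 1
        assert scen.input_clamps["EtOH"] == 0

    def test_inflammatory_preset_runs_with_il15_and_pd1(self):
        scen = make_scenario("il12_ifng")
        assert scen.input_clamps["IL12s"] == 1
        assert scen.input_clamps["IFNgs"] == 1
        assert scen.input_clamps["IL15s"] == 1
        assert scen.input_clamps["PD1"] == 1
        assert scen.input_clamps["IL4s"] == 0

    def test_il15_deprivation_override(self):
        scen = make_scenario("il12_ifng", {"IL15s": 0})
        assert scen.input_clamps["IL15s"] == 0

    def test_every_preset_clamps_every_input(self, cd8_reconciled):
        for preset in ("no_cytokines", "il12_ifng", "il6_tgfb", "il4_il12", "il4",
                       "diabetic", "hyperglycemia", "dyslipidemia", "ceramide", "ethanol"):
            make_scenario(preset).validate(cd8_reconciled)

    def test_unknown_preset_and_input_are_named(self):
        with pytest.raises(ValueError, match="nope"):
            make_scenario("nope")
        with pytest.raises(ValueError, match="Bogus"):
            make_scenario("il4", {"Bogus": 1})

    def test_stat6_null_clamps_stat6_responsive_nodes(self):
        base = make_scenario("il4")
        null = stat6_null_scenario(base)
        assert null.perturbations == {"GATA3": 0, "IL4": 0, "IL10": 0}
        assert null.input_clamps["IL4s"] == 1  # the cytokine is still present

    def test_stat6_null_is_idempotent(self):
        once = stat6_null_scenario(make_scenario("il4"))
        twice = stat6_null_scenario(once)
        assert once.perturbations == twice.perturbations


class TestDeviations:
    def test_every_reconciled_override_is_documented(self):
        documented = {d.node for d in DEVIATIONS if d.applies_to == "reconciled"}
        assert set(RECONCILED_RULES) == documented

    def test_verbatim_manifest_is_a_subset(self):
        verbatim = deviations_manifest("verbatim")
        reconciled = deviations_manifest("reconciled")
        assert len(verbatim) < len(reconciled)
        assert all(d.applies_to == "both" for d in verbatim)

    def test_variants_differ_exactly_on_the_overridden_rows(self, cd8_verbatim, cd8_reconciled):
        differing = set()
        for name, verbatim_spec, reconciled_spec in zip(
            cd8_verbatim.names, cd8_verbatim.internal_nodes, cd8_reconciled.internal_nodes
        ):
            if str(verbatim_spec.rule) != str(reconciled_spec.rule):
                differing.add(name)
        assert differing == set(RECONCILED_RULES)

    def test_damaged_rows_auto_close_under_verbatim_parse(self):
        # five printed rows are truncated; parsing them must log repairs
        from cd8net.expr import parse_rule

        vocab = set(NODE_ORDER) | set(INPUT_ORDER)
        damaged = ("GATA3", "IL4", "RORgT", "FOXP3", "EOMES")
        for name in damaged:
            repairs = []
            parse_rule(VERBATIM_RULES[name], vocab, aliases=ALIASES,
                       on_repair=repairs.append)
            assert repairs, f"expected a repair for the {name} row"


class TestCalibrationSuite:
    def test_thirteen_assertions_with_provenance(self):
        suite = calibration_suite()
        assert len(suite) == 13
        assert all(a.provenance for a in suite)
        assert all(a.cells for a in suite)

    def test_assertions_reference_buildable_cells(self, cd8_reconciled):
        for assertion in calibration_suite():
            for cell in assertion.cells:
                cell.scenario().validate(cd8_reconciled)

    def test_expected_assertions_present(self):
        names = {a.name for a in calibration_suite()}
        assert {"tcreg_il4_il12", "tcreg_resistant", "metabolic_module_rescue"} <= names
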