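"""Campaigns: structure, reproducibility, cross-campaign consistency."""

import json

import pytest

from cd8net.cd8 import calibration_suite
from cd8net.experiments import (
    _CAMPAIGN_ASSERTIONS,
    PERTURBATION_TARGETS,
    VALIDATION_CELLS,
    run_metabolic_screen,
    run_perturbation_screen,
    run_validation_panel,
)


@pytest.fixture(scope="module")
def validation():
    return run_validation_panel("synchronous")


@pytest.fixture(scope="module")
def metabolic():
    return run_metabolic_screen("synchronous")


@pytest.fixture(scope="module")
def knockout():
    return run_perturbation_screen("knockout")


class TestValidationPanel:
    def test_all_ten_cells_present(self, validation):
        assert set(validation.tables) == {c.label for c in VALIDATION_CELLS}

    def test_ten_assertions_evaluated(self, validation):
        assert len(validation.verdicts) == 10

    def test_inflammatory_polarization_reproduced(self, validation):
        verdicts = {v.name: v.passed for v in validation.verdicts}
        assert verdicts["tc1_vs_tc17_inflammatory"]
        assert verdicts["tcreg_il4_il12"]
        assert verdicts["tc2_il4"]

    def test_memory_depends_on_il15_and_pd1(self, validation):
        verdicts = {v.name: v.passed for v in validation.verdicts}
        assert verdicts["il15_memory"]
        assert verdicts["pd1_memory"]
        base = validation.tables["il12_ifng"]
        assert base.memory_fraction > 0
        assert validation.tables["il12_ifng+IL15s=0"].memory_fraction == 0

    def test_inflammatory_cells_fully_converge(self, validation):
        for label in ("il12_ifng", "il4_il12", "il4",
                      "il12_ifng+IL15s=0", "il12_ifng+PD1=0"):
            assert validation.convergence[label] == 100.0


class TestMetabolicScreen:
    def test_grid_covers_stressors_by_presets(self, metabolic):
        # 5 baselines + 5 stressors x 5 polarizing presets
        assert len(metabolic.tables) == 30

    def test_deltas_are_against_stress_free_baseline(self, metabolic):
        delta = metabolic.deltas["il12_ifng+diabetic"]
        base = metabolic.tables["il12_ifng"]
        stressed = metabolic.tables["il12_ifng+diabetic"]
        assert delta["Tc1"] == stressed.freq("Tc1") - base.freq("Tc1")

    def test_diabetic_context_abolishes_tc1(self, metabolic):
        assert metabolic.tables["il12_ifng+diabetic"].freq("Tc1") == 0.0
        assert metabolic.tables["il12_ifng"].freq("Tc1") > 0.0

    def test_tcreg_untouched_by_every_stressor(self, metabolic):
        base = metabolic.tables["il4_il12"].freq("TcReg")
        for stressor in ("hyperglycemia", "dyslipidemia", "ceramide",
                         "ethanol", "diabetic"):
            assert metabolic.tables[f"il4_il12+{stressor}"].freq("TcReg") == base

    def test_dyslipidemia_reduces_granzymeB_tc1(self, metabolic):
        assert (metabolic.extras["granzymeB_tc1_dyslipidemia"]
                < metabolic.extras["granzymeB_tc1_baseline"])


class TestPerturbationScreens:
    def test_targets_and_summary(self, knockout):
        assert set(knockout.summary_change) == set(PERTURBATION_TARGETS)
        assert all(v >= 0 for v in knockout.summary_change.values())

    def test_unknown_direction_and_target_rejected(self):
        with pytest.raises(ValueError):
            run_perturbation_screen("overexpress")
        with pytest.raises(ValueError, match="NOX2"):
            run_perturbation_screen("knockout", targets=("NOX2",))

    def test_ros_knockout_restores_tc1_in_diabetic_context(self, knockout):
        base = knockout.tables["il12_ifng+diabetic"]
        rescued = knockout.tables["il12_ifng+diabetic+ROS_ko"]
        assert rescued.freq("Tc1") > base.freq("Tc1")

    def test_mtorc2_knockout_abolishes_inflammatory_effectors(self, knockout):
        # The knockout forces FOXO1 on in the PD-1/IL-15-licensed context,
        # which shuts T-BET and with it the whole Tc1 programme.
        table = knockout.tables["il12_ifng+diabetic+mTORC2_ko"]
        assert table.freq("Tc1") == 0.0
        assert table.memory_fraction > 0.0  # the mass moves into FOXO1+ states

    def test_baseline_embedding_across_campaigns(self, knockout, metabolic):
        """The unperturbed diabetic cells of the screen equal the metabolic
        screen's diabetic cells exactly (same integer basin counts)."""
        for preset in ("il12_ifng", "il4", "il6_tgfb", "no_cytokines", "il4_il12"):
            label = f"{preset}+diabetic"
            assert (knockout.tables[label].lineage_counts
                    == metabolic.tables[label].lineage_counts)

    def test_reproducibility_byte_identical_reports(self, tmp_path):
        r1 = run_perturbation_screen("knockin", targets=("mTORC2",))
        r2 = run_perturbation_screen("knockin", targets=("mTORC2",))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        r1.write(d1)
        r2.write(d2)
        f1 = (d1 / "knockin_synchronous_reconciled.json").read_bytes()
        f2 = (d2 / "knockin_synchronous_reconciled.json").read_bytes()
        assert f1 == f2


def test_every_calibration_assertion_is_covered_by_a_campaign():
    covered = set()
    for names in _CAMPAIGN_ASSERTIONS.values():
        covered.update(names)
    assert covered == {a.name for a in calibration_suite()}


def test_campaign_report_writes_all_formats(tmp_path, knockout):
    knockout.write(tmp_path)
    stem = "knockout_synchronous_reconciled"
    assert (tmp_path / f"{stem}.json").exists()
    assert (tmp_path / f"{stem}.csv").exists()
    md = (tmp_path / f"{stem}.md").read_text()
    assert "Assertion verdicts" in md
    payload = json.loads((tmp_path / f"{stem}.json").read_text())
    assert payload["campaign"] == "knockout"
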