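"""Phenotype classification and basin-weighted frequencies."""

import itertools

import pytest

from cd8net.cd8 import CellSpec
from cd8net.network import Attractor
from cd8net.phenotypes import (
    FrequencyTable,
    LINEAGE_LABELS,
    classify_attractor,
    classify_state,
    default_phenotype_rules,
    frequency_delta,
    phenotype_frequencies,
)

RULES = default_phenotype_rules()
MARKERS = ("EOMES", "TBET", "IFNg", "GATA3", "IL4", "RORgT", "FOXP3", "IL10", "FOXO1")


def _state(**on):
    state = {m: 0 for m in MARKERS}
    state.update(on)
    return state


class TestClassifyState:
    def test_tc1_effector(self):
        call = classify_state(_state(EOMES=1, TBET=1, IFNg=1), RULES)
        assert call.lineage == "Tc1" and call.stage == "Effector"

    def test_all_masters_off_is_naive_tc0(self):
        call = classify_state(_state(), RULES)
        assert call.stage == "Naive" and call.lineage == "Tc0"

    def test_foxo1_with_eomes_and_master_is_memory(self):
        call = classify_state(_state(FOXO1=1, EOMES=1, TBET=1), RULES)
        assert call.stage == "Memory"
        assert call.lineage == "unclassified"  # strict axis requires FOXO1 off
        assert call.memory_lineage == "Tc1"  # master-regulator identity

    def test_tcreg_requires_foxp3_with_il10(self):
        call = classify_state(_state(EOMES=1, FOXP3=1, IL10=1), RULES)
        assert call.lineage == "TcReg"
        call = classify_state(_state(EOMES=1, FOXP3=1), RULES)
        assert call.lineage == "unclassified"

    def test_master_on_without_eomes_matches_nothing(self):
        call = classify_state(_state(TBET=1, IFNg=1), RULES)
        assert call.stage == "none" and call.lineage == "unclassified"
        assert not call.classified

    def test_lineage_identifiers_are_pairwise_exclusive(self):
        """Exhaustive over all marker combinations: no state matches two of
        Tc1/Tc2/Tc17/TcReg (each requires a master the others negate)."""
        tc = ("Tc1", "Tc2", "Tc17", "TcReg")
        for bits in itertools.product((0, 1), repeat=len(MARKERS)):
            state = dict(zip(MARKERS, bits))
            matches = [label for label in tc if RULES[label].matches(state)]
            assert len(matches) <= 1, (state, matches)

    def test_naive_and_tc0_identifiers_coincide(self):
        for bits in itertools.product((0, 1), repeat=len(MARKERS)):
            state = dict(zip(MARKERS, bits))
            assert RULES["Naive"].matches(state) == RULES["Tc0"].matches(state)


class TestClassifyAttractor:
    def test_cycles_are_unclassified(self, cd8_reconciled):
        cyc = Attractor("cycle", ((0,) * 18, (1,) + (0,) * 17), basin_size=2)
        call = classify_attractor(cyc, RULES, cd8_reconciled.names)
        assert call.stage == "none" and call.lineage == "unclassified"

    def test_granzyme_flag_reported(self, cd8_reconciled):
        bits = {n: 0 for n in cd8_reconciled.names}
        bits.update(EOMES=1, TBET=1, IFNg=1, GranzymeB=1)
        fp = Attractor("fixed_point",
                       (tuple(bits[n] for n in cd8_reconciled.names),), basin_size=1)
        call = classify_attractor(fp, RULES, cd8_reconciled.names)
        assert call.lineage == "Tc1" and "GranzymeB_positive" in call.flags


class TestFrequencies:
    def test_arithmetic_of_the_definition(self):
        table = FrequencyTable(
            omega=4,
            lineage_counts={"Tc0": 2, "Tc1": 2, "Tc2": 0, "Tc17": 0,
                            "TcReg": 0, "unclassified": 0},
            stage_counts={"Naive": 2, "Effector": 2, "Memory": 0, "none": 0},
            classified_count=4, cyclic_count=0,
        )
        assert table.freq("Tc0") == 50.0 and table.freq("Tc1") == 50.0
        assert table.classified_fraction == 100.0

    def test_single_attractor_owns_everything(self, cells):
        # fully clamped scenario: one fixed point, basin 2^18
        cell = CellSpec("all_clamped", "no_cytokines",
                        perturbations={n: 0 for n in cells.network.names})
        table = cells.table(cell)
        assert table.freq("Tc0") == 100.0
        assert sum(table.lineage_counts.values()) == table.omega

    def test_lineage_partition_on_real_atlases(self, cells):
        for preset in ("il4", "il12_ifng", "il6_tgfb"):
            table = cells.table(CellSpec(preset, preset))
            assert sum(table.lineage_counts.values()) == table.omega
            assert all(0.0 <= table.freq(l) <= 100.0 for l in LINEAGE_LABELS)

    def test_il4_polarization_fully_classified(self, cells):
        table = cells.table(CellSpec("il4", "il4"))
        assert table.classified_fraction == 100.0
        assert table.modal_lineage() == "Tc2"

    def test_counts_are_exact_integers(self, cells):
        table = cells.table(CellSpec("il4_il12", "il4_il12"))
        assert all(isinstance(v, int) for v in table.lineage_counts.values())
        assert table.freq("TcReg") == 100.0 * table.lineage_counts["TcReg"] / table.omega


class TestDelta:
    def _table(self, tc1):
        counts = {"Tc0": 0, "Tc1": tc1, "Tc2": 0, "Tc17": 0, "TcReg": 0,
                  "unclassified": 100 - tc1}
        return FrequencyTable(100, counts,
                              {"Naive": 0, "Effector": tc1, "Memory": 0,
                               "none": 100 - tc1}, tc1, 0)

    def test_identical_tables_give_zeros(self):
        t = self._table(40)
        assert all(v == 0.0 for v in frequency_delta(t, t).values())

    def test_signed_difference(self):
        assert frequency_delta(self._table(100), self._table(0))["Tc1"] == 100.0

    def test_mismatched_tables_rejected(self):
        other = FrequencyTable(200, {l: 0 for l in (*LINEAGE_LABELS, "unclassified")},
                               {"Naive": 0, "Effector": 0, "Memory": 0, "none": 0}, 0, 0)
        with pytest.raises(ValueError):
            frequency_delta(self._table(1), other)
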