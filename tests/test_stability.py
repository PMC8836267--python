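"""Stability screen: ΔΔG engine, standardization, foldability, reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import melanostab as ms
from melanostab.mutation import AA_ALPHABET
from melanostab.stability import (
    GAS_CONSTANT_KCAL,
    ScreenConfig,
    StabilityRecord,
    WildTypeMismatchError,
    foldability_from_records,
)
from melanostab.structure import Atom, Residue, Structure


def two_state(ddg: float, temperature: float = 298.15) -> float:
    """Independent closed-form oracle for the standardization transform."""
    return 1.0 / (1.0 + math.exp(-ddg / (GAS_CONSTANT_KCAL * temperature)))


class TestDdgEstimate:
    def test_identity_substitution_is_zero(self, oca8_mini):
        assert ms.ddg_estimate(oca8_mini, ms.MutationSpec(40, "C", "C")) == 0.0

    def test_bridge_cys_gets_the_disulfide_loss_floor(self, oca8_mini):
        ddg = ms.ddg_estimate(oca8_mini, ms.MutationSpec.from_string("C40S"))
        assert ddg >= 4.0

    def test_isolated_residue_has_no_environment_terms(self):
        lone = Structure([Residue("A", 1, "ALA", atoms=[
            Atom("N", "N", [0, 1.4, 0], 1), Atom("CA", "C", [0, 0, 0], 2),
            Atom("C", "C", [1.4, 0, 0], 3), Atom("CB", "C", [-1, -1, 0], 4)])])
        ddg = ms.ddg_estimate(lone, ms.MutationSpec.from_string("A1S"))
        assert abs(ddg) <= 0.5

    def test_wild_type_mismatch_raises(self, oca8_mini):
        with pytest.raises(WildTypeMismatchError):
            ms.ddg_estimate(oca8_mini, ms.MutationSpec.from_string("C10S"))

    def test_table_engine_returns_imported_values(self, oca8_mini):
        config = ScreenConfig(engine="table",
                              ddg_table={"C40S": 2.75, "G59V": 77.6})
        assert ms.ddg_estimate(oca8_mini, ms.MutationSpec.from_string("C40S"),
                               config=config) == 2.75
        with pytest.raises(KeyError):
            ms.ddg_estimate(oca8_mini, ms.MutationSpec.from_string("C40W"),
                            config=config)


class TestUnfoldingFraction:
    @pytest.mark.parametrize("ddg,expected,tol", [
        (0.0, 0.5, 1e-12),          # two-state symmetry point
        (6.01, 0.9999607, 1e-6),    # printed C61W ΔΔG maps above 0.99
        (-5.0, 2.2e-4, 2e-5),
    ])
    def test_known_values(self, ddg, expected, tol):
        assert ms.unfolding_fraction(ddg) == pytest.approx(expected, abs=tol)

    def test_extreme_ddg_saturates_to_one_at_two_decimals(self):
        assert round(ms.unfolding_fraction(77.6), 2) == 1.00

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert ms.unfolding_fraction(lo) <= ms.unfolding_fraction(hi)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-80, 80))
    def test_two_state_symmetry(self, x):
        assert ms.unfolding_fraction(x) + ms.unfolding_fraction(-x) \
            == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        for ddg in (-3.0, 0.7, 2.75, 6.01, 12.0):
            assert ms.unfolding_fraction(ddg) == pytest.approx(two_state(ddg),
                                                               rel=1e-12)


class TestFoldability:
    def test_ceiling_is_nineteen(self):
        records = [StabilityRecord(ms.MutationSpec(40, "C", m), ddg=77.6,
                                   unfolding=1.0, weight=1.0)
                   for m in AA_ALPHABET if m != "C"]
        assert foldability_from_records(records) == 19.0

    def test_ddg_zero_gives_nine_point_five(self):
        records = [StabilityRecord(ms.MutationSpec(1, "A", m), ddg=0.0,
                                   unfolding=ms.unfolding_fraction(0.0), weight=1.0)
                   for m in AA_ALPHABET if m != "A"]
        assert foldability_from_records(records) == pytest.approx(19 * 0.5)

    def test_zero_weights_give_zero(self, oca8_mini):
        config = ScreenConfig(weights={m: 0.0 for m in AA_ALPHABET})
        assert ms.foldability(oca8_mini, 40, config) == 0.0

    def test_equals_brute_force_enumeration(self, oca8_mini):
        """Foldability matches an explicit 19-substitution sum oracle."""
        bridges = ms.detect_disulfides(oca8_mini)
        expected = 0.0
        count = 0
        for mut in AA_ALPHABET:
            if mut == "C":
                continue
            ddg = ms.ddg_estimate(oca8_mini, ms.MutationSpec(40, "C", mut),
                                  bridges=bridges)
            expected += two_state(ddg)
            count += 1
        assert count == 19
        assert ms.foldability(oca8_mini, 40) == pytest.approx(expected, abs=1e-12)

    def test_het_position_is_a_domain_error(self, zinc_site):
        with pytest.raises(ValueError, match="not a standard"):
            ms.foldability(zinc_site, 600)


class TestScreenAll:
    def test_criticality_recovery_on_the_cys_fixture(self, tyrp2_screen):
        """All and only the engineered bridge cysteines are flagged critical."""
        engineered = sorted({p for pair in ms.TYRP2_DISULFIDE_PAIRS for p in pair})
        assert tyrp2_screen.critical_residues() == engineered

    def test_bridge_cys_outrank_other_residues(self, tyrp2_screen):
        frame = tyrp2_screen.to_frame()
        cys = frame[frame["name"] == "CYS"]["foldability"]
        rest = frame[frame["name"] != "CYS"]["foldability"]
        assert cys.median() > rest.median()

    def test_surface_gly_ala_fixture_has_no_critical_residues(self):
        structure = ms.make_cys_fixture(
            ms.FixtureSpec(n_residues=5, sequence="GAGAG"))
        fmap = ms.screen_all(structure)
        assert fmap.critical_residues() == []

    def test_single_residue_structure_yields_one_entry(self):
        structure = ms.make_cys_fixture(ms.FixtureSpec(n_residues=1, sequence="A"))
        assert len(ms.screen_all(structure)) == 1

    def test_empty_structure_is_an_error(self, zinc_site):
        bare = ms.Structure([r for r in zinc_site.residues if not r.is_amino])
        with pytest.raises(ValueError):
            ms.screen_all(bare)

    def test_permutation_invariance(self, oca8_mini):
        """Renaming the chain and reversing residue order changes nothing."""
        shuffled = oca8_mini.copy()
        for res in shuffled.residues:
            res.chain = "B"
        shuffled.residues = list(reversed(shuffled.residues))
        assert ms.foldability(shuffled, 40) == pytest.approx(
            ms.foldability(oca8_mini, 40), abs=1e-12)


class TestReportTable:
    def test_oca8_rows(self, tyrp2_fixture, tyrp2_screen):
        specs = [ms.MutationSpec.from_string(m) for m in ("C40S", "C61W")]
        table = ms.report_table(tyrp2_screen, specs)
        assert list(table["mutation"]) == ["C40S", "C61W"]
        row = table.iloc[0]
        assert row["ddg_kcal_mol"] >= 4.0
        assert row["unfolding_fraction"] > 0.99
        assert row["foldability"] >= tyrp2_screen.config.critical_threshold
        assert tyrp2_screen.entry(40).critical

    def test_non_bridge_mutation_lacks_the_bridge_loss_term(self, oca8_mini):
        fmap = ms.screen_all(oca8_mini)
        table = ms.report_table(fmap, [ms.MutationSpec.from_string("G59V")])
        assert len(table) == 1
        assert table.iloc[0]["ddg_kcal_mol"] < 4.0

    def test_empty_request_gives_header_only(self, tyrp2_screen):
        table = ms.report_table(tyrp2_screen, [])
        assert len(table) == 0
        assert list(table.columns) == [
            "mutation", "unfolding_fraction", "foldability", "ddg_kcal_mol"]

    def test_unknown_mutation_is_a_key_error(self, tyrp2_screen):
        with pytest.raises(KeyError):
            ms.report_table(tyrp2_screen, [ms.MutationSpec.from_string("W9999A")])


class TestImportDdgTable:
    def test_reads_three_rows(self, tmp_path):
        path = tmp_path / "ddg.tsv"
        path.write_text("mutation\tddg\nC40S\t2.75\nG59V\t77.6\nC61W\t6.01\n")
        table = ms.import_ddg_table(path)
        assert table == {"C40S": 2.75, "G59V": 77.6, "C61W": 6.01}

    def test_empty_file_gives_empty_map(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert ms.import_ddg_table(path) == {}

    def test_non_numeric_ddg_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("C40S\tbanana\n")
        with pytest.raises(ValueError, match="not a number"):
            ms.import_ddg_table(path)

    def test_duplicate_mutation_is_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("C40S\t2.75\nC40S\t3.00\n")
        with pytest.raises(ValueError, match="duplicate"):
            ms.import_ddg_table(path)
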