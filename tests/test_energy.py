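"""Interaction-energy ledger: formulas, fixture table, orderings, hydration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnastack import (
    ComponentLedger,
    EnergyRecord,
    RecordSet,
    counterpoise_correct,
    delta_bind,
    delta_hoogsteen,
    delta_int,
    delta_pair,
    delta_stack,
    delta_tetrad,
    duplex_ledger,
    hydration_model,
    ion_binding,
    per_bond,
    quadruplex_ledger,
    rank_stability,
    round_half_away,
    third_base_stack,
)
from dnastack.qm import mock_records_for_pair

finite = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)


def _simple_records(energies: dict) -> RecordSet:
    rs = RecordSet()
    for sid, e in energies.items():
        rs.add(
            EnergyRecord(
                fragments=((sid, False),),
                basis_context=sid,
                geometry_context=sid,
                phase="water",
                energy=e,
            )
        )
    return rs


class TestDeltaBind:
    def test_direct_arithmetic(self):
        rs = _simple_records({"AB": -10.0, "A": -4.0, "B": -4.0})
        assert delta_bind(rs, "AB", ["A", "B"]) == pytest.approx(-2.0)

    def test_non_interacting_limit_is_zero(self):
        rs = _simple_records({"AB": -8.0, "A": -4.0, "B": -4.0})
        assert delta_bind(rs, "AB", ["A", "B"]) == pytest.approx(0.0)

    def test_missing_record_raises(self):
        rs = _simple_records({"AB": -8.0, "A": -4.0})
        with pytest.raises(KeyError):
            delta_bind(rs, "AB", ["A", "B"])

    def test_planted_pair_value_recovered_through_mock(self):
        rs = mock_records_for_pair("G-C", -11.45)
        assert delta_pair(rs, "G-C") == pytest.approx(-11.45)


class TestCounterpoise:
    def test_no_superposition_means_no_correction(self):
        rs = mock_records_for_pair("A-T", -6.80)
        corr, bsse = counterpoise_correct(rs, ["A-T:A", "A-T:T"])
        assert corr == pytest.approx(-6.80)
        assert all(abs(v) < 1e-12 for v in bsse.values())

    def test_printed_formula_substitution(self):
        rs = mock_records_for_pair("G-C", -10.0 + 0.8 + 0.7, bsse={"G-C:G": -0.8, "G-C:C": -0.7})
        # raw binding = planted + sum(bsse) = -10.0; corrected removes BSSE
        raw = delta_bind(rs, ("G-C:C", "G-C:G"), ["G-C:G", "G-C:C"])
        corr, _ = counterpoise_correct(rs, ["G-C:G", "G-C:C"])
        assert raw == pytest.approx(-10.0)
        assert corr == pytest.approx(-8.5)

    @settings(max_examples=50, deadline=None)
    @given(de=finite, b1=st.floats(-3, 0), b2=st.floats(-3, 0))
    def test_correction_identity_on_random_ledgers(self, de, b1, b2):
        rs = mock_records_for_pair("X-Y", de, bsse={"X-Y:X": b1, "X-Y:Y": b2})
        raw = delta_bind(rs, ("X-Y:X", "X-Y:Y"), ["X-Y:X", "X-Y:Y"])
        corr, bsse = counterpoise_correct(rs, ["X-Y:X", "X-Y:Y"])
        assert corr - raw == pytest.approx(-(bsse["X-Y:X"] + bsse["X-Y:Y"]), abs=1e-9)

    def test_missing_ghost_record_raises(self):
        rs = _simple_records({"A": -1.0, "B": -1.0})
        with pytest.raises(KeyError):
            counterpoise_correct(rs, ["A", "B"])


class TestFixtureComponents:
    def test_pairing_energies(self, fixture_table):
        assert delta_pair(fixture_table, "G-C") == pytest.approx(-11.45)
        assert delta_hoogsteen(fixture_table, "C+.G") == pytest.approx(-11.04)
        with pytest.raises(KeyError):
            delta_pair(fixture_table, "Z-Z")

    def test_tetrad_identity(self, fixture_table):
        total, ionic = delta_tetrad(fixture_table, "G4_Li")
        assert (total, ionic) == (pytest.approx(-31.28), pytest.approx(-7.82))
        total, ionic = delta_tetrad(fixture_table, "G4_Na")
        assert (total, ionic) == (pytest.approx(-27.68), pytest.approx(-6.92))
        assert total / ionic == pytest.approx(4.0)

    def test_stacking_energies(self, fixture_table):
        assert delta_stack(fixture_table, "G-C/C-G") == pytest.approx(-5.46)
        assert delta_stack(fixture_table, "G4/G4") == pytest.approx(-13.16)

    def test_per_bond_report_rounding(self):
        assert per_bond(-11.45, 3) == -3.82
        assert per_bond(-6.80, 2) == -3.40
        assert per_bond(-20.26, 4) == -5.07  # half rounds away from zero
        assert per_bond(-39.1, 8, ndigits=1) == -4.9
        with pytest.raises(ValueError):
            per_bond(-1.0, 0)

    def test_round_half_away_is_not_bankers(self):
        assert round_half_away(-3.385, 2) == -3.39
        assert round_half_away(2.5, 0) == 3.0

    def test_fixture_self_consistency(self, fixture_table):
        report = fixture_table.consistency_report()
        bad = report[~report.consistent & ~report.flagged]
        assert bad.empty
        flagged = report[report.flagged]
        assert list(flagged.structure_id) == ["G4_Li_G4"]


class TestThirdBaseStack:
    @pytest.mark.parametrize(
        "triplex,expected",
        [
            ("C+.G-C/T.A-T", -3.35),
            ("T.A-T/T.A-T", -2.15),
            ("A.A-T/A.A-T", -6.65),
        ],
    )
    def test_subtraction_against_core_duplex(self, fixture_table, triplex, expected):
        assert third_base_stack(fixture_table, triplex) == pytest.approx(expected, abs=1e-9)

    def test_identical_energies_cancel(self):
        rs = _simple_records(
            {"T.A-T/T.A-T": 0.0, "T.A-T/T.A-T:parts": 5.0, "A-T/A-T": 0.0, "A-T/A-T:parts": 5.0}
        )
        assert third_base_stack(rs, "T.A-T/T.A-T") == pytest.approx(0.0)

    def test_unmapped_triplex_raises(self, fixture_table):
        with pytest.raises(KeyError):
            third_base_stack(fixture_table, "X.X-X/X.X-X")


class TestDeltaInt:
    def test_empty_ledger_is_zero(self):
        assert delta_int(ComponentLedger()) == 0.0

    def test_duplex_sum_from_fixture(self, fixture_table):
        led = duplex_ledger(fixture_table, "G-C/C-G")
        assert delta_int(led) == pytest.approx(2 * -11.45 + -5.46)

    def test_quadruplex_aggregate_reaches_minus_106_3(self, fixture_table):
        led = quadruplex_ledger(fixture_table, "Na+", in_plane=False)
        assert round_half_away(delta_int(led), 1) == pytest.approx(-106.3)

    @settings(max_examples=50, deadline=None)
    @given(
        pairs=st.lists(finite, max_size=4),
        hoog=st.lists(finite, max_size=2),
        ionic=st.lists(finite, max_size=2),
        stack=finite,
    )
    def test_ledger_additivity(self, pairs, hoog, ionic, stack):
        led = ComponentLedger(
            pair_terms={f"p{i}": v for i, v in enumerate(pairs)},
            hoogsteen_terms={f"h{i}": v for i, v in enumerate(hoog)},
            ionic_terms={f"i{i}": v for i, v in enumerate(ionic)},
            stack_term=stack,
        )
        assert delta_int(led) == pytest.approx(
            sum(pairs) + sum(hoog) + sum(ionic) + stack, abs=1e-9
        )


class TestHydration:
    def test_equal_energies_cancel(self):
        m = ion_binding(-30.0, hydration_model("Na+", hydration_energy=-30.0))
        assert m.ion_binding_energy == pytest.approx(0.0)

    def test_plain_arithmetic(self):
        m = ion_binding(-37.0, hydration_model("K+", hydration_energy=-34.0))
        assert m.ion_binding_energy == pytest.approx(-3.0)

    def test_lithium_flips_positive_when_overhydrated(self, fixture_table):
        sum_li = fixture_table.total("G4_Li_G4")
        m = ion_binding(sum_li, hydration_model("Li+", hydration_energy=sum_li - 5.0))
        assert m.ion_binding_energy > 0

    def test_wrong_coordination_number_rejected(self):
        from dnastack import HydrationModel

        bad = HydrationModel(species="K+", coordination_number=4, hydration_energy=-30.0)
        with pytest.raises(ValueError):
            ion_binding(-37.0, bad)

    @settings(max_examples=50, deadline=None)
    @given(
        h_na=st.floats(-45.0, -20.0),
        gap=st.floats(2.11, 8.0),
        li_extra=st.floats(0.1, 15.0),
    )
    def test_potassium_ranks_first_given_printed_na_k_gap(
        self, fixture_table, h_na, gap, li_extra
    ):
        # any hydration energies with Li < Na < K and |Na - K| > 2.1 put K+ first
        h = {"Na+": h_na, "K+": h_na + gap, "Li+": h_na - li_extra}
        values = {
            sp: ion_binding(
                fixture_table.total(f"G4_{sp.rstrip('+')}_G4"),
                hydration_model(sp, hydration_energy=h[sp]),
            ).ion_binding_energy
            for sp in ("Li+", "Na+", "K+")
        }
        ranked = [e.name for e in rank_stability(values, tolerance=0.0)]
        assert ranked[0] == "K+"
        assert ranked.index("Na+") < ranked.index("Li+")


class TestRankStability:
    def test_pair_order_reproduces_nature(self, fixture_table):
        values = {sid: fixture_table.total(sid) for sid in fixture_table.ids("pair")}
        ranked = [e.name for e in rank_stability(values)]
        assert ranked[:3] == ["G-C", "A-T", "G-T"]

    def test_duplex_int_order_splits_at_at_from_at_ta(self, fixture_table):
        duplex_ids = ["G-C/C-G", "A-T/A-T", "G-C/A-T", "A-T/T-A", "G-C/G-C", "G-C/T-A"]
        values = {sid: delta_int(duplex_ledger(fixture_table, sid)) for sid in duplex_ids}
        ranked = [e.name for e in rank_stability(values)]
        assert ranked.index("A-T/A-T") < ranked.index("A-T/T-A")
        assert ranked[0] == "G-C/C-G"

    def test_single_entry(self):
        [entry] = rank_stability({"only": -1.0})
        assert entry.name == "only" and entry.tie_group == 0

    def test_close_values_share_a_tie_group(self):
        ranked = rank_stability({"a": -6.80, "b": -6.77, "c": -3.0}, tolerance=0.05)
        assert ranked[0].tie_group == ranked[1].tie_group != ranked[2].tie_group
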