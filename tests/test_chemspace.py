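import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxntriage.chemspace import (
    BUILTIN_RULES,
    AssemblySpecies,
    BuildingBlock,
    ChemspaceError,
    Formula,
    Role,
    RouteStage,
    adduct_mz,
    apply_transform,
    assembly_charge,
    build_lookup_table,
    enumerate_assemblies,
    enumerate_route,
    formula_mass,
    mz_series,
    parse_charged_formula,
)


class TestFormula:
    @pytest.mark.parametrize(
        "formula,mode,expected",
        [
            ("H2O", "monoisotopic", 18.0106),
            ("H", "monoisotopic", 1.00783),
            ("C3H5N", "monoisotopic", 55.0422),  # propargylamine
            ("C10H10N2O", "monoisotopic", 174.0793),  # phenyl urea of propargylamine
        ],
    )
    def test_monoisotopic_masses(self, formula, mode, expected):
        assert formula_mass(formula, mode) == pytest.approx(expected, abs=5e-5)

    def test_average_mass_exceeds_monoisotopic_for_chlorinated(self):
        # Cl is 76% 35Cl / 24% 37Cl, so the average sits well above monoisotopic
        assert formula_mass("CHCl3", "average") > formula_mass("CHCl3", "monoisotopic") + 0.3

    def test_empty_formula_rejected(self):
        with pytest.raises(ChemspaceError):
            Formula({})
        with pytest.raises(ChemspaceError):
            Formula("")

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ChemspaceError, match="Xx"):
            Formula({"Xx": 1})

    def test_parenthesized_groups_and_hill_roundtrip(self):
        f = Formula("Zn(CF3O3S)2")
        assert f.counts == {"Zn": 1, "C": 2, "F": 6, "O": 6, "S": 2}
        assert Formula(f.hill()) == f

    def test_charge_suffix_parsing(self):
        assert parse_charged_formula("Zn2+") == (Formula("Zn"), 2)
        assert parse_charged_formula("CF3O3S-") == (Formula("CF3O3S"), -1)
        assert parse_charged_formula("C6H5NO") == (Formula("C6H5NO"), 0)

    def test_arithmetic_and_negative_guard(self):
        assert Formula("CH4") + Formula("O") == Formula("CH4O")
        assert Formula("C2H6O") - Formula("H2O") == Formula("C2H4")
        with pytest.raises(ChemspaceError):
            Formula("CH4") - Formula("O")
        assert 3 * Formula("H2O") == Formula("H6O3")


class TestTransforms:
    def test_urea_condensation_product(self, divergent_blocks):
        product = apply_transform(
            BUILTIN_RULES["urea"], [divergent_blocks["1"], divergent_blocks["5"]]
        )
        assert product.formula == Formula("C10H10N2O")
        assert product.mass() == pytest.approx(174.0793, abs=5e-5)

    def test_imine_rule_loses_water_per_bond(self, supra_blocks):
        amine, pyr = supra_blocks["28"], supra_blocks["24"]
        total = amine.formula + 3 * pyr.formula
        product = apply_transform(
            BUILTIN_RULES["imine_condensation"], [amine, pyr, pyr, pyr]
        )
        assert product.formula == total - 3 * Formula("H2O")

    def test_addition_rules_conserve_formula(self, divergent_blocks):
        p1 = apply_transform(
            BUILTIN_RULES["urea"], [divergent_blocks["1"], divergent_blocks["5"]]
        )
        cuaac = apply_transform(BUILTIN_RULES["cuaac"], [p1, divergent_blocks["18"]])
        assert cuaac.formula == p1.formula + divergent_blocks["18"].formula
        sono = apply_transform(BUILTIN_RULES["sonogashira"], [p1, divergent_blocks["12"]])
        assert sono.formula == p1.formula + divergent_blocks["12"].formula - Formula("HBr")

    def test_role_mismatch_rejected(self, divergent_blocks):
        with pytest.raises(ChemspaceError, match="roles"):
            apply_transform(
                BUILTIN_RULES["urea"], [divergent_blocks["5"], divergent_blocks["1"]]
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        c1=st.integers(1, 30),
        h1=st.integers(4, 60),
        n1=st.integers(1, 6),
        c2=st.integers(1, 30),
        h2=st.integers(4, 60),
        o2=st.integers(1, 6),
    )
    def test_mass_conservation_property(self, c1, h1, n1, c2, h2, o2):
        a = BuildingBlock("a", Role.POLYTOPIC_AMINE, Formula({"C": c1, "H": h1, "N": n1}), topicity=2)
        b = BuildingBlock("b", Role.CARBONYL_PYRIDINE, Formula({"C": c2, "H": h2, "O": o2, "N": 1}))
        product = apply_transform(BUILTIN_RULES["imine_condensation"], [a, b, b])
        b_mass = 2 * b.mass()
        delta = -2 * formula_mass("H2O")
        assert product.mass() == pytest.approx(a.mass() + b_mass + delta, abs=1e-6)


class TestRoutes:
    def _stage1(self):
        return RouteStage(
            branches=(
                (BUILTIN_RULES["urea"], Role.ISOCYANATE),
                (BUILTIN_RULES["thiourea"], Role.ISOTHIOCYANATE),
            )
        )

    def _stage2(self):
        return RouteStage(
            branches=(
                (BUILTIN_RULES["sonogashira"], Role.ARYL_HALIDE),
                (BUILTIN_RULES["cuaac"], Role.AZIDE),
            )
        )

    def test_divergent_route_counts(self, divergent_blocks):
        graph = enumerate_route(divergent_blocks.values(), [self._stage1(), self._stage2()])
        counts = graph.stage_counts()
        assert counts[1] == 6  # 3 amines x {isocyanate, isothiocyanate}
        assert counts[2] == 12  # 6 precursors x 2 diversifications
        assert len(graph.terminal_products()) == 12

    def test_degenerate_route(self, divergent_blocks):
        blocks = [divergent_blocks["1"], divergent_blocks["5"]]
        stage = RouteStage(branches=((BUILTIN_RULES["urea"], Role.ISOCYANATE),))
        graph = enumerate_route(blocks, [stage])
        assert len(graph.terminal_products()) == 1

    def test_route_counts_are_products_of_block_set_sizes(self, divergent_blocks):
        # closed form: stage1 = amines x electrophiles per branch, stage2 multiplies
        graph = enumerate_route(divergent_blocks.values(), [self._stage1(), self._stage2()])
        n_amines = 3
        assert graph.stage_counts()[1] == n_amines * (1 + 1)
        assert graph.stage_counts()[2] == graph.stage_counts()[1] * 2

    def test_missing_role_is_an_error(self, divergent_blocks):
        no_azide = [b for b in divergent_blocks.values() if b.role is not Role.AZIDE]
        with pytest.raises(ChemspaceError, match="azide"):
            enumerate_route(no_azide, [self._stage1(), self._stage2()])


class TestAssemblies:
    @pytest.mark.parametrize("m,c,q", [(4, 2, 8), (2, 2, 4), (1, 1, 1)])
    def test_assembly_charge(self, m, c, q):
        assert assembly_charge(m, c) == q

    def test_charge_preconditions(self):
        with pytest.raises(ChemspaceError):
            assembly_charge(0, 2)
        with pytest.raises(ChemspaceError):
            assembly_charge(2, 0)

    def test_ditopic_series_with_octahedral_metal(self, supra_blocks):
        series = enumerate_assemblies(
            supra_blocks["24"], supra_blocks["29"], supra_blocks["Zn"], 10
        )
        assert [(s.metal_count, s.ligand_count) for s in series] == [
            (2, 3), (4, 6), (6, 9), (8, 12), (10, 15),
        ]

    def test_tritopic_series_is_one_to_one(self, supra_blocks):
        series = enumerate_assemblies(
            supra_blocks["24"], supra_blocks["28"], supra_blocks["Zn"], 10
        )
        assert [(s.metal_count, s.ligand_count) for s in series] == [(k, k) for k in range(1, 11)]

    def test_zero_max_metals_gives_empty_list(self, supra_blocks):
        assert enumerate_assemblies(
            supra_blocks["24"], supra_blocks["28"], supra_blocks["Zn"], 0
        ) == []

    def test_mononuclear_exclusion_switch(self, supra_blocks):
        series = enumerate_assemblies(
            supra_blocks["24"], supra_blocks["28"], supra_blocks["Zn"], 10,
            include_mononuclear=False,
        )
        assert all(s.metal_count > 1 for s in series)

    def test_coordination_balance_enforced(self, supra_blocks):
        with pytest.raises(ChemspaceError, match="imbalance"):
            AssemblySpecies(
                supra_blocks["Zn"], 3, supra_blocks["24"], supra_blocks["29"], 2
            )

    def test_assembly_formula_books_imine_water_loss(self, supra_blocks):
        cage = AssemblySpecies(
            supra_blocks["Zn"], 4, supra_blocks["24"], supra_blocks["28"], 4
        )
        expected = (
            4 * supra_blocks["Zn"].formula
            + 4 * (supra_blocks["28"].formula + 3 * supra_blocks["24"].formula - 3 * Formula("H2O"))
        )
        assert cage.formula == expected
        assert cage.net_charge == 8


class TestMzLadders:
    def _species(self, mass_da, q, supra_blocks):
        # real assemblies carry arbitrary masses; for ladder arithmetic use a stub
        class Stub:
            net_charge = q

            def mass(self, mode="monoisotopic"):
                return mass_da

        return Stub()

    def test_ladder_arithmetic_hand_checked(self, supra_blocks):
        ctr = BuildingBlock("X", Role.COUNTERION, Formula("CF3O3S"), charge=-1)
        ctr_mass = 100.0

        class Ctr:
            def mass(self, mode="monoisotopic"):
                return ctr_mass

        ladder = mz_series(self._species(3000.0, 8, supra_blocks), Ctr())
        by_z = {z: mz for z, n, mz in ladder}
        assert by_z[8] == pytest.approx(375.0)
        assert by_z[4] == pytest.approx(850.0)
        assert len(ladder) == 8
        assert all(z + n == 8 for z, n, _ in ladder)

    def test_single_charge_ladder_is_bare_mass(self, supra_blocks, counterion):
        ladder = mz_series(self._species(500.0, 1, supra_blocks), counterion)
        assert ladder == [(1, 0, pytest.approx(500.0))]

    def test_mz_strictly_decreases_with_charge(self, supra_blocks, counterion):
        cage = enumerate_assemblies(
            supra_blocks["24"], supra_blocks["28"], supra_blocks["Zn"], 10
        )[3]
        ladder = mz_series(cage, counterion)
        mzs = [mz for _, _, mz in sorted(ladder)]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))


class TestAdducts:
    def test_proton_adduct(self, divergent_blocks):
        product = apply_transform(
            BUILTIN_RULES["urea"], [divergent_blocks["1"], divergent_blocks["5"]]
        )
        mzs = dict(adduct_mz(product))
        assert mzs["[M+H]+"] == pytest.approx(175.0866, abs=5e-5)

    def test_sodium_proton_offset_is_constant(self, divergent_blocks):
        for bid in ("1", "2", "18"):
            mzs = dict(adduct_mz(divergent_blocks[bid]))
            assert mzs["[M+Na]+"] - mzs["[M+H]+"] == pytest.approx(21.9819, abs=5e-5)

    def test_invalid_inputs(self, divergent_blocks):
        with pytest.raises(ChemspaceError):
            adduct_mz(divergent_blocks["1"], adducts={})
        with pytest.raises(ChemspaceError):
            adduct_mz(0.0)


class TestLookupTable:
    def test_grid_combination_count(self, supra_blocks):
        table = build_lookup_table(
            [supra_blocks[i] for i in ("24", "25", "26")],
            [supra_blocks[i] for i in ("27", "28", "29")],
            [supra_blocks[i] for i in ("Zn", "Cu")],
            supra_blocks["OTf"],
            max_metals={"Zn": 10, "Cu": 12},
        )
        assert len({e.combination for e in table.entries}) == 18

    def test_single_combination_counts(self, supra_blocks):
        table = build_lookup_table(
            [supra_blocks["24"]], [supra_blocks["28"]], [supra_blocks["Zn"]],
            supra_blocks["OTf"], max_metals=10,
        )
        assert table.n_entries == 10  # (1,1)..(10,10)
        assert table.n_values == sum(2 * m for m in range(1, 11))  # sum of Q

    def test_empty_grid(self, supra_blocks):
        table = build_lookup_table([], [], [], supra_blocks["OTf"])
        assert table.n_entries == 0 and table.n_values == 0

    def test_duplicate_ids_rejected(self, supra_blocks):
        with pytest.raises(ChemspaceError, match="duplicate"):
            build_lookup_table(
                [supra_blocks["24"]], [supra_blocks["28"]], [supra_blocks["Zn"]],
                BuildingBlock("24", Role.COUNTERION, Formula("CF3O3S"), charge=-1),
            )

    def test_csv_and_json_round_trip(self, supra_blocks, tmp_path):
        from rxntriage.chemspace import MzTable

        table = build_lookup_table(
            [supra_blocks["24"]], [supra_blocks["29"]], [supra_blocks["Zn"]],
            supra_blocks["OTf"], max_metals=10,
        )
        table.to_csv(tmp_path / "t.csv")
        table.to_json(tmp_path / "t.json")
        back = MzTable.from_json(tmp_path / "t.json")
        assert back.n_entries == table.n_entries
        assert back.entries[0].ladder == pytest.approx(table.entries[0].ladder)
        frame = table.to_frame()
        assert list(frame.columns) == ["entry_id", "combination", "m", "l", "Q", "z", "n", "mz"]
        assert len(frame) == table.n_values
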