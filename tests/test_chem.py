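"""Mass arithmetic: formulas, adducts, candidate enumeration.

Independent oracles: pyteomics.mass for monoisotopic masses, a brute-force
ordered-pair enumerator for acyl combinations, and hand-assembled formulas
for the species construction rule.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyt_mass

from algalipid.chem import (
    ADDUCTS,
    ElementalFormula,
    FattyAcyl,
    LipidSpecies,
    adduct_mz,
    enumerate_candidates,
    get_adduct,
    monoisotopic_mass,
    parse_fa_name,
    ppm_error,
    species_formula,
)

H2O = ElementalFormula({"H": 2, "O": 1})


class TestElementalFormula:
    def test_parse_and_str_roundtrip(self):
        f = ElementalFormula.parse("C41H76O10")
        assert f.counts == {"C": 41, "H": 76, "O": 10}
        assert str(f) == "C41H76O10"

    def test_addition_and_subtraction_are_elementwise(self):
        a = ElementalFormula.parse("C6H12O6")
        b = ElementalFormula.parse("C3H8O3")
        assert (a + b).counts == {"C": 9, "H": 20, "O": 9}
        assert (a - b).counts == {"C": 3, "H": 4, "O": 3}

    def test_subtraction_below_zero_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            ElementalFormula.parse("CH4") - ElementalFormula.parse("C2H4")

    def test_empty_formula_mass_is_zero(self):
        assert monoisotopic_mass(ElementalFormula()) == 0.0

    @pytest.mark.parametrize(
        "formula, expected",
        [("H2O", 18.0106), ("C41H76O10", 728.5438)],
    )
    def test_known_masses(self, formula, expected):
        assert monoisotopic_mass(ElementalFormula.parse(formula)) == pytest.approx(
            expected, abs=5e-4
        )

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S"]),
            st.integers(min_value=0, max_value=120),
            min_size=1,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_agrees_with_pyteomics(self, counts):
        ours = monoisotopic_mass(ElementalFormula(counts))
        theirs = pyt_mass.calculate_mass(
            composition=pyt_mass.Composition(
                {k: v for k, v in counts.items() if v}
            )
        )
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestFattyAcyl:
    def test_free_acid_formula_rule(self):
        assert FattyAcyl(18, 1).formula.counts == {"C": 18, "H": 34, "O": 2}
        assert FattyAcyl(14, 0).formula.counts == {"C": 14, "H": 28, "O": 2}

    def test_unsaturation_cap(self):
        with pytest.raises(ValueError):
            FattyAcyl(4, 3)

    @pytest.mark.parametrize(
        "name, carbons, dbs, omega",
        [("18:3n-3", 18, 3, 3), ("20:4n-6", 20, 4, 6), ("18:1", 18, 1, None)],
    )
    def test_name_parsing(self, name, carbons, dbs, omega):
        acyl = parse_fa_name(name)
        assert (acyl.carbons, acyl.double_bonds, acyl.omega) == (
            carbons,
            dbs,
            omega,
        )

    def test_ketene_is_acid_minus_water(self):
        acyl = FattyAcyl(16, 0)
        assert acyl.ketene_mass == pytest.approx(acyl.mass - H2O.mass, abs=1e-12)


class TestSpeciesFormula:
    def test_mgdg_32_1_hand_assembled(self, class_defs):
        """Glycerol + galactose + 18:1 + 14:0 - 3 H2O, bookkept by hand."""
        sp = LipidSpecies("MGDG", 32, 1, (FattyAcyl(18, 1), FattyAcyl(14, 0)))
        got = species_formula(sp, class_defs["MGDG"])
        glycerol = ElementalFormula.parse("C3H8O3")
        galactose = ElementalFormula.parse("C6H12O6")
        expected = (
            glycerol
            + galactose
            + FattyAcyl(18, 1).formula
            + FattyAcyl(14, 0).formula
            - 3 * H2O
        )
        assert got.counts == expected.counts == ElementalFormula.parse("C41H76O10").counts

    def test_dgdg_adds_one_anhydrogalactose(self, class_defs):
        sp = LipidSpecies("DGDG", 32, 1)
        got = species_formula(sp, class_defs["DGDG"])
        mgdg = species_formula(LipidSpecies("MGDG", 32, 1), class_defs["MGDG"])
        assert got.counts == (mgdg + ElementalFormula.parse("C6H10O5")).counts
        assert str(got) == "C47H86O15"

    def test_mono_acyl_species(self, class_defs):
        sp = LipidSpecies("MGMG", 18, 4)
        assert str(species_formula(sp, class_defs["MGMG"])) == "C27H44O9"

    def test_formula_is_decomposition_invariant(self, class_defs):
        a = LipidSpecies("MGDG", 32, 1, (FattyAcyl(18, 1), FattyAcyl(14, 0)))
        b = LipidSpecies("MGDG", 32, 1, (FattyAcyl(16, 1), FattyAcyl(16, 0)))
        assert (
            species_formula(a, class_defs["MGDG"]).counts
            == species_formula(b, class_defs["MGDG"]).counts
        )

    def test_class_code_mismatch_rejected(self, class_defs):
        with pytest.raises(ValueError, match="class mismatch"):
            species_formula(LipidSpecies("PC", 34, 1), class_defs["MGDG"])

    def test_mass_additivity(self, class_defs):
        """species mass == backbone + sum(acyls) - n_acyl * H2O to 1e-9 Da."""
        for code in ("MGDG", "DGDG", "SQDG", "PC", "PG", "PI", "PE", "DGTA"):
            cdef = class_defs[code]
            chains = (FattyAcyl(18, 2), FattyAcyl(16, 0))[: cdef.n_acyl]
            sp = LipidSpecies(
                code,
                sum(c.carbons for c in chains),
                sum(c.double_bonds for c in chains),
                chains,
            )
            got = monoisotopic_mass(species_formula(sp, cdef))
            expected = (
                monoisotopic_mass(cdef.backbone)
                + sum(c.mass for c in chains)
                - cdef.n_acyl * H2O.mass
            )
            assert got == pytest.approx(expected, abs=1e-9)

    def test_lyso_plus_fatty_acid_equals_diacyl(self, class_defs):
        """MGMG(16:0) + 18:1 free acid - H2O == MGDG(34:1), masswise."""
        lyso = monoisotopic_mass(
            species_formula(LipidSpecies("MGMG", 16, 0), class_defs["MGMG"])
        )
        diacyl = monoisotopic_mass(
            species_formula(LipidSpecies("MGDG", 34, 1), class_defs["MGDG"])
        )
        assert lyso + FattyAcyl(18, 1).mass - H2O.mass == pytest.approx(
            diacyl, abs=1e-9
        )


class TestAdducts:
    def test_known_shifts(self):
        assert ADDUCTS["[M+H]+"].mass_shift == pytest.approx(1.007276, abs=1e-6)
        assert ADDUCTS["[M+NH4]+"].mass_shift == pytest.approx(18.033823, abs=5e-6)
        assert ADDUCTS["[M-H]-"].mass_shift == pytest.approx(-1.007276, abs=1e-6)
        assert ADDUCTS["[M+CH3COO]-"].mass_shift == pytest.approx(59.013851, abs=1e-5)

    @pytest.mark.parametrize("code", list(ADDUCTS))
    @given(neutral=st.floats(min_value=100.0, max_value=2000.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_adduct_then_inverse_is_identity(self, code, neutral):
        adduct = get_adduct(code)
        assert adduct.neutral_mass(adduct.mz(neutral)) == pytest.approx(
            neutral, abs=1e-9
        )

    def test_unsupported_code_raises(self):
        with pytest.raises(KeyError):
            get_adduct("[M+K]+")

    def test_mgdg_32_1_ammoniated(self, class_defs):
        mass = monoisotopic_mass(
            species_formula(LipidSpecies("MGDG", 32, 1), class_defs["MGDG"])
        )
        mz = adduct_mz(mass, "[M+NH4]+")
        assert mz == pytest.approx(746.578, abs=2e-3)
        assert abs(ppm_error(746.5765, mz)) < 5

    def test_pc_36_2_protonated(self, class_defs):
        mass = monoisotopic_mass(
            species_formula(LipidSpecies("PC", 36, 2), class_defs["PC"])
        )
        assert abs(ppm_error(786.6005, adduct_mz(mass, "[M+H]+"))) < 5

    def test_sqdg_34_1_deprotonated(self, class_defs):
        mass = monoisotopic_mass(
            species_formula(LipidSpecies("SQDG", 34, 1), class_defs["SQDG"])
        )
        assert abs(ppm_error(819.5269, adduct_mz(mass, "[M-H]-"))) < 5


class TestPpmError:
    def test_zero_for_identical(self):
        assert ppm_error(746.5765, 746.5765) == 0.0

    def test_signed_direct_arithmetic(self):
        assert ppm_error(746.5765, 746.5782) == pytest.approx(-2.277, abs=5e-3)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(1.0, 0.0)


def _brute_force_pairs(pool, total_c, total_n):
    """Oracle: try every ordered pair, deduplicate unordered sets."""
    found = set()
    for a, b in itertools.product(pool, repeat=2):
        if a.carbons + b.carbons == total_c and a.double_bonds + b.double_bonds == total_n:
            found.add(tuple(sorted([a, b], key=lambda x: (-x.carbons, -x.double_bonds))))
    return found


class TestEnumerateCandidates:
    def test_mgdg_38_8_printed_combinations(self, class_defs):
        pool = [FattyAcyl(*cd) for cd in
                [(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2),
                 (18, 3), (18, 4), (20, 4), (20, 5)]]
        got = enumerate_candidates(class_defs["MGDG"], pool, 38, 8)
        assert {s.chain_label for s in got} == {"20:5/18:3", "20:4/18:4"}

    def test_single_combination(self, class_defs):
        got = enumerate_candidates(
            class_defs["SQDG"], [FattyAcyl(14, 0), FattyAcyl(16, 0)], 28, 0
        )
        assert [s.chain_label for s in got] == ["14:0/14:0"]

    def test_unattainable_totals_give_empty_list(self, class_defs):
        got = enumerate_candidates(
            class_defs["MGDG"], [FattyAcyl(14, 0), FattyAcyl(16, 1)], 30, 9
        )
        assert got == []

    @given(
        pool_spec=st.lists(
            st.tuples(
                st.integers(min_value=12, max_value=22),
                st.integers(min_value=0, max_value=6),
            ),
            min_size=1,
            max_size=12,
        ),
        total_c=st.integers(min_value=24, max_value=44),
        total_n=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(
        self, class_defs, pool_spec, total_c, total_n
    ):
        pool = [
            FattyAcyl(c, min(d, c // 2)) for c, d in pool_spec
        ]
        got = enumerate_candidates(class_defs["MGDG"], pool, total_c, total_n)
        expected = _brute_force_pairs(set(pool), total_c, total_n)
        assert {s.acyl_chains for s in got} == expected


class TestReferenceTable:
    def test_theoretical_mz_tracks_printed_values(
        self, class_defs, reference_rows
    ):
        """Printed observed m/z sit close to theory across all 159 rows.

        Row-level agreement at the 5 ppm identification bound is exercised
        by the acceptance suite; here the distribution is sanity-checked:
        the median |ppm| must be small and no row may drift past 6 ppm
        (which would indicate a wrong backbone, not measurement error).
        """
        ppms = []
        for row in reference_rows:
            mass = monoisotopic_mass(
                species_formula(row.species, class_defs[row.class_code])
            )
            ppms.append(abs(ppm_error(row.observed_mz, adduct_mz(mass, row.adduct))))
        assert len(ppms) == 159
        assert np.median(ppms) < 2.0
        assert max(ppms) < 6.0

    def test_isomeric_betaine_backbones_identical(self, class_defs):
        assert (
            class_defs["DGTA"].backbone.counts
            == class_defs["DGTS"].backbone.counts
        )
        lo_s, hi_s = class_defs["DGTS"].rt_window
        lo_a, hi_a = class_defs["DGTA"].rt_window
        assert hi_s < lo_a  # disjoint elution windows
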