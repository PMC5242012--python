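"""Mass ladders, isotope patterns, extinction coefficients, quantification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venombank.mass_qc import (
    M_H_AVG,
    M_H_MONO,
    MassProfile,
    composition_isotope_pattern,
    concentration_and_yield,
    extinction_coeff,
    match_observed,
    molar_recovery,
    oxidized_species,
    peptide_mass,
    theoretical_isotope_pattern,
)
from venombank.mass_qc import _element_isotopes

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_mass("G", "mono") == pytest.approx(75.032, abs=1e-3)

    def test_mono_below_average_for_sulfur_peptides(self):
        seq = "MCCCWMCC"
        assert peptide_mass(seq, "mono") < peptide_mass(seq, "average")

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("GXG")

    @given(peptides, peptides)
    @settings(max_examples=60, derandomize=True)
    def test_additivity_minus_water(self, s1, s2):
        for mode in ("mono", "average"):
            # joining two chains releases exactly one water
            water = 2 * peptide_mass("G", mode) - peptide_mass("GG", mode)
            joint = peptide_mass(s1 + s2, mode)
            parts = peptide_mass(s1, mode) + peptide_mass(s2, mode)
            assert parts - joint == pytest.approx(water, abs=1e-6)


class TestOxidizedLadder:
    def test_zero_bridge_species_equals_reduced(self):
        ladder = oxidized_species(1000.0, 1001.0, 3)
        assert ladder[0].mono == 1000.0
        assert ladder[0].average == 1001.0

    def test_one_bridge_removes_two_hydrogens(self):
        ladder = oxidized_species(1000.0, 1000.0, 1)
        assert ladder[1].mono == pytest.approx(997.98435)
        assert ladder[1].average == pytest.approx(997.98412)

    def test_spacing_constant_and_strictly_decreasing(self):
        ladder = oxidized_species(5000.0, 5003.0, 9)
        monos = [s.mono for s in ladder]
        avgs = [s.average for s in ladder]
        assert all(a - b == pytest.approx(2 * M_H_MONO)
                   for a, b in zip(monos, monos[1:]))
        assert all(a - b == pytest.approx(2 * M_H_AVG)
                   for a, b in zip(avgs, avgs[1:]))


def _bruteforce_pattern(composition):
    """Independent oracle: atom-by-atom dict convolution of isotopologues."""
    dist = {0: 1.0}
    for element, count in composition.items():
        isos = _element_isotopes(element)
        total = sum(ab for _, ab in isos)
        for _ in range(count):
            new = {}
            for off0, p0 in dist.items():
                for off, ab in isos:
                    key = off0 + off
                    new[key] = new.get(key, 0.0) + p0 * ab / total
            dist = new
    peak = max(dist.values())
    return {k: v / peak for k, v in dist.items()}


class TestIsotopePattern:
    def test_single_carbon_ratio(self):
        pattern = dict(composition_isotope_pattern({"C": 1}, threshold=0))
        assert pattern[1] == pytest.approx(0.0108, abs=2e-4)

    def test_engine_matches_bruteforce_oracle(self):
        for comp in ({"C": 30, "H": 50, "N": 10, "O": 10, "S": 4},
                     {"C": 12, "H": 20, "O": 5},
                     {"S": 8}):
            mine = dict(composition_isotope_pattern(comp, threshold=0))
            oracle = _bruteforce_pattern(comp)
            for offset, expected in oracle.items():
                assert mine.get(offset, 0.0) == pytest.approx(expected,
                                                              abs=1e-6)

    def test_m1_grows_linearly_with_carbon_count(self):
        ratios = []
        for n in (10, 40, 70, 100):
            pattern = dict(theoretical_isotope_pattern("G" * n,
                                                       normalize="sum"))
            ratios.append(pattern[1] / pattern[0])
        increments = [b - a for a, b in zip(ratios, ratios[1:])]
        assert all(i > 0 for i in increments)
        assert max(increments) / min(increments) < 1.35

    def test_sum_normalization(self):
        pattern = theoretical_isotope_pattern("ACDW", normalize="sum",
                                              threshold=0)
        assert sum(a for _, a in pattern) == pytest.approx(1.0, abs=1e-9)

    def test_bridges_shift_composition(self):
        with_bridge = dict(theoretical_isotope_pattern("CCACCA", n_bridges=2,
                                                       threshold=0))
        assert with_bridge[0] == 1.0  # still max-normalized


class TestMatchObserved:
    def test_fully_oxidized_exact_match(self, small_library):
        rec = next(r for r in small_library if r.n_bridges_max >= 2)
        profile = MassProfile.from_sequence(rec.sequence, rec.id)
        observed = profile.species[-1].average
        result = match_observed(profile, observed)
        assert result.status == "fully_oxidized"
        assert result.delta == 0.0
        assert result.matched_n_bridges == rec.n_bridges_max

    def test_reduced_mass_called_reduced(self):
        profile = MassProfile.from_sequence("CCACCACC", "p")  # 3 bridges max
        result = match_observed(profile, profile.average_reduced)
        assert result.status == "reduced"

    def test_midpoint_tie_broken_toward_more_oxidized(self):
        profile = MassProfile.from_sequence("CCACCACC", "p")
        sp = {s.n_bridges: s.average for s in profile.species}
        midpoint = (sp[2] + sp[3]) / 2
        result = match_observed(profile, midpoint, tolerance=1.5)
        assert result.matched_n_bridges == 3

    def test_far_mass_is_no_match(self):
        profile = MassProfile.from_sequence("CCAC", "p")
        result = match_observed(profile, profile.average_reduced + 50.0)
        assert result.status == "no_match"
        assert result.matched_n_bridges is None


class TestExtinction:
    @pytest.mark.parametrize(
        "seq, assume, expected, low_conf",
        [
            ("AGLKR", True, 0.0, True),
            ("WAGKL", True, 5500.0, False),
            ("YYACCA", True, 2 * 1490 + 125, False),
            ("YYACCA", False, 2 * 1490, False),
        ],
    )
    def test_gill_von_hippel_rule(self, seq, assume, expected, low_conf):
        result = extinction_coeff(seq, assume_cystine=assume)
        assert result.epsilon == expected
        assert result.low_confidence is low_conf


class TestQuantification:
    def test_printed_worked_example_arithmetic(self):
        # 65.6 uM in 250 uL -> 16.4 nmol; 97.3 ug from 24 mL -> 4.06 mg/L
        q = concentration_and_yield(mass_da=5935.0, volume_ul=250.0,
                                    culture_ml=24.0, conc_um=65.6)
        assert q.amount_nmol == pytest.approx(16.4)
        assert q.amount_ug == pytest.approx(16.4 * 5935 / 1000, rel=1e-6)
        assert q.yield_mg_per_l == pytest.approx(q.amount_ug / 24.0)

    def test_a280_path(self):
        q = concentration_and_yield(mass_da=3000.0, volume_ul=250.0,
                                    culture_ml=24.0, a280=0.11,
                                    epsilon=5500.0)
        assert q.conc_um == pytest.approx(20.0)

    def test_zero_epsilon_directs_to_area_quantification(self):
        with pytest.raises(ValueError, match="area"):
            concentration_and_yield(mass_da=3000.0, volume_ul=250.0,
                                    culture_ml=24.0, a280=0.1, epsilon=0.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            concentration_and_yield(mass_da=3000.0, volume_ul=0.0,
                                    culture_ml=24.0, conc_um=10.0)


class TestMolarRecovery:
    def test_printed_library_average(self):
        fusion_mass = 5935.0 / 0.176
        assert molar_recovery(186.0, fusion_mass, 3.91, 5935.0) == pytest.approx(
            11.9, abs=0.05
        )

    def test_identical_molar_amounts_give_100(self):
        assert molar_recovery(100.0, 10000.0, 10.0, 1000.0) == pytest.approx(100.0)

    def test_linearity_in_peptide_yield(self):
        full = molar_recovery(186.0, 33722.0, 4.0, 5935.0)
        half = molar_recovery(186.0, 33722.0, 2.0, 5935.0)
        assert half == pytest.approx(full / 2)
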