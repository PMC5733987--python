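import random

import numpy as np
import pytest

from protchar import (
    AMINO_ACIDS,
    CompositionTable,
    ProteinSequence,
    aliphatic_index,
    build_report,
    charged_counts,
    composition,
    estimated_half_life,
    gravy,
    instability_index,
    isoelectric_point,
    molecular_weight,
    net_charge,
)
from protchar.synthetic_data import random_sequence


def _random_composition(rng, max_count=20):
    return CompositionTable({aa: rng.randint(0, max_count) for aa in AMINO_ACIDS})


def grid_pi(comp, nterm, tables, step=1e-3):
    """Independent dense-grid scan for the pH of zero net charge."""
    grid = np.arange(0.0, 14.0 + step, step)
    q = np.array([net_charge(comp, nterm, p, tables) for p in grid])
    return float(grid[np.argmin(np.abs(q))])


class TestMolecularWeight:
    def test_3k4q_fixture(self, fixtures, tables):
        # frozen full-precision sum of ProtParam average masses + one water
        mw = molecular_weight(fixtures.compositions["3K4Q"], tables)
        assert mw * 1000 == pytest.approx(48846.280, abs=0.01)

    def test_1qfx_fixture(self, fixtures, tables):
        mw = molecular_weight(fixtures.compositions["1QFX"], tables)
        assert mw == pytest.approx(50.78, abs=0.005)

    def test_empty_composition_is_one_water(self, tables):
        assert molecular_weight(CompositionTable({}), tables) * 1000 == pytest.approx(
            18.02, abs=0.005)

    def test_single_glycine(self, tables):
        # free glycine: residue mass 57.0519 + water 18.0152 = 75.07 Da
        mw = molecular_weight(CompositionTable({"G": 1}), tables)
        assert mw * 1000 == pytest.approx(75.07, abs=0.005)

    def test_additivity(self, tables):
        a = CompositionTable({"A": 3, "W": 2})
        b = CompositionTable({"G": 5, "K": 1})
        merged = CompositionTable({"A": 3, "W": 2, "G": 5, "K": 1})
        lhs = molecular_weight(merged, tables)
        rhs = (molecular_weight(a, tables) + molecular_weight(b, tables)
               - tables.water_mass / 1000)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestIsoelectricPoint:
    def test_3k4q(self, fixtures, tables):
        assert isoelectric_point(fixtures.compositions["3K4Q"], "A", tables) == \
            pytest.approx(4.94, abs=0.01)

    def test_1qfx(self, fixtures, tables):
        assert isoelectric_point(fixtures.compositions["1QFX"], "F", tables) == \
            pytest.approx(4.60, abs=0.01)

    def test_gg_against_grid_oracle(self, tables):
        comp = CompositionTable({"G": 2})
        pi = isoelectric_point(comp, "G", tables)
        assert abs(net_charge(comp, "G", pi, tables)) < 1e-3
        assert pi == pytest.approx(grid_pi(comp, "G", tables), abs=1e-3)

    def test_bisection_vs_grid_on_random_compositions(self, tables):
        rng = random.Random(0)
        for _ in range(50):
            comp = _random_composition(rng)
            if comp.length == 0:
                continue
            nterm = rng.choice(AMINO_ACIDS)
            pi = isoelectric_point(comp, nterm, tables)
            assert pi == pytest.approx(grid_pi(comp, nterm, tables), abs=1e-3)

    def test_net_charge_strictly_decreasing(self, tables):
        comp = CompositionTable({"D": 3, "K": 2, "H": 1})
        qs = [net_charge(comp, "A", p, tables) for p in np.linspace(0, 14, 57)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_unknown_nterm(self, tables):
        with pytest.raises(ValueError):
            isoelectric_point(CompositionTable({"A": 1}), "B", tables)


class TestChargedCounts:
    def test_3k4q(self, fixtures):
        neg, neg_pct, pos, pos_pct = charged_counts(fixtures.compositions["3K4Q"])
        assert (neg, pos) == (51, 34)
        assert neg_pct == pytest.approx(11.48, abs=0.01)
        assert pos_pct == pytest.approx(7.65, abs=0.01)

    def test_1qfx(self, fixtures):
        neg, neg_pct, pos, pos_pct = charged_counts(fixtures.compositions["1QFX"])
        assert (neg, pos) == (48, 27)
        assert neg_pct == pytest.approx(10.43, abs=0.01)

    def test_poly_g(self):
        assert charged_counts(CompositionTable({"G": 10})) == (0, 0.0, 0, 0.0)


class TestGravy:
    def test_3k4q(self, fixtures, tables):
        assert gravy(fixtures.compositions["3K4Q"], tables) == \
            pytest.approx(-0.304, abs=0.001)

    def test_single_ile_is_scale_max(self, tables):
        assert gravy(CompositionTable({"I": 1}), tables) == 4.5

    def test_expansion_oracle(self, tables):
        rng = random.Random(3)
        comp = _random_composition(rng)
        expanded = "".join(aa * n for aa, n in sorted(comp.counts.items()))
        brute = sum(tables.kd_scale[c] for c in expanded) / len(expanded)
        assert gravy(comp, tables) == pytest.approx(brute, abs=1e-12)


class TestAliphaticIndex:
    def test_3k4q(self, fixtures, tables):
        assert aliphatic_index(fixtures.compositions["3K4Q"], tables) == \
            pytest.approx(72.25, abs=0.01)

    def test_1qfx(self, fixtures, tables):
        assert aliphatic_index(fixtures.compositions["1QFX"], tables) == \
            pytest.approx(70.46, abs=0.01)

    def test_poly_ala(self, tables):
        assert aliphatic_index(CompositionTable({"A": 7}), tables) == 100.0


class TestInstabilityIndex:
    def test_two_mer_formula(self, tables):
        for s in ("AG", "WC", "DP"):
            ii, _ = instability_index(ProteinSequence("x", s), tables)
            assert ii == pytest.approx(5.0 * tables.diwv[s[0]][s[1]], abs=1e-12)

    def test_random_50mer_brute_force(self, tables):
        rng = random.Random(11)
        s = "".join(rng.choices(AMINO_ACIDS, k=50))
        ii, label = instability_index(ProteinSequence("x", s), tables)
        brute = 0.0
        for i in range(49):
            brute += tables.diwv[s[i]][s[i + 1]]
        brute *= 10.0 / 50
        assert ii == pytest.approx(brute, abs=1e-9)
        assert label == ("unstable" if brute > 40 else "stable")

    def test_too_short(self, tables):
        with pytest.raises(ValueError):
            instability_index(ProteinSequence("x", "A"), tables)


class TestHalfLife:
    def test_ala(self, tables):
        assert estimated_half_life("A", tables) == ("4.4 hours", ">20 hours", ">10 hours")

    def test_phe(self, tables):
        assert estimated_half_life("F", tables) == ("1.1 hours", "3 min", "2 min")

    def test_unknown(self, tables):
        with pytest.raises(ValueError):
            estimated_half_life("B", tables)


class TestCompositionSufficiency:
    def test_sequence_vs_composition(self, fixtures, tables):
        comp = fixtures.compositions["3K4Q"]
        seq = random_sequence(comp, seed=5)
        seq_comp = composition(seq)
        assert gravy(seq_comp, tables) == pytest.approx(gravy(comp, tables))
        assert aliphatic_index(seq_comp, tables) == pytest.approx(
            aliphatic_index(comp, tables))


class TestBuildReport:
    def test_full_report(self, fixtures, tables):
        comp = fixtures.compositions["3K4Q"]
        seq = random_sequence(comp, seed=1)
        report = build_report(comp, "A", tables, seq=seq)
        assert 0 < report.pi < 14
        assert report.neg_pct == pytest.approx(100 * report.neg_count / report.length)
        assert (report.instability_index > 40) == (report.stability_label == "unstable")

    def test_mismatched_sequence_rejected(self, fixtures, tables):
        seq = ProteinSequence("x", "AAGG")
        with pytest.raises(ValueError, match="match"):
            build_report(fixtures.compositions["3K4Q"], "A", tables, seq=seq)
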