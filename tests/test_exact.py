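from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import dblquad

from contibd.exact import (
    expected_segment_count,
    ibd1_start_hazard,
    ibd1_survival,
    identity_coefficients,
    pr_no_ibd,
    pr_no_ibd_genome,
    segment_count_dispersion,
    total_ibd_moments,
    two_locus_kappa11,
)
from contibd.genmap import GeneticMap
from contibd.simulate import simulate_totals

# Relationship -> kappa1, ordered by degree (columns of the reference table)
KAPPA1 = {
    "GP": "1/2", "HS": "1/2", "N": "1/2",
    "GGP": "1/4", "HN": "1/4", "GN": "1/4", "1C": "1/4",
    "G2GP": "1/8", "H1C": "1/8", "G2N": "1/8", "1C1R": "1/8",
    "G3GP": "1/16", "H1C1R": "1/16", "G3N": "1/16", "2C": "1/16",
    "G4GP": "1/32", "H2C": "1/32", "G4N": "1/32", "2C1R": "1/32",
    "G5GP": "1/64", "H2C1R": "1/64", "G5N": "1/64", "3C": "1/64",
    "G6GP": "1/128", "H3C": "1/128", "G6N": "1/128", "3C1R": "1/128",
    "G7GP": "1/256", "H3C1R": "1/256", "G7N": "1/256", "4C": "1/256",
    "G8GP": "1/512", "H4C": "1/512", "G8N": "1/512", "4C1R": "1/512",
    "G9GP": "1/1024", "H4C1R": "1/1024", "G9N": "1/1024", "5C": "1/1024",
}


class TestIdentityCoefficients:
    @pytest.mark.parametrize("token,frac", sorted(KAPPA1.items()))
    def test_kappa1_exact(self, rel, token, frac):
        c = identity_coefficients(rel(token))
        assert c.kappa1 == Fraction(frac)
        assert c.kappa2 == 0
        assert c.kappa0 + c.kappa1 == 1

    def test_parent_child(self, rel):
        assert identity_coefficients(rel("PO")).kappa1 == 1


class TestTwoLocus:
    def test_zero_distance_is_kappa1(self, rel):
        for tok in ("GP", "N", "2C"):
            ped = rel(tok)
            k1 = float(identity_coefficients(ped).kappa1)
            assert two_locus_kappa11(ped, 0.0) == pytest.approx(k1, abs=1e-14)

    def test_long_distance_is_kappa1_squared(self, rel):
        for tok in ("GP", "HS", "1C", "3C"):
            ped = rel(tok)
            k1 = float(identity_coefficients(ped).kappa1)
            assert abs(two_locus_kappa11(ped, 10000.0) - k1 * k1) < 1e-9

    def test_gp_closed_form(self, rel):
        ped = rel("GP")
        for d in (0.0, 1.0, 13.7, 80.0, 250.0):
            assert two_locus_kappa11(ped, d) == pytest.approx(
                0.25 * (1.0 + np.exp(-0.02 * d)), abs=1e-14
            )

    @pytest.mark.parametrize("token", ["GP", "HS", "N", "1C", "2C"])
    def test_nonincreasing(self, rel, token):
        ped = rel(token)
        d = np.linspace(0, 400, 60)
        vals = [two_locus_kappa11(ped, x) for x in d]
        assert all(a >= b - 1e-14 for a, b in zip(vals, vals[1:]))


class TestTotalIbdMoments:
    def test_expected_total_is_exact(self, rel, autosomes):
        for tok, expect in (("GP", 1695.68), ("GGP", 847.84), ("G3GP", 211.96)):
            m = total_ibd_moments(rel(tok), autosomes)
            assert m.e_total == pytest.approx(expect, abs=1e-9)

    def test_any_relationship_expectation_identity(self, rel, autosomes):
        for tok in ("N", "2C", "H3C"):
            k1 = float(identity_coefficients(rel(tok)).kappa1)
            m = total_ibd_moments(rel(tok), autosomes)
            assert m.e_total == pytest.approx(k1 * 3391.36, abs=1e-9)

    def test_gp_variance_closed_form(self, rel):
        # Var(T) = 25 L - 1250 (1 - exp(-0.02 L)) for the two-state chain
        L = 100.0
        m = total_ibd_moments(rel("GP"), GeneticMap(("1",), (L,)))
        expect = 25.0 * L - 1250.0 * (1.0 - np.exp(-0.02 * L))
        assert m.var_t[0] == pytest.approx(expect, rel=1e-12)

    def test_gp_variance_against_monte_carlo(self, rel):
        L = 100.0
        gmap = GeneticMap(("1",), (L,))
        m = total_ibd_moments(rel("GP"), gmap)
        s = simulate_totals(rel("GP"), gmap, reps=100000, seed=31)
        var = s.total_ibd.var(ddof=1)
        se = var * np.sqrt(2.0 / (s.reps - 1))
        assert abs(var - m.var_t[0]) <= 3 * se

    def test_e_t2_reduction_matches_double_quadrature(self, rel):
        ped = rel("HS")
        L = 50.0
        m = total_ibd_moments(ped, GeneticMap(("1",), (L,)))
        e_t2_closed = m.var_t[0] + m.e_t[0] ** 2
        e_t2_quad, err = dblquad(
            lambda v, u: two_locus_kappa11(ped, abs(u - v)),
            0.0, L, 0.0, L, epsabs=1e-10, epsrel=1e-10,
        )
        assert abs(e_t2_closed - e_t2_quad) < 1e-8 + 10 * err

    def test_same_kappa_ordering(self, rel, autosomes):
        gp = total_ibd_moments(rel("GP"), autosomes)
        hs = total_ibd_moments(rel("HS"), autosomes)
        n = total_ibd_moments(rel("N"), autosomes)
        assert gp.e_total == hs.e_total == n.e_total
        assert gp.sd_total > hs.sd_total > n.sd_total
        assert (gp.expected_segment_count < hs.expected_segment_count
                < n.expected_segment_count)


class TestSegmentCount:
    @pytest.mark.parametrize(
        "token,expect", [("GP", 27.96), ("HS", 44.91), ("N", 53.39)]
    )
    def test_flux_formula_matches_table(self, rel, autosomes, token, expect):
        got = expected_segment_count(rel(token), autosomes)
        assert round(got, 2) == pytest.approx(expect)

    def test_parent_child_one_segment_per_chromosome(self, rel, autosomes):
        assert expected_segment_count(rel("PO"), autosomes) == pytest.approx(22.0)

    def test_gp_dispersion(self, rel, autosomes):
        d = segment_count_dispersion(rel("GP"), autosomes, reps=100000, seed=41)
        assert abs(d.sd - 3.38) <= 3 * d.se + 0.06  # slack: fixture-map split

    def test_hs_dispersion(self, rel, autosomes):
        d = segment_count_dispersion(rel("HS"), autosomes, reps=60000, seed=43)
        assert abs(d.sd - 4.44) <= 3 * d.se + 0.06

    def test_parent_child_dispersion_zero(self, rel, autosomes):
        d = segment_count_dispersion(rel("PO"), autosomes, reps=2000, seed=1)
        assert d.sd == 0.0

    def test_too_few_reps(self, rel, autosomes):
        with pytest.raises(ValueError):
            segment_count_dispersion(rel("GP"), autosomes, reps=10, seed=1)


class TestPrNoIbd:
    def test_zero_length_is_kappa0(self, rel):
        for tok in ("GP", "1C", "3C"):
            k0 = float(identity_coefficients(rel(tok)).kappa0)
            assert pr_no_ibd(rel(tok), 0.0) == pytest.approx(k0, abs=1e-12)

    def test_gp_closed_form(self, rel):
        for L in (10.0, 100.0, 280.0):
            assert pr_no_ibd(rel("GP"), L) == pytest.approx(
                0.5 * np.exp(-0.01 * L), rel=1e-9
            )

    def test_monotone_nonincreasing(self, rel):
        vals = [pr_no_ibd(rel("2C"), L) for L in np.linspace(0, 300, 40)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("token", ["GP", "HS", "1C", "2C"])
    def test_crude_path_lower_bound(self, rel, token):
        ped = rel(token)
        k0 = float(identity_coefficients(ped).kappa0)
        for L in (10.0, 60.0):
            bound = k0 * np.exp(-0.01 * ped.n_meioses * L)
            assert pr_no_ibd(ped, L) >= bound - 1e-12

    def test_1c_against_monte_carlo(self, rel):
        L = 100.0
        gmap = GeneticMap(("1",), (L,))
        p = pr_no_ibd(rel("1C"), L)
        s = simulate_totals(rel("1C"), gmap, reps=100000, seed=51)
        phat = np.mean(s.segment_count == 0)
        se = np.sqrt(p * (1 - p) / s.reps)
        assert abs(phat - p) <= 3 * se

    def test_genome_zero_sharing_probabilities(self, rel, autosomes):
        # about 69% for fifth cousins and 30% for fourth cousins
        assert pr_no_ibd_genome(rel("5C"), autosomes) == pytest.approx(
            0.6912, abs=0.02
        )
        assert pr_no_ibd_genome(rel("4C"), autosomes) == pytest.approx(
            0.2979, abs=0.02
        )

    def test_n0_moments(self, rel, autosomes):
        m = total_ibd_moments(rel("GP"), autosomes)
        assert m.n0_mean == pytest.approx(2.67, abs=0.05)
        assert m.n0_sd == pytest.approx(1.51, abs=0.05)


class TestSegmentStartLaws:
    def test_survival_gp_hs(self, rel):
        for L in (25.0, 150.0):
            assert ibd1_survival(rel("GP"), L) == pytest.approx(
                np.exp(-0.01 * L), rel=1e-9
            )
            assert ibd1_survival(rel("HS"), L) == pytest.approx(
                np.exp(-0.02 * L), rel=1e-9
            )

    def test_uncle_nephew_start_hazard(self, rel):
        assert ibd1_start_hazard(rel("N")) == pytest.approx(0.025, abs=1e-12)

    def test_uncle_nephew_hazard_decreases(self, rel):
        # double-IBD background accumulates, lowering the hazard over length
        s = [ibd1_survival(rel("N"), L) for L in (0.0, 20.0, 40.0, 60.0)]
        hazards = [-np.log(b / a) / 20.0 for a, b in zip(s, s[1:])]
        assert hazards[0] < 0.025
        assert all(a > b for a, b in zip(hazards, hazards[1:]))
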