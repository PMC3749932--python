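"""Diversity and neutrality statistics against independent oracles.

The expensive cross-checks (brute-force equivalence on many random
alignments, constant-transcription oracles at 1e-10) live in
test_acceptance.py; here are the worked examples, domain errors and sign
properties.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from tandemsweep.diversity import (
    RegressionResult,
    fu_li_D_star_F_star,
    jukes_cantor_K,
    jukes_cantor_distance,
    mean_pairwise_differences,
    nucleotide_diversity,
    percent_identity,
    regress_K_on_pi,
    site_counts,
    tajimas_D,
    watterson_theta,
)
from tandemsweep.segments import encode_alignment

from conftest import make_alignment


def brute_force_pi(seqs):
    """Independent oracle: explicit loop over all pairs and columns."""
    n = len(seqs)
    L = len(seqs[0])
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2) / L


class TestPi:
    def test_single_pair(self):
        assert nucleotide_diversity(make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])) == 0.1

    def test_identical(self):
        assert nucleotide_diversity(make_alignment(["ACGT"] * 5)) == 0.0

    def test_worked_four_sequences(self, worked_alignment):
        assert nucleotide_diversity(worked_alignment) == pytest.approx(7 / 24, abs=1e-15)

    def test_single_sequence_error(self):
        with pytest.raises(ValueError, match="two sequences"):
            nucleotide_diversity(make_alignment(["ACGT"]))

    def test_jc_corrected_exceeds_raw(self):
        aln = make_alignment(["ACGTACGTAC", "TCGAACGTAC", "ACGTACTTAC"])
        assert nucleotide_diversity(aln, jc_correct=True) > nucleotide_diversity(aln)


class TestSiteCounts:
    def test_monomorphic(self):
        assert site_counts(make_alignment(["ACGT"] * 4)) == (0, 0, 0)

    def test_triallelic_column(self):
        aln = make_alignment(["A", "A", "A", "C", "G"])
        S, eta, eta_s = site_counts(aln)
        assert (S, eta) == (1, 2)
        assert eta_s == 2  # C and G each observed once

    def test_singleton(self):
        aln = make_alignment(["AT", "AA", "AA", "AA", "AA"])
        assert site_counts(aln) == (1, 1, 1)

    def test_worked_alignment(self, worked_alignment):
        assert site_counts(worked_alignment) == (2, 2, 1)

    def test_pair_sample_minor_is_singleton(self):
        assert site_counts(make_alignment(["AT", "AA"])) == (1, 1, 1)


class TestTajimasD:
    def test_undefined_at_zero_S(self):
        assert math.isnan(tajimas_D(make_alignment(["ACGT"] * 5)))

    def test_negative_when_all_singletons(self):
        seqs = ["A" * 20 for _ in range(8)]
        seqs = [s[:i] + "T" + s[i + 1:] if i < 4 else s for i, s in enumerate(seqs)]
        assert tajimas_D(make_alignment(seqs)) < 0

    def test_positive_with_balanced_variants(self):
        # two haplotype classes at intermediate frequency
        seqs = ["AAAAA" + "T" * 5] * 4 + ["AAAAA" + "A" * 5] * 4
        assert tajimas_D(make_alignment(seqs)) > 0

    def test_worked_value_against_transcription(self, worked_alignment):
        # independent transcription of the variance constants in exact
        # rational arithmetic, n=4, S=2, kbar=7/6
        n, S = 4, 2
        kbar = Fraction(7, 6)
        a1 = sum(Fraction(1, i) for i in range(1, n))
        a2 = sum(Fraction(1, i * i) for i in range(1, n))
        b1 = Fraction(n + 1, 3 * (n - 1))
        b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = float(kbar - S / a1) / math.sqrt(float(e1 * S + e2 * S * (S - 1)))
        assert tajimas_D(worked_alignment) == pytest.approx(expected, abs=1e-10)


class TestFuLi:
    def test_all_singletons_negative(self):
        seqs = ["A" * 30 for _ in range(10)]
        seqs = [s[:i] + "T" + s[i + 1:] if i < 5 else s for i, s in enumerate(seqs)]
        Ds, Fs = fu_li_D_star_F_star(make_alignment(seqs))
        assert Ds < 0 and Fs < 0

    def test_no_singletons_positive_Dstar(self):
        seqs = ["AAAAATTTTT"] * 5 + ["AAAAAAAAAA"] * 5
        Ds, _ = fu_li_D_star_F_star(make_alignment(seqs))
        assert Ds > 0

    def test_undefined_at_zero_S(self):
        Ds, Fs = fu_li_D_star_F_star(make_alignment(["ACGT"] * 5))
        assert math.isnan(Ds) and math.isnan(Fs)


class TestJukesCantor:
    def test_identical_groups(self):
        m = encode_alignment(["ACGTACGTAC"] * 2)
        assert jukes_cantor_K(m[:1], m[1:]) == 0.0

    def test_closed_form(self):
        assert jukes_cantor_distance(0.3) == pytest.approx(
            -0.75 * math.log(0.6), abs=1e-15
        )
        assert jukes_cantor_distance(0.3) == pytest.approx(0.38312, abs=1e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="undefined"):
            jukes_cantor_distance(0.8)

    def test_between_groups_mean(self):
        a = encode_alignment(["AAAAAAAAAA"])
        b = encode_alignment(["AAAAAAAAAT", "AAAAAAAATT"])
        phat = (0.1 + 0.2) / 2
        assert jukes_cantor_K(a, b) == pytest.approx(jukes_cantor_distance(phat))


class TestWatterson:
    def test_single_pair_single_snp(self):
        # n=2: a1=1, S=1, L=10 -> theta = 0.1
        assert watterson_theta(make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])) == 0.1


class TestRegression:
    def test_collinear(self):
        import pandas as pd

        tab = pd.DataFrame(
            {"pi_permil": [1.0, 2.0, 3.0, 4.0], "K_vs_outgroup": [2.0, 4.0, 6.0, 8.0]}
        )
        res = regress_K_on_pi(tab)
        assert res.R2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_flat_K(self):
        import pandas as pd

        tab = pd.DataFrame(
            {"pi_permil": [1.0, 2.0, 3.0], "K_vs_outgroup": [5.0, 5.0, 5.0]}
        )
        res = regress_K_on_pi(tab)
        assert res.R2 == 0.0 and res.F_stat == 0.0

    def test_too_few_points(self):
        import pandas as pd

        tab = pd.DataFrame({"pi_permil": [1.0, 2.0], "K_vs_outgroup": [1.0, 2.0]})
        with pytest.raises(ValueError, match="three segments"):
            regress_K_on_pi(tab)

    def test_slope_recovery_with_noise(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        x = np.linspace(1, 10, 10)
        slope_true = 1.7
        y = slope_true * x + 3 + rng.normal(0, 0.3, 10)
        tab = pd.DataFrame({"pi_permil": x, "K_vs_outgroup": y})
        res = regress_K_on_pi(tab)
        # parametric check: slope CI half-width from residual variance
        se = math.sqrt(
            np.sum((y - (res.slope * x + res.intercept)) ** 2)
            / 8
            / np.sum((x - x.mean()) ** 2)
        )
        assert abs(res.slope - slope_true) < 3 * se
        assert res.p_value < 1e-6


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("ACGTACGT", "ACGTACGT") == (100.0, 100.0)

    def test_one_mismatch_in_hundred(self):
        a = "ACGT" * 25
        b = "T" + a[1:]
        ident, cov = percent_identity(a, b)
        assert ident == pytest.approx(99.0)
        assert cov == pytest.approx(100.0)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            percent_identity("", "ACGT")
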