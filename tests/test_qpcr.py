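"""qPCR quantification: efficiency estimation, relative quantities,
multi-reference dosage, geNorm stability, transcript folds."""

import numpy as np
import pandas as pd
import pytest

from tandemsweep.qpcr import (
    CurveError,
    estimate_efficiency,
    genorm_stability,
    normalized_dosage,
    relative_quantity,
    relative_transcript_level,
    transcript_table,
)
from tandemsweep.simulate import synth_amplification_curve


class TestEfficiency:
    def test_exact_doubling(self):
        curve = 0.01 * 2.0 ** np.arange(1, 31)
        assert estimate_efficiency(curve) == pytest.approx(2.0, abs=1e-6)

    def test_flat_curve_excluded(self):
        with pytest.raises(CurveError):
            estimate_efficiency(np.full(40, 0.013))

    def test_noisy_plateau_recovery(self):
        # E = 1.88 with plateau saturation and 1% noise: the per-amplicon
        # mean over reactions lands within [1.85, 1.91]; implausible
        # single-reaction fits are excluded, not averaged in
        from tandemsweep.qpcr import mean_amplicon_efficiencies

        rng = np.random.default_rng(0)
        curves = [
            synth_amplification_curve(1.88, 1.0, n_cycles=40, noise=0.01, rng=rng)
            for _ in range(100)
        ]
        eff, excluded = mean_amplicon_efficiencies({"amp": curves})
        assert 1.85 <= eff["amp"] <= 1.91
        assert excluded <= 10

    def test_too_few_exponential_cycles(self):
        curve = np.full(40, 0.01)
        curve[-2:] = [0.2, 0.4]
        with pytest.raises(CurveError):
            estimate_efficiency(curve)


class TestRelativeQuantity:
    @pytest.mark.parametrize(
        "cq_s,cq_cal,E,expected",
        [
            (19.0, 20.0, 2.0, 2.0),
            (20.0, 20.0, 1.9, 1.0),
            (21.0, 20.0, 1.9, 1 / 1.9),
        ],
    )
    def test_closed_forms(self, cq_s, cq_cal, E, expected):
        assert relative_quantity(cq_s, cq_cal, E) == pytest.approx(expected)

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError, match="efficiency"):
            relative_quantity(20, 20, 1.0)

    def test_identity_for_any_E(self):
        for E in (1.1, 1.5, 1.9, 2.0):
            assert relative_quantity(23.4, 23.4, E) == 1.0


def make_plate(samples, target_copies, E=2.0, sigma=0.0, seed=0, n_reps=3):
    rng = np.random.default_rng(seed)
    amps = {
        "HMA4_coding": ("target", 24.0, E),
        "FRD3_5p": ("reference", 25.0, E),
        "FRD3_3p": ("reference", 25.5, E),
    }
    rows = []
    for s in ["calibrator"] + samples:
        q = 1.0 if s == "calibrator" else target_copies[s]
        for amp, (role, base, eff) in amps.items():
            quantity = q if role == "target" else 1.0
            for rep in range(1, n_reps + 1):
                rows.append(
                    dict(
                        sample_id=s,
                        target_amplicon=amp,
                        technical_replicate_id=rep,
                        Cq=base - np.log(quantity) / np.log(eff)
                        + rng.normal(0, sigma),
                    )
                )
    return pd.DataFrame(rows)


EFFS = {"HMA4_coding": 2.0, "FRD3_5p": 2.0, "FRD3_3p": 2.0}


class TestDosage:
    def test_two_copies_exact(self):
        plate = make_plate(["s1"], {"s1": 2.0})
        res = normalized_dosage(
            plate, EFFS, "HMA4_coding", ["FRD3_5p", "FRD3_3p"], "calibrator"
        )
        row = res.table.set_index("sample_id").loc["s1"]
        assert row["copy_number"] == pytest.approx(2.0, abs=1e-9)

    def test_all_equal_cq_gives_one(self):
        plate = make_plate(["s1", "s2"], {"s1": 1.0, "s2": 1.0})
        res = normalized_dosage(
            plate, EFFS, "HMA4_coding", ["FRD3_5p", "FRD3_3p"], "calibrator"
        )
        assert np.allclose(res.table["copy_number"], 1.0)

    def test_reference_rescaling_invariance(self):
        # multiplying all reference quantities of one sample by a constant
        # shifts its reference Cqs equally; the normalization absorbs it
        plate = make_plate(["s1"], {"s1": 3.0})
        shifted = plate.copy()
        mask = (shifted.sample_id == "s1") & (
            shifted.target_amplicon != "HMA4_coding"
        )
        shifted.loc[mask, "Cq"] -= 2.0  # 4-fold more of both references
        res0 = normalized_dosage(
            plate, EFFS, "HMA4_coding", ["FRD3_5p", "FRD3_3p"], "calibrator"
        )
        res1 = normalized_dosage(
            shifted, EFFS, "HMA4_coding", ["FRD3_5p", "FRD3_3p"], "calibrator"
        )
        r0 = res0.table.set_index("sample_id").loc["s1", "copy_number"]
        r1 = res1.table.set_index("sample_id").loc["s1", "copy_number"]
        assert r1 == pytest.approx(r0 / 4.0)

    def test_missing_reference_flagged(self):
        plate = make_plate(["s1", "s2"], {"s1": 2.0, "s2": 2.0})
        plate = plate[
            ~((plate.sample_id == "s2") & (plate.target_amplicon == "FRD3_3p"))
        ]
        res = normalized_dosage(
            plate, EFFS, "HMA4_coding", ["FRD3_5p", "FRD3_3p"], "calibrator"
        )
        assert res.flagged_samples == ["s2"]
        assert list(res.table.sample_id) != []

    def test_fewer_than_two_references_rejected(self):
        plate = make_plate(["s1"], {"s1": 2.0})
        with pytest.raises(ValueError, match="two reference"):
            normalized_dosage(plate, EFFS, "HMA4_coding", ["FRD3_5p"], "calibrator")


class TestGenorm:
    def test_perfectly_covarying_references(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.5, 10)
        tab = pd.DataFrame({"r1": base, "r2": base * 2, "r3": base * 0.5})
        M, CV = genorm_stability(tab)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in M.values())
        assert CV == pytest.approx(0.0, abs=1e-12)

    def test_unstable_reference_ranked_worst(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(0, 0.3, 20)
        jumpy = base * 2 ** rng.choice([-1.0, 1.0], 20)
        tab = pd.DataFrame(
            {
                "good1": base * rng.lognormal(0, 0.02, 20),
                "good2": base * rng.lognormal(0, 0.02, 20),
                "bad": jumpy,
            }
        )
        M, _ = genorm_stability(tab)
        assert M["bad"] == max(M.values())

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError, match="two references"):
            genorm_stability(pd.DataFrame({"r1": [1.0, 2.0]}))

    def test_known_lognormal_noise_expectation(self):
        # independent lognormal references with log2-scale sd s: V_jk has
        # expectation ~ s*sqrt(2); M within MC error of that
        rng = np.random.default_rng(3)
        s = 0.25
        reps = 60
        Ms = []
        for _ in range(reps):
            tab = pd.DataFrame(
                {f"r{i}": 2 ** rng.normal(0, s, 25) for i in range(3)}
            )
            M, _ = genorm_stability(tab)
            Ms.append(np.mean(list(M.values())))
        expected = s * np.sqrt(2)
        se = np.std(Ms, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(Ms) - expected) < 3 * se + 0.01


class TestTranscripts:
    def test_fold_closed_forms(self):
        assert relative_transcript_level(20, 20, 18, 18, 1.88, 1.9) == 1.0
        assert relative_transcript_level(15, 20, 18, 18, 2.0, 1.9) == pytest.approx(32.0)

    def test_table_end_to_end(self):
        rows = []
        for s, expr in [("calibrator", 1.0), ("h1", 50.0)]:
            for amp, E, base, q in [
                ("HMA4_cdna", 1.88, 22.0, expr),
                ("EF1a", 1.90, 20.0, 1.0),
            ]:
                for rep in range(3):
                    rows.append(
                        dict(
                            sample_id=s,
                            target_amplicon=amp,
                            technical_replicate_id=rep,
                            Cq=base - np.log(q) / np.log(E),
                        )
                    )
        tab = transcript_table(
            pd.DataFrame(rows), "HMA4_cdna", "EF1a", "calibrator", 1.88, 1.90
        )
        fold = tab.set_index("sample_id").loc["h1", "fold_change"]
        assert fold == pytest.approx(50.0, rel=1e-9)
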