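"""Efficiency-corrected relative qPCR quantification.

Covers genomic gene-dosage assays (target copy number against multiple
single-copy reference amplicons, scaled to a single-copy calibrator
genome) and relative transcript levels (target normalized to a
constitutive reference gene with per-primer-pair efficiencies). Reaction
efficiency E (1 < E <= 2) is estimated per reaction from the raw
fluorescence curve by the window-of-linearity method and averaged per
amplicon; reference-gene adequacy is scored with geNorm-style stability
M and pairwise variation CV.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CurveError(ValueError):
    """No usable exponential window in a fluorescence curve."""


def estimate_efficiency(
    curve: np.ndarray,
    baseline_cycles: int = 5,
    window_sizes: tuple[int, ...] = (4, 5, 6),
) -> float:
    """Per-reaction amplification efficiency by window of linearity.

    The baseline (median of the first ``baseline_cycles`` readings) is
    subtracted; log10 fluorescence is then fit against cycle number over
    every contiguous window of 4-6 cycles in the exponential phase, and
    the window with the best linear fit (highest R^2) wins:
    E = 10^slope. Curves without at least 4 usable above-baseline cycles
    raise CurveError.
    """
    f = np.asarray(curve, dtype=float)
    base = np.median(f[:baseline_cycles])
    g = f - base
    # exponential phase: above the noise floor and below plateau onset
    # (saturation flattens the log-linear slope and biases E downward, so
    # cycles beyond 2% of the signal maximum are excluded)
    noise = max(1e-12, 3 * np.std(f[:baseline_cycles] - base))
    usable = np.nonzero((g > noise) & (g < 0.02 * g.max()))[0]
    if len(usable) < 4:
        raise CurveError("fewer than 4 cycles above baseline")
    logf = np.full_like(g, np.nan)
    logf[usable] = np.log10(g[usable])
    best = None
    for w in window_sizes:
        for start in usable:
            idx = np.arange(start, start + w)
            if idx[-1] >= len(g) or np.isnan(logf[idx]).any():
                continue
            x = idx.astype(float)
            y = logf[idx]
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
            ss_res = float(np.sum((y - yhat) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
            if slope <= 0:
                continue
            if best is None or r2 > best[0]:
                best = (r2, slope)
    if best is None:
        raise CurveError("no positive-slope window found")
    E = 10 ** best[1]
    if not 1.0 < E <= 2.05:
        raise CurveError(f"estimated efficiency {E:.3f} outside (1, 2]")
    return min(E, 2.0)


def mean_amplicon_efficiencies(
    curves: dict[str, list[np.ndarray]],
) -> tuple[dict[str, float], int]:
    """Mean E per amplicon over all reactions; unusable curves excluded.

    Returns (amplicon -> mean E, number of excluded reactions).
    """
    out = {}
    excluded = 0
    for amp, cc in curves.items():
        es = []
        for c in cc:
            try:
                es.append(estimate_efficiency(c))
            except CurveError:
                excluded += 1
        if not es:
            raise CurveError(f"no usable reactions for amplicon {amp}")
        out[amp] = float(np.mean(es))
    return out, excluded


def relative_quantity(cq_sample: float, cq_calibrator: float, E: float) -> float:
    """RQ = E^(Cq_calibrator - Cq_sample)."""
    if E <= 1:
        raise ValueError(f"efficiency must exceed 1, got {E}")
    return E ** (cq_calibrator - cq_sample)


@dataclass
class DosageResult:
    table: pd.DataFrame  # per sample: copy_number, sem, n_reps
    stability_M: dict[str, float]
    stability_CV: float
    flagged_samples: list[str]


def _mean_cq(plate: pd.DataFrame) -> pd.DataFrame:
    return (
        plate.groupby(["sample_id", "target_amplicon"])["Cq"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )


def normalized_dosage(
    plate: pd.DataFrame,
    efficiencies: dict[str, float],
    target: str,
    references: list[str],
    calibrator: str,
    calibrator_copies: float = 1.0,
) -> DosageResult:
    """Relative gene copy number per sample.

    Per sample, the target's relative quantity (vs the calibrator, with
    the amplicon's mean efficiency) is divided by the geometric mean of
    the reference-amplicon relative quantities, then scaled so the
    calibrator genome equals its known copy count. The s.e.m. over
    technical replicates of the target Cq is propagated through
    E^(dCq +/- sem). Samples missing a reference are flagged, not
    dropped silently.
    """
    if len(references) < 2:
        raise ValueError("need at least two reference amplicons")
    cal_cq = (
        plate[plate.sample_id == calibrator]
        .groupby("target_amplicon")["Cq"]
        .mean()
        .to_dict()
    )
    for amp in [target, *references]:
        if amp not in cal_cq:
            raise ValueError(f"calibrator has no reactions for amplicon {amp}")
    rows = []
    flagged = []
    ref_rq: dict[str, dict[str, float]] = {r: {} for r in references}
    stats = _mean_cq(plate)
    for sample in sorted(plate.sample_id.unique()):
        sub = stats[stats.sample_id == sample].set_index("target_amplicon")
        if target not in sub.index:
            flagged.append(sample)
            continue
        rqs = {}
        missing = False
        for amp in [target, *references]:
            if amp not in sub.index:
                missing = True
                continue
            rqs[amp] = relative_quantity(
                sub.loc[amp, "mean"], cal_cq[amp], efficiencies[amp]
            )
        if missing:
            flagged.append(sample)
            continue
        for r in references:
            ref_rq[r][sample] = rqs[r]
        nf = float(np.exp(np.mean([math.log(rqs[r]) for r in references])))
        copy = calibrator_copies * rqs[target] / nf
        # sem of target Cq propagated multiplicatively
        sem_cq = float(sub.loc[target, "sem"]) if sub.loc[target, "count"] > 1 else 0.0
        E = efficiencies[target]
        sem = copy * (E**sem_cq - 1.0)
        rows.append(
            dict(
                sample_id=sample,
                copy_number=copy,
                sem=sem,
                n_reps=int(sub.loc[target, "count"]),
            )
        )
    table = pd.DataFrame(rows)
    M, CV = genorm_stability(pd.DataFrame(ref_rq).dropna())
    return DosageResult(
        table=table, stability_M=M, stability_CV=CV, flagged_samples=flagged
    )


def genorm_stability(ref_rq: pd.DataFrame) -> tuple[dict[str, float], float]:
    """geNorm-style reference stability.

    ``ref_rq``: samples x references table of relative quantities.
    V_jk = SD over samples of log2(RQ_j / RQ_k); M_j = mean V_jk over
    k != j. CV = coefficient of variation, over samples, of the
    reference quantities normalized by their per-sample geometric mean,
    averaged over references.
    """
    refs = list(ref_rq.columns)
    if len(refs) < 2:
        raise ValueError("need at least two references")
    if len(ref_rq) < 2:
        raise ValueError("need at least two samples")
    M = {}
    for j in refs:
        vs = []
        for k in refs:
            if k == j:
                continue
            ratio = np.log2(ref_rq[j] / ref_rq[k])
            vs.append(float(np.std(ratio, ddof=1)))
        M[j] = float(np.mean(vs))
    geo = np.exp(np.log(ref_rq).mean(axis=1))
    norm = ref_rq.div(geo, axis=0)
    cvs = norm.std(ddof=1) / norm.mean()
    return M, float(cvs.mean())


def relative_transcript_level(
    cq_target: float,
    cq_target_cal: float,
    cq_ref: float,
    cq_ref_cal: float,
    E_target: float,
    E_ref: float,
) -> float:
    """Efficiency-corrected fold change vs the calibrator sample.

    fold = E_t^(Cq_t,cal - Cq_t) / E_r^(Cq_r,cal - Cq_r): the classical
    two-efficiency ratio with a constitutive reference gene.
    """
    rq_t = relative_quantity(cq_target, cq_target_cal, E_target)
    rq_r = relative_quantity(cq_ref, cq_ref_cal, E_ref)
    return rq_t / rq_r


def transcript_table(
    plate: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
    E_target: float,
    E_ref: float,
) -> pd.DataFrame:
    """Per-sample fold change table from a tidy transcript plate."""
    stats = _mean_cq(plate)
    cal = stats[stats.sample_id == calibrator].set_index("target_amplicon")
    rows = []
    for sample in sorted(plate.sample_id.unique()):
        sub = stats[stats.sample_id == sample].set_index("target_amplicon")
        if target not in sub.index or reference not in sub.index:
            continue
        fold = relative_transcript_level(
            sub.loc[target, "mean"],
            cal.loc[target, "mean"],
            sub.loc[reference, "mean"],
            cal.loc[reference, "mean"],
            E_target,
            E_ref,
        )
        sem_cq = float(sub.loc[target, "sem"]) if sub.loc[target, "count"] > 1 else 0.0
        rows.append(
            dict(
                sample_id=sample,
                fold_change=fold,
                sem=fold * (E_target**sem_cq - 1.0),
                n_reps=int(sub.loc[target, "count"]),
            )
        )
    return pd.DataFrame(rows)
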