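"""Per-segment diversity and neutrality statistics.

Implements from first principles the quantities behind a segment-wise
selective-sweep scan: nucleotide diversity pi, segregating sites S, total
and singleton mutation counts (eta, eta_s), Watterson's theta, Tajima's D,
Fu & Li's outgroup-free D* and F* (Simonsen-corrected variance constants,
eta-based), Jukes-Cantor divergence K, the per-segment diversity profile,
and the divergence-on-diversity regression.

All per-site statistics are computed on the complete-deletion masked
alignment; pi is reported uncorrected by default (a Jukes-Cantor-corrected
variant is exposed separately) and in per-mil in profile tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segments import (
    GAP,
    N_CODE,
    SegmentAlignment,
    complete_deletion_mask,
    materialize_inferred_alleles,
)


def _masked_matrix(aln: SegmentAlignment) -> np.ndarray:
    masked, _ = complete_deletion_mask(aln)
    return masked.matrix()


def mean_pairwise_differences(m: np.ndarray) -> float:
    """Mean number of differing sites over all sequence pairs (k-bar)."""
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0
    # column-wise allele counting: sum_{i<j} d_ij = sum_cols [C(n,2) - sum_a C(n_a,2)]
    npairs = n * (n - 1) // 2
    for col in m.T:
        counts = np.bincount(col, minlength=6)
        same = sum(c * (c - 1) // 2 for c in counts)
        total += npairs - same
    return total / npairs


def nucleotide_diversity(aln: SegmentAlignment, jc_correct: bool = False) -> float:
    """Per-site nucleotide diversity pi on the masked alignment.

    With ``jc_correct`` the mean pairwise p-distance is passed through the
    Jukes-Cantor multiple-hit correction before averaging.
    """
    m = _masked_matrix(aln)
    if m.shape[0] < 2:
        raise ValueError("need at least two sequences for pi")
    L = m.shape[1]
    if not jc_correct:
        return mean_pairwise_differences(m) / L
    n = m.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(m[i] != m[j]))
            tot += jukes_cantor_distance(p)
    return tot / (n * (n - 1) / 2)


def site_counts(aln: SegmentAlignment) -> tuple[int, int, int]:
    """(S, eta, eta_s) on the masked alignment.

    S = polymorphic columns; eta = total mutations, summing (alleles - 1)
    per column; eta_s = variants carried by exactly one sequence.
    """
    m = _masked_matrix(aln)
    S = eta = eta_s = 0
    for col in m.T:
        counts = np.bincount(col, minlength=6)[:4]
        alleles = int((counts > 0).sum())
        if alleles > 1:
            S += 1
            eta += alleles - 1
            # singleton variants: alleles seen once; one allele per column
            # is the (putatively ancestral) background, so at most
            # alleles-1 of them count as mutations
            once = int((counts == 1).sum())
            eta_s += min(once, alleles - 1)
    return S, eta, eta_s


def watterson_theta(aln: SegmentAlignment) -> float:
    """Watterson's per-site theta, S / (a1 * L)."""
    m = _masked_matrix(aln)
    n, L = m.shape
    S, _, _ = site_counts(aln)
    a1 = harmonic(n - 1)
    return S / (a1 * L)


def harmonic(k: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, k + 1)))


def tajimas_D(aln: SegmentAlignment) -> float:
    """Tajima's D from k-bar and S with the standard variance constants.

    Returns NaN when S = 0 (statistic undefined).
    """
    m = _masked_matrix(aln)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    S, _, _ = site_counts(aln)
    if S == 0:
        return math.nan
    kbar = mean_pairwise_differences(m)
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(u_D*, v_D*, u_F*, v_F*) variance constants, Simonsen-corrected."""
    an = harmonic(n - 1)
    bn = harmonic(n - 1, 2)
    an1 = an + 1.0 / n
    if n == 2:
        cn = 1.0
    else:
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    v_Dstar = (
        (n / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    u_Dstar = (n / (n - 1)) * (an - n / (n - 1)) - v_Dstar
    v_Fstar = (
        dn
        + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        - (2 / (n - 1)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    u_Fstar = (
        n / (n - 1)
        + (n + 1) / (3 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / an - v_Fstar
    return u_Dstar, v_Dstar, u_Fstar, v_Fstar


def fu_li_D_star_F_star(aln: SegmentAlignment) -> tuple[float, float]:
    """Fu & Li's outgroup-free D* and F*, using eta and eta_s.

    D* contrasts total mutations against singletons; F* contrasts mean
    pairwise differences against singletons. (NaN, NaN) when S = 0.
    """
    m = _masked_matrix(aln)
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least three sequences for D*/F*")
    S, eta, eta_s = site_counts(aln)
    if S == 0:
        return math.nan, math.nan
    an = harmonic(n - 1)
    kbar = mean_pairwise_differences(m)
    uD, vD, uF, vF = _fu_li_constants(n)
    Dstar = (n / (n - 1) * eta - an * eta_s) / math.sqrt(uD * eta + vD * eta**2)
    Fstar = (kbar - (n - 1) / n * eta_s) / math.sqrt(uF * eta + vF * eta**2)
    return Dstar, Fstar


def jukes_cantor_distance(p: float) -> float:
    """K = -(3/4) ln(1 - 4p/3); undefined at p >= 0.75."""
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p = {p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_K(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """JC-corrected divergence between two groups of aligned sequences.

    The mean per-site mismatch over all between-group pairs (on columns
    free of gaps/Ns in the pair) is corrected once.
    """
    phat_sum = 0.0
    npairs = 0
    for x in np.atleast_2d(group_a):
        for y in np.atleast_2d(group_b):
            ok = (x != GAP) & (y != GAP) & (x != N_CODE) & (y != N_CODE)
            if not ok.any():
                continue
            phat_sum += float(np.mean(x[ok] != y[ok]))
            npairs += 1
    if npairs == 0:
        raise ValueError("no comparable between-group pairs")
    return jukes_cantor_distance(phat_sum / npairs)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    F_stat: float
    df: tuple[int, int]
    p_value: float


def diversity_profile(
    panel: list[SegmentAlignment],
    outgroup: dict[str, np.ndarray] | None = None,
    materialize_homozygotes: bool = True,
) -> pd.DataFrame:
    """Per-segment statistics table ordered along the region.

    One row per segment: n, L, S, eta, eta_s, pi (per-mil), theta_w
    (per-mil), Tajima's D, Fu & Li's D* and F*, and JC divergence K against
    ``outgroup`` sequences (keyed by segment id) when provided. Multi-copy
    segments are flagged: their pooled diversity mixes paralogs.
    """
    if not panel:
        raise ValueError("empty panel")
    rows = []
    for aln in sorted(panel, key=lambda a: a.segment.order_index):
        if materialize_homozygotes:
            aln = materialize_inferred_alleles(aln)
        masked, _ = complete_deletion_mask(aln)
        m = masked.matrix()
        S, eta, eta_s = site_counts(masked)
        pi = nucleotide_diversity(masked)
        rec = dict(
            segment=aln.segment.id,
            region_role=aln.segment.region_role,
            multicopy=aln.segment.is_multicopy,
            offset_bp=aln.segment.approx_offset_bp,
            n=m.shape[0],
            L=m.shape[1],
            S=S,
            eta=eta,
            eta_s=eta_s,
            pi_permil=pi * 1000,
            theta_w_permil=watterson_theta(masked) * 1000,
            tajima_D=tajimas_D(masked),
        )
        rec["fuli_Dstar"], rec["fuli_Fstar"] = (
            fu_li_D_star_F_star(masked) if m.shape[0] >= 3 else (math.nan, math.nan)
        )
        if outgroup is not None and aln.segment.id in outgroup:
            og = np.atleast_2d(outgroup[aln.segment.id])
            try:
                rec["K_vs_outgroup"] = jukes_cantor_K(m, og[:, : m.shape[1]])
            except ValueError:
                rec["K_vs_outgroup"] = math.nan
        else:
            rec["K_vs_outgroup"] = math.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def regress_K_on_pi(table: pd.DataFrame) -> RegressionResult:
    """OLS of between-taxon divergence K on within-taxon diversity pi.

    Under shared ancestral polymorphism and neutral divergence the two are
    positively correlated across segments; the fit is reported with the
    F(1, n-2) test of the slope.
    """
    sub = table.dropna(subset=["K_vs_outgroup", "pi_permil"])
    if len(sub) < 3:
        raise ValueError("need at least three segments with defined K and pi")
    x = sub["pi_permil"].to_numpy(float)
    y = sub["K_vs_outgroup"].to_numpy(float)
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    R2 = 0.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    R2 = min(max(R2, 0.0), 1.0)
    if R2 >= 1.0:
        F = math.inf
        p = 0.0
    else:
        F = (R2 / (1 - R2)) * (n - 2)
        p = float(sps.f.sf(F, 1, n - 2))
    return RegressionResult(float(slope), float(intercept), R2, F, (1, n - 2), p)


def percent_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage between two sequences.

    Returns (identity %, coverage %): identity over aligned non-gap columns,
    coverage of those columns relative to the shorter input.
    """
    from Bio import Align

    if not a or not b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-0.5,
    )
    alignment = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
    sa, sb = alignment[0], alignment[1]
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not pairs:
        return 0.0, 0.0
    ident = sum(x == y for x, y in pairs) / len(pairs) * 100
    cov = len(pairs) / min(len(a.replace("-", "")), len(b.replace("-", ""))) * 100
    return ident, cov
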