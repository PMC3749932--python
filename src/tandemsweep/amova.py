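"""Hierarchical analysis of molecular variance (AMOVA).

Three-level nested design: geographic regions / collection sites within
regions / alleles within sites. Sums of squared pairwise distances are
partitioned Excoffier-style into method-of-moments variance components
and Phi-statistics, with permutation tests per level. Distances are the
weighted difference counts used throughout (transitions = transversions =
1, deletions = 0). Alleles (two per diploid individual) are the units.

Negative component estimates are reported as-is with a flag; percentages
are computed on the raw components (truncation at zero is available as an
option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class AmovaResult:
    sigma2_among_regions: float
    sigma2_among_sites: float  # among sites within regions
    sigma2_within_sites: float
    pct_among_regions: float
    pct_among_sites: float
    pct_within_sites: float
    phi_CT: float  # regions / total
    phi_SC: float  # sites / within-region
    phi_ST: float  # sites+regions / total
    ss_total: float
    ss_levels: tuple[float, float, float]
    df: tuple[int, int, int]
    negative_components: bool
    p_values: dict | None = None
    n_permutations: int = 0


def _ssd_within_groups(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of squared distances within) / group size."""
    tot = 0.0
    for idx in groups:
        if len(idx) == 0:
            continue
        sub = d2[np.ix_(idx, idx)]
        tot += sub.sum() / (2.0 * len(idx))
    return tot


def amova_fit(
    d: np.ndarray,
    regions: np.ndarray,
    sites: np.ndarray,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Variance components and Phi-statistics from a distance matrix.

    ``d`` is the (n x n) pairwise distance matrix between alleles;
    ``regions`` and ``sites`` are per-allele labels (sites nested in
    regions). Squared distances enter the sums of squares.
    """
    regions = np.asarray(regions)
    sites = np.asarray(sites)
    n = d.shape[0]
    if len(set(zip(regions, sites))) < 2 or len(set(regions)) < 2:
        raise ValueError("need >=2 regions and >=2 sites for the nested design")
    d2 = np.asarray(d, dtype=float) ** 2

    region_labels = sorted(set(regions))
    site_labels = sorted(set(zip(regions, sites)))
    G = len(region_labels)
    S = len(site_labels)

    all_idx = [np.arange(n)]
    region_idx = [np.nonzero(regions == r)[0] for r in region_labels]
    site_idx = [
        np.nonzero((regions == r) & (sites == s))[0] for r, s in site_labels
    ]

    ss_total = _ssd_within_groups(d2, all_idx)
    ss_within_regions = _ssd_within_groups(d2, region_idx)
    ss_within_sites = _ssd_within_groups(d2, site_idx)
    ss_ag = ss_total - ss_within_regions  # among regions
    ss_ap = ss_within_regions - ss_within_sites  # among sites within regions
    ss_wp = ss_within_sites

    df_ag, df_ap, df_wp = G - 1, S - G, n - S
    ms_ag = ss_ag / df_ag if df_ag else math.nan
    ms_ap = ss_ap / df_ap if df_ap else math.nan
    ms_wp = ss_wp / df_wp if df_wp else math.nan

    # unequal-size coefficients (method of moments, standard nested design)
    site_sizes = np.array([len(ix) for ix in site_idx], dtype=float)
    region_sizes = np.array([len(ix) for ix in region_idx], dtype=float)
    sizes_by_region = {
        r: np.array(
            [len(site_idx[k]) for k, (rr, _) in enumerate(site_labels) if rr == r],
            dtype=float,
        )
        for r in region_labels
    }
    n1 = (n - sum((sz**2).sum() / sz.sum() for sz in sizes_by_region.values())) / (
        S - G
    )
    n2 = (
        sum((sz**2).sum() / sz.sum() for sz in sizes_by_region.values())
        - (site_sizes**2).sum() / n
    ) / (G - 1)
    n3 = (n - (region_sizes**2).sum() / n) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap else math.nan
    if math.isnan(sigma_b):
        sigma_b = 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3

    negative = (sigma_a < 0) or (sigma_b < 0)
    if truncate_negative:
        sigma_a, sigma_b = max(sigma_a, 0.0), max(sigma_b, 0.0)
    total = sigma_a + sigma_b + sigma_c
    pct = lambda x: 100.0 * x / total if total != 0 else math.nan

    phi_CT = sigma_a / total if total else math.nan
    denom_sc = sigma_b + sigma_c
    phi_SC = sigma_b / denom_sc if denom_sc else math.nan
    phi_ST = (sigma_a + sigma_b) / total if total else math.nan

    return AmovaResult(
        sigma2_among_regions=float(sigma_a),
        sigma2_among_sites=float(sigma_b),
        sigma2_within_sites=float(sigma_c),
        pct_among_regions=pct(sigma_a),
        pct_among_sites=pct(sigma_b),
        pct_within_sites=pct(sigma_c),
        phi_CT=float(phi_CT),
        phi_SC=float(phi_SC),
        phi_ST=float(phi_ST),
        ss_total=float(ss_total),
        ss_levels=(float(ss_ag), float(ss_ap), float(ss_wp)),
        df=(df_ag, df_ap, df_wp),
        negative_components=negative,
    )


def amova_permute(
    d: np.ndarray,
    regions: np.ndarray,
    sites: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-values for the three Phi-statistics.

    Schemes: Phi_ST — alleles permuted among sites across the whole
    sample; Phi_SC — alleles permuted among sites within their region;
    Phi_CT — whole sites permuted among regions. p = (#perm >= observed
    + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    regions = np.asarray(regions)
    sites = np.asarray(sites)
    obs = amova_fit(d, regions, sites)
    n = len(sites)

    def safe_fit(rg, st):
        try:
            return amova_fit(d, rg, st)
        except ValueError:
            return None

    count = dict(phi_ST=0, phi_SC=0, phi_CT=0)
    site_labels = sorted(set(zip(regions, sites)))
    region_of_site = {s: r for r, s in site_labels}
    for _ in range(n_perm):
        # Phi_ST: shuffle alleles among sites across the whole sample
        # (regions follow their sites)
        perm = rng.permutation(n)
        rr = np.array([region_of_site[s] for s in sites[perm]])
        r1 = safe_fit(rr, sites[perm])
        if r1 and not math.isnan(r1.phi_ST) and r1.phi_ST >= obs.phi_ST:
            count["phi_ST"] += 1
        # Phi_SC: shuffle alleles among sites within each region
        st2 = sites.copy()
        for r in sorted(set(regions)):
            ix = np.nonzero(regions == r)[0]
            st2[ix] = st2[ix][rng.permutation(len(ix))]
        r2 = safe_fit(regions, st2)
        if r2 and not math.isnan(r2.phi_SC) and r2.phi_SC >= obs.phi_SC:
            count["phi_SC"] += 1
        # Phi_CT: shuffle whole sites among regions
        perm_sites = rng.permutation([s for _, s in site_labels])
        new_region_of_site = {
            s: region_of_site[site_labels[k][1]]
            for k, s in enumerate(perm_sites)
        }
        rg3 = np.array([new_region_of_site[s] for s in sites])
        r3 = safe_fit(rg3, sites)
        if r3 and not math.isnan(r3.phi_CT) and r3.phi_CT >= obs.phi_CT:
            count["phi_CT"] += 1
    p = {k: (v + 1) / (n_perm + 1) for k, v in count.items()}
    obs.p_values = p
    obs.n_permutations = n_perm
    return p
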