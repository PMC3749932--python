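"""Raw clone cleaning: Taq-error correction, PCR-chimera removal,
authenticity filtering and zygosity inference.

Sanger-sequenced plasmid clones from one PCR amplicon of one individual are
noisy observations of the individual's true alleles: polymerase
misincorporations appear as private single-clone variants, and template
switches during PCR create single-breakpoint recombinant chimeras between
co-amplified alleles. Cleaning proceeds: cluster identical clones, merge
Taq-error singletons into their source cluster, flag chimeric clusters
against candidate parent alleles, then keep clusters passing the
authenticity rule (same sequence >= 3x in one PCR, or in >= 2 independent
PCRs). Cleaning is deterministic under clone-order permutation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .segments import encode


@dataclass
class CloneObservation:
    """One sequenced clone."""

    clone_id: str
    individual_id: str
    amplicon_id: str
    pcr_replicate_id: int
    sequence: str
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty clone sequence: {self.clone_id}")
        if self.pcr_replicate_id < 1:
            raise ValueError("pcr_replicate_id must be >= 1")
        self.sequence = self.sequence.upper()


@dataclass
class CloneCluster:
    """Clones sharing one candidate allele sequence within one
    individual x amplicon group."""

    individual_id: str
    amplicon_id: str
    sequence: str
    clones: list[CloneObservation] = field(default_factory=list)
    taq_corrections: list[tuple[str, int]] = field(default_factory=list)  # (clone_id, column)
    is_chimera: bool = False
    chimera_parents: tuple[str, str] | None = None
    chimera_breakpoint: tuple[int, int] | None = None
    low_support: bool = False

    @property
    def support(self) -> int:
        return len(self.clones)

    @property
    def support_by_pcr(self) -> dict[int, int]:
        return dict(
            sorted(Counter(c.pcr_replicate_id for c in self.clones).items())
        )

    @property
    def authentic(self) -> bool:
        by_pcr = self.support_by_pcr
        return max(by_pcr.values()) >= 3 or len(by_pcr) >= 2


@dataclass
class CleaningReport:
    n_input_clones: int
    n_chimeras_removed: int
    n_taq_corrections: int
    retained: list[CloneCluster]
    rejected: list[CloneCluster]  # survived chimera removal but not authentic

    @property
    def chimera_fraction(self) -> float:
        return (
            self.n_chimeras_removed / self.n_input_clones
            if self.n_input_clones
            else 0.0
        )


def cluster_clones(clones: list[CloneObservation]) -> dict[tuple[str, str], list[CloneCluster]]:
    """Group clones by individual x amplicon and cluster identical sequences.

    Clusters are returned sorted by (support desc, sequence) so all later
    steps are order-independent.
    """
    groups: dict[tuple[str, str], dict[str, list[CloneObservation]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for c in clones:
        groups[(c.individual_id, c.amplicon_id)][c.sequence].append(c)
    out: dict[tuple[str, str], list[CloneCluster]] = {}
    for key, by_seq in groups.items():
        clusters = [
            CloneCluster(key[0], key[1], seq, sorted(cs, key=lambda c: c.clone_id))
            for seq, cs in by_seq.items()
        ]
        clusters.sort(key=lambda cl: (-cl.support, cl.sequence))
        out[key] = clusters
    return out


def correct_taq_errors(
    clusters: list[CloneCluster],
    all_groups: dict[tuple[str, str], list[CloneCluster]] | None = None,
    max_taq_mismatches: int = 2,
) -> list[CloneCluster]:
    """Merge clone clusters explainable as Taq errors of a larger cluster.

    A singleton cluster is merged into a better-supported cluster of the
    same group when it differs only at positions where its variant is
    observed in no other clone of the group (sole-observer positions) and
    at no more than ``max_taq_mismatches`` positions: one or two private
    mismatches in a single clone are far more plausible as polymerase
    errors than as an unsampled allele. Larger divergence is retained and
    flagged low-support instead.
    """
    if not clusters:
        return []
    L = len(clusters[0].sequence)
    # per-column variant observation counts (in clones, not clusters)
    obs = np.zeros((L, 6), dtype=int)
    mats = {id(cl): encode(cl.sequence) for cl in clusters}
    for cl in clusters:
        m = mats[id(cl)]
        for col in range(L):
            obs[col, m[col]] += cl.support

    merged: list[CloneCluster] = []
    pending = sorted(clusters, key=lambda cl: (-cl.support, cl.sequence))
    for cl in pending:
        target = None
        if cl.support == 1:
            m = mats[id(cl)]
            for big in merged:
                if big.support < 2:
                    continue
                mb = mats[id(big)]
                diff = np.nonzero(m != mb)[0]
                if 0 < len(diff) <= max_taq_mismatches and all(
                    obs[d, m[d]] == 1 for d in diff
                ):
                    target = (big, diff)
                    break
        if target is None:
            merged.append(cl)
        else:
            big, diff = target
            clone = cl.clones[0]
            big.clones.append(clone)
            big.clones.sort(key=lambda c: c.clone_id)
            big.taq_corrections.extend((clone.clone_id, int(d)) for d in diff)
    for cl in merged:
        if cl.support == 1:
            cl.low_support = True
    merged.sort(key=lambda cl: (-cl.support, cl.sequence))
    return merged


def detect_chimera(
    clone_seq: str,
    parents: dict[str, str],
    min_flank_sites: int = 2,
    ignore_positions: np.ndarray | None = None,
) -> dict:
    """Test one sequence for a single-breakpoint PCR chimera of two parents.

    The clone is chimeric iff it matches no parent exactly, but for some
    ordered parent pair (A, B) its prefix matches A and suffix matches B
    with zero mismatches, with at least ``min_flank_sites`` A/B-diagnostic
    sites on each flank (one flanking site is indistinguishable from a Taq
    singleton). The breakpoint is reported as the open interval between the
    last A-diagnostic and the first B-diagnostic site (0-based columns).

    ``ignore_positions`` (columns carrying the clone's private Taq-like
    variants) are excluded from all comparisons, so a chimera that also
    picked up a polymerase error remains detectable.
    """
    result = dict(is_chimera=False, parent_pair=None, breakpoint_interval=None, assessable=True)
    if len(parents) < 2:
        result["assessable"] = False
        return result
    m = encode(clone_seq)
    keep = np.ones(len(m), dtype=bool)
    if ignore_positions is not None and len(ignore_positions):
        keep[np.asarray(ignore_positions, dtype=int)] = False
    enc = {name: encode(seq) for name, seq in parents.items()}
    for name, pv in enc.items():
        if pv.shape == m.shape and np.array_equal(pv[keep], m[keep]):
            return result
    names = sorted(enc)
    for ia in names:
        for ib in names:
            if ia == ib:
                continue
            pa, pb = enc[ia], enc[ib]
            if pa.shape != m.shape or pb.shape != m.shape:
                continue
            diag = np.nonzero((pa != pb) & keep)[0]
            if len(diag) < 2 * min_flank_sites:
                continue
            # at non-diagnostic sites the clone must match both parents
            nondiag = keep.copy()
            nondiag[diag] = False
            if np.any(m[nondiag] != pa[nondiag]):
                continue
            states = np.where(m[diag] == pa[diag], 0, np.where(m[diag] == pb[diag], 1, -1))
            if np.any(states == -1):
                continue
            # valid iff pattern is A..AB..B with >= min_flank on each side
            k = int(np.sum(states == 0))
            if (
                k >= min_flank_sites
                and len(states) - k >= min_flank_sites
                and np.all(states[:k] == 0)
                and np.all(states[k:] == 1)
            ):
                return dict(
                    is_chimera=True,
                    parent_pair=(ia, ib),
                    breakpoint_interval=(int(diag[k - 1]), int(diag[k])),
                    assessable=True,
                )
    return result


def flag_chimeras(
    clusters: list[CloneCluster],
    min_flank_sites: int = 2,
    max_taq_mismatches: int = 2,
) -> None:
    """Flag chimeric clusters in one group, in place.

    Parent candidates are the group's clusters that already satisfy the
    authenticity rule on their own support; chimeras are defined against
    these Taq-corrected alleles. For singleton clusters, up to
    ``max_taq_mismatches`` sole-observer positions (Taq-like noise the
    correction step could not resolve) are masked before assessment.
    """
    parents = {
        f"c{idx}": cl.sequence
        for idx, cl in enumerate(clusters)
        if cl.authentic
    }
    name_to_cluster = {f"c{idx}": cl for idx, cl in enumerate(clusters) if cl.authentic}
    if not parents:
        return
    L = len(next(iter(parents.values())))
    obs = np.zeros((L, 6), dtype=int)
    mats = {}
    for cl in clusters:
        if len(cl.sequence) != L:
            continue
        mats[id(cl)] = encode(cl.sequence)
        for col in range(L):
            obs[col, mats[id(cl)][col]] += cl.support
    for cl in clusters:
        if cl.authentic:
            # reproducibly observed sequences are real alleles by the
            # authenticity rule; EGC can make genuine alleles look
            # recombinant, so they are never re-flagged as chimeras
            continue
        others = {k: v for k, v in parents.items() if name_to_cluster[k] is not cl}
        ignore = None
        if cl.support == 1 and id(cl) in mats:
            mv = mats[id(cl)]
            private = np.nonzero(obs[np.arange(L), mv] == 1)[0]
            if 0 < len(private) <= max_taq_mismatches:
                ignore = private
        res = detect_chimera(cl.sequence, others, min_flank_sites, ignore_positions=ignore)
        if res["is_chimera"]:
            cl.is_chimera = True
            pa, pb = res["parent_pair"]
            cl.chimera_parents = (name_to_cluster[pa].sequence, name_to_cluster[pb].sequence)
            cl.chimera_breakpoint = res["breakpoint_interval"]


def authenticity_filter(
    clusters: list[CloneCluster],
) -> tuple[list[CloneCluster], list[CloneCluster]]:
    """Split non-chimeric clusters into (authentic, rejected)."""
    keep, drop = [], []
    for cl in clusters:
        if cl.is_chimera:
            continue
        (keep if cl.authentic else drop).append(cl)
    return keep, drop


def infer_zygosity(alleles: list[CloneCluster]) -> tuple[str, str, bool]:
    """Allele pair of one individual at a unique (single-locus) segment.

    Two distinct authentic alleles: heterozygote. One: homozygote, the
    second allele inferred (flagged). More than two at a single diploid
    locus indicates contamination or unrecognized paralogy and is an error.
    """
    seqs = sorted({cl.sequence for cl in alleles})
    if len(seqs) == 0:
        raise ValueError("no authentic alleles")
    if len(seqs) == 1:
        return seqs[0], seqs[0], True
    if len(seqs) == 2:
        return seqs[0], seqs[1], False
    raise ValueError(
        f"{len(seqs)} distinct alleles at a unique-copy segment "
        "(max 2 expected for a diploid): contamination or paralogy"
    )


def clean_clones(
    clones: list[CloneObservation],
    max_taq_mismatches: int = 2,
    min_flank_sites: int = 2,
) -> CleaningReport:
    """Full cleaning pass over raw clones, all groups.

    Order of operations: cluster -> Taq-error correction -> chimera
    flagging against corrected authentic alleles -> authenticity filter.
    """
    grouped = cluster_clones(clones)
    retained: list[CloneCluster] = []
    rejected: list[CloneCluster] = []
    n_chim = 0
    n_taq = 0
    for key in sorted(grouped):
        clusters = correct_taq_errors(grouped[key], max_taq_mismatches=max_taq_mismatches)
        n_taq += sum(len(cl.taq_corrections) for cl in clusters)
        flag_chimeras(clusters, min_flank_sites=min_flank_sites)
        n_chim += sum(cl.support for cl in clusters if cl.is_chimera)
        keep, drop = authenticity_filter(clusters)
        retained.extend(keep)
        rejected.extend(drop)
    return CleaningReport(
        n_input_clones=len(clones),
        n_chimeras_removed=n_chim,
        n_taq_corrections=n_taq,
        retained=retained,
        rejected=rejected,
    )
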