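"""Forward-time simulator of a tandem three-copy gene array under
mutation, crossover, ectopic gene conversion (EGC) and a hard sweep.

A diploid Wright-Fisher population carries a 13-segment region (default
600 bp per segment) whose three coding segments are tandem paralogs,
initially identical (the post-duplication state). Each generation applies
fitness-weighted parent sampling within subdivided demes (island-model
migration), meiotic crossover between segment midpoints at a per-kb rate
scaled by the physical segment offsets, finite-sites Jukes-Cantor
mutation, and EGC events that copy a geometric-length tract from one array
copy onto another within the same individual. A beneficial mutation is
injected into the promoter of the third copy and conditioned on fixation
by rerunning from the injection state; sampling occurs shortly after
fixation, emulating a very recent completed sweep.

Every emitted artifact (allele panels, amplicon clones with PCR chimeras
and Taq errors, qPCR plates) is traceable to ground-truth records, so the
cleaning, assignment, statistics and quantification stages can be scored
against the truth.

Defaults are desk-scale study conditions, not a calibrated demographic fit
(see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cleaning import CloneObservation
from .segments import (
    AlleleSequence,
    SegmentAlignment,
    SegmentDef,
    decode,
    default_segment_map,
)

#: order indices of the three paralogous coding segments (S5, S7, S10)
CODING_SEGMENTS = (4, 6, 9)
#: order index of the swept promoter segment (S9, third copy's promoter)
SWEEP_SEGMENT = 8
#: order index of the copy-2 downstream segment (S8)
S8_SEGMENT = 7

DEFAULT_LAYOUT: dict[str, dict[str, int]] = {
    "Harz": {"1": 3, "2": 3},
    "Thuringia": {"6": 3, "7": 3},
    "Japan": {"9": 3},
}


@dataclass
class SimConfig:
    """Study conditions of one simulation run. ``seed`` is mandatory."""

    seed: int
    N: int = 200  # diploid individuals
    seg_len: int = 600
    mu: float = 6.25e-6  # per base per generation (theta = 4*N*mu = 5 per kb)
    r_per_kb: float = 1e-4  # crossover per kb per meiosis
    g: float = 5e-4  # EGC initiations per copy per generation
    tract_mean: float = 400.0  # mean conversion tract (geometric)
    s: float = 0.2  # selection coefficient, additive (2Ns = 80, strong sweep)
    sweep_target: str = "S9"
    burn_in: int | None = None  # default 10*N
    post_sweep_gens: int = 20
    migration: float = 0.1
    sample_layout: dict[str, dict[str, int]] = field(
        default_factory=lambda: {r: dict(s) for r, s in DEFAULT_LAYOUT.items()}
    )
    sweep: bool = True
    max_fixation_attempts: int = 200
    # amplicon sequencing emulation
    p_chim: float = 0.05
    taq_rate: float = 2e-4
    s8_overlap: int = 200
    clones_per_pcr_unique: int = 6
    n_pcr_unique: int = 2
    clones_per_pcr_coding: int = 19
    n_pcr_coding: int = 3
    # qPCR emulation
    sigma_Cq: float = 0.15
    n_tech_reps: int = 16

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class SampledIndividual:
    individual_id: str
    site_id: str
    region_id: str
    hap0: np.ndarray  # full-region haplotype, uint8 codes 0..3
    hap1: np.ndarray


@dataclass
class SimResult:
    config: SimConfig
    segments: list[SegmentDef]
    sample: list[SampledIndividual]
    egc_events: list[dict]
    sweep_fixation_gen: int | None
    sweep_attempts: int

    def seg_slice(self, order_index: int) -> slice:
        L = self.config.seg_len
        return slice(order_index * L, (order_index + 1) * L)


class FixationError(RuntimeError):
    pass


class _Population:
    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.segments = default_segment_map()
        self.n_seg = len(self.segments)
        self.L = cfg.seg_len * self.n_seg
        anc = rng.integers(0, 4, size=self.L).astype(np.uint8)
        sl = cfg.seg_len
        # post-duplication state: the three coding paralogs start identical
        base = anc[CODING_SEGMENTS[0] * sl : (CODING_SEGMENTS[0] + 1) * sl]
        for c in CODING_SEGMENTS[1:]:
            anc[c * sl : (c + 1) * sl] = base
        self.genomes = np.tile(anc, (2 * cfg.N, 1))
        # per-boundary crossover probabilities from physical offsets
        offs = [s.approx_offset_bp for s in self.segments]
        self.r_bound = np.minimum(
            0.5,
            np.diff(offs) / 1000.0 * cfg.r_per_kb,
        )
        # demes follow the sampling layout (one deme per collection site)
        sites = [
            (region, site)
            for region, d in cfg.sample_layout.items()
            for site in d
        ]
        self.demes = sites
        bounds = np.linspace(0, cfg.N, len(sites) + 1).astype(int)
        self.deme_of = np.zeros(cfg.N, dtype=int)
        for d in range(len(sites)):
            self.deme_of[bounds[d] : bounds[d + 1]] = d
        self.deme_members = [np.nonzero(self.deme_of == d)[0] for d in range(len(sites))]
        self.sweep_pos = SWEEP_SEGMENT * sl + sl // 2
        self.benef_state: int | None = None
        self.egc_events: list[dict] = []
        self.gen = 0

    # --- per-generation machinery -------------------------------------

    def _fitness(self) -> np.ndarray:
        if self.benef_state is None:
            return np.ones(self.cfg.N)
        carr = (self.genomes[:, self.sweep_pos] == self.benef_state).astype(float)
        counts = carr[0::2] + carr[1::2]
        return 1.0 + self.cfg.s * counts

    def _choose_parents(self) -> np.ndarray:
        """(N, 2) parent individual indices with migration + selection."""
        cfg, rng = self.cfg, self.rng
        n_demes = len(self.demes)
        pd_ = np.repeat(self.deme_of[:, None], 2, axis=1)
        if n_demes > 1 and cfg.migration > 0:
            mig = rng.random((cfg.N, 2)) < cfg.migration
            shift = rng.integers(1, n_demes, size=(cfg.N, 2))
            pd_ = np.where(mig, (pd_ + shift) % n_demes, pd_)
        w = self._fitness()
        parents = np.empty((cfg.N, 2), dtype=int)
        for d in range(n_demes):
            members = self.deme_members[d]
            sel = pd_ == d
            k = int(sel.sum())
            if k == 0:
                continue
            wd = w[members]
            parents[sel] = rng.choice(members, size=k, p=wd / wd.sum())
        return parents

    def step(self) -> None:
        cfg, rng, sl = self.cfg, self.rng, self.cfg.seg_len
        parents = self._choose_parents()  # (N, 2)
        # gametes: per child haplotype, source homolog per segment
        start = rng.integers(0, 2, size=(cfg.N, 2))
        switch = rng.random((cfg.N, 2, self.n_seg - 1)) < self.r_bound
        homolog = np.concatenate(
            [start[..., None], np.zeros((cfg.N, 2, self.n_seg - 1), dtype=int)],
            axis=2,
        )
        homolog[..., 1:] = switch
        homolog = np.cumsum(homolog, axis=2) % 2
        # interleave: child hap 2i from parent column 0, 2i+1 from column 1
        src = np.empty((2 * cfg.N, self.n_seg), dtype=int)
        src[0::2] = (2 * parents[:, 0, None] + homolog[:, 0, :])
        src[1::2] = (2 * parents[:, 1, None] + homolog[:, 1, :])
        new = np.empty_like(self.genomes)
        for sidx in range(self.n_seg):
            cols = slice(sidx * sl, (sidx + 1) * sl)
            new[:, cols] = self.genomes[src[:, sidx], cols]
        self.genomes = new
        # finite-sites Jukes-Cantor mutation
        n_mut = rng.poisson(2 * cfg.N * self.L * cfg.mu)
        if n_mut:
            rr = rng.integers(0, 2 * cfg.N, size=n_mut)
            cc = rng.integers(0, self.L, size=n_mut)
            delta = rng.integers(1, 4, size=n_mut).astype(np.uint8)
            self.genomes[rr, cc] = (self.genomes[rr, cc] + delta) % 4
        # ectopic gene conversion among the array copies
        n_egc = rng.poisson(2 * cfg.N * len(CODING_SEGMENTS) * cfg.g)
        for _ in range(n_egc):
            hap = int(rng.integers(0, 2 * cfg.N))
            rc, dc = rng.choice(len(CODING_SEGMENTS), size=2, replace=False)
            donor_hap = 2 * (hap // 2) + int(rng.integers(0, 2))
            # tract start may lie upstream of the segment (tracts can enter
            # from flanking homology and cover the whole segment)
            lead = int(3 * cfg.tract_mean)
            s0 = int(rng.integers(-lead, sl))
            tlen = int(rng.geometric(1.0 / cfg.tract_mean))
            s1 = min(sl, s0 + tlen)
            s0 = max(0, s0)
            if s1 <= s0:
                continue
            roff = CODING_SEGMENTS[rc] * sl
            doff = CODING_SEGMENTS[dc] * sl
            self.genomes[hap, roff + s0 : roff + s1] = self.genomes[
                donor_hap, doff + s0 : doff + s1
            ]
            self.egc_events.append(
                dict(
                    gen=self.gen,
                    recipient_hap=hap,
                    donor_copy=int(dc),
                    recipient_copy=int(rc),
                    tract=(s0, s1),
                )
            )
        self.gen += 1

    # --- sweep ---------------------------------------------------------

    def benef_freq(self) -> int:
        if self.benef_state is None:
            return 0
        return int(np.sum(self.genomes[:, self.sweep_pos] == self.benef_state))

    def run_sweep(self) -> tuple[int, int]:
        """Inject the beneficial allele and condition on fixation.

        Reruns from the injection state with fresh randomness until the
        derived allele fixes. Returns (fixation generation, attempts).
        """
        cfg = self.cfg
        saved = self.genomes.copy()
        saved_gen = self.gen
        cap = saved_gen + int(40 / cfg.s * math.log(2 * cfg.N) + 10 * cfg.N)
        for attempt in range(1, cfg.max_fixation_attempts + 1):
            self.genomes = saved.copy()
            self.gen = saved_gen
            hap = int(self.rng.integers(0, 2 * cfg.N))
            anc = int(self.genomes[hap, self.sweep_pos])
            self.benef_state = (anc + 1) % 4
            # set every haplotype's site to the ancestral state first so the
            # derived state is unique to the injected copy
            self.genomes[:, self.sweep_pos] = anc
            self.genomes[hap, self.sweep_pos] = self.benef_state
            while True:
                self.step()
                f = self.benef_freq()
                if f == 0 or self.gen > cap:
                    break
                if f == 2 * cfg.N:
                    return self.gen, attempt
        raise FixationError(
            f"beneficial allele did not fix in {cfg.max_fixation_attempts} attempts"
        )


def simulate_population(config: SimConfig) -> SimResult:
    """Run the full scenario and sample individuals per the layout."""
    rng = np.random.default_rng(config.seed)
    pop = _Population(config, rng)
    burn = config.burn_in if config.burn_in is not None else 10 * config.N
    for _ in range(burn):
        pop.step()
    fix_gen = None
    attempts = 0
    if config.sweep:
        fix_gen, attempts = pop.run_sweep()
        for _ in range(config.post_sweep_gens):
            pop.step()
    # hierarchical sampling: per collection site (deme), the configured
    # number of individuals
    sample: list[SampledIndividual] = []
    for d, (region, site) in enumerate(pop.demes):
        want = config.sample_layout[region][site]
        members = pop.deme_members[d]
        chosen = rng.choice(members, size=want, replace=False)
        for k, ind in enumerate(sorted(int(i) for i in chosen), start=1):
            sample.append(
                SampledIndividual(
                    individual_id=f"{site}.{k}",
                    site_id=site,
                    region_id=region,
                    hap0=pop.genomes[2 * ind].copy(),
                    hap1=pop.genomes[2 * ind + 1].copy(),
                )
            )
    return SimResult(
        config=config,
        segments=pop.segments,
        sample=sample,
        egc_events=pop.egc_events,
        sweep_fixation_gen=fix_gen,
        sweep_attempts=attempts,
    )


# --- artifact emission -------------------------------------------------


def allele_panel(result: SimResult) -> list[SegmentAlignment]:
    """Ground-truth per-segment allele panel (both alleles per individual).

    Multi-copy coding segments are pooled across the three paralogs, as in
    joint PCR amplification of all copies. The S8 amplicon is emitted as
    the copy-2 coding 3' overlap plus the S8 segment proper.
    """
    cfg = result.config
    panel = []
    for seg in result.segments:
        rows = []
        if seg.order_index in CODING_SEGMENTS:
            continue  # pooled below
        for ind in result.sample:
            for h, hap in enumerate((ind.hap0, ind.hap1)):
                seq = _amplicon_sequence(result, hap, seg.order_index)
                rows.append(
                    AlleleSequence(
                        individual_id=ind.individual_id,
                        site_id=ind.site_id,
                        region_id=ind.region_id,
                        segment_id=seg.id,
                        sequence=seq,
                        allele_name=f"{seg.id}_{ind.individual_id}-{h}",
                    )
                )
        panel.append(SegmentAlignment(seg, rows))
    # pooled coding segments: one alignment per coding segment id, carrying
    # that copy's alleles (used per-copy), plus a pooled alignment under S5
    # handled by callers via coding_haplotypes()
    for cidx in CODING_SEGMENTS:
        seg = result.segments[cidx]
        rows = []
        for ind in result.sample:
            for h, hap in enumerate((ind.hap0, ind.hap1)):
                rows.append(
                    AlleleSequence(
                        individual_id=ind.individual_id,
                        site_id=ind.site_id,
                        region_id=ind.region_id,
                        segment_id=seg.id,
                        sequence=decode(hap[result.seg_slice(cidx)]),
                        allele_name=f"{seg.id}_{ind.individual_id}-{h}",
                    )
                )
        panel.append(SegmentAlignment(seg, rows))
    panel.sort(key=lambda a: a.segment.order_index)
    return panel


def _amplicon_sequence(result: SimResult, hap: np.ndarray, order_index: int) -> str:
    cfg = result.config
    if order_index == S8_SEGMENT:
        ov = cfg.s8_overlap
        s7 = hap[result.seg_slice(CODING_SEGMENTS[1])]
        s8 = hap[result.seg_slice(S8_SEGMENT)]
        return decode(np.concatenate([s7[-ov:], s8]))
    return decode(hap[result.seg_slice(order_index)])


def coding_haplotypes(result: SimResult) -> pd.DataFrame:
    """True coding-segment alleles: one row per individual x copy x homolog.

    Columns: individual_id, copy (HMA4-1/-2/-3), homolog, sequence.
    """
    from .segments import COPIES

    rows = []
    for ind in result.sample:
        for h, hap in enumerate((ind.hap0, ind.hap1)):
            for ci, cidx in enumerate(CODING_SEGMENTS):
                rows.append(
                    dict(
                        individual_id=ind.individual_id,
                        copy=COPIES[ci],
                        homolog=h,
                        sequence=decode(hap[result.seg_slice(cidx)]),
                    )
                )
    return pd.DataFrame(rows)


def emit_amplicon_clones(
    result: SimResult, rng: np.random.Generator | None = None
) -> list[CloneObservation]:
    """Simulated clone sequencing with PCR chimeras and Taq errors.

    Unique segments amplify the individual's two alleles; the coding-pool
    amplicon co-amplifies all six array alleles. With probability
    ``p_chim`` a clone is replaced by a single-switch chimera of two
    distinct templates from the same PCR; Taq errors hit each clone at
    ``taq_rate`` per base. Truth labels are attached to every clone.
    """
    cfg = result.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    clones: list[CloneObservation] = []
    uid = 0
    for ind in result.sample:
        amplicons: list[tuple[str, list[str], int, int]] = []
        for seg in result.segments:
            if seg.order_index in CODING_SEGMENTS:
                continue
            templates = [
                _amplicon_sequence(result, hap, seg.order_index)
                for hap in (ind.hap0, ind.hap1)
            ]
            amplicons.append(
                (seg.id, templates, cfg.n_pcr_unique, cfg.clones_per_pcr_unique)
            )
        pool = [
            decode(hap[result.seg_slice(cidx)])
            for hap in (ind.hap0, ind.hap1)
            for cidx in CODING_SEGMENTS
        ]
        amplicons.append(
            ("S5/S7/S10", pool, cfg.n_pcr_coding, cfg.clones_per_pcr_coding)
        )
        for amp_id, templates, n_pcr, n_clones in amplicons:
            distinct = sorted(set(templates))
            for pcr in range(1, n_pcr + 1):
                for _ in range(n_clones):
                    uid += 1
                    truth: dict = {"is_chimera": False, "taq_error_positions": []}
                    if len(distinct) >= 2 and rng.random() < cfg.p_chim:
                        a, b = rng.choice(len(distinct), size=2, replace=False)
                        ta, tb = distinct[a], distinct[b]
                        k = int(rng.integers(1, len(ta)))
                        seq = ta[:k] + tb[k:]
                        truth.update(
                            is_chimera=True,
                            breakpoint=k,
                            source_haplotype=None,
                            parents=(ta, tb),
                        )
                    else:
                        t = templates[int(rng.integers(0, len(templates)))]
                        seq = t
                        truth["source_haplotype"] = t
                    n_err = rng.poisson(cfg.taq_rate * len(seq))
                    if n_err:
                        arr = list(seq)
                        pos = rng.choice(len(seq), size=min(n_err, len(seq)), replace=False)
                        for p in pos:
                            cur = arr[p]
                            arr[p] = rng.choice([c for c in "ACGT" if c != cur])
                            truth["taq_error_positions"].append(int(p))
                        seq = "".join(arr)
                    clones.append(
                        CloneObservation(
                            clone_id=f"cl{uid:06d}",
                            individual_id=ind.individual_id,
                            amplicon_id=amp_id,
                            pcr_replicate_id=pcr,
                            sequence=seq,
                            truth=truth,
                        )
                    )
    return clones


def emit_qpcr_plates(
    result: SimResult, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(genomic copy-number plate, transcript plate) as tidy DataFrames.

    Genomic assay: target = array coding amplicon (true quantity = 3
    copies in array-carrying samples), references = three single-copy loci,
    calibrator = a single-copy outgroup genome. Transcript assay: target
    normalized to a constitutive reference, calibrator = the outgroup
    sample with 1x expression; array samples express copy number x
    cis-activation (about 50-fold), with lognormal biological scatter.
    Cq = Cq_calibrator - log_E(quantity) + N(0, sigma_Cq).
    """
    cfg = result.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    samples = [ind.individual_id for ind in result.sample]

    amplicons = {
        "HMA4_coding": dict(E=1.92, role="target", base_cq=24.0),
        "FRD3_5p": dict(E=1.90, role="reference", base_cq=25.0),
        "FRD3_3p": dict(E=1.86, role="reference", base_cq=25.5),
        "S13_ref": dict(E=1.94, role="reference", base_cq=24.5),
    }
    rows = []
    well = 0
    for sample_id, copies in [("calibrator", 1.0)] + [(s, 3.0) for s in samples]:
        for amp, info in amplicons.items():
            q = copies if info["role"] == "target" else 1.0
            for rep in range(1, cfg.n_tech_reps + 1):
                well += 1
                cq = (
                    info["base_cq"]
                    - math.log(q) / math.log(info["E"])
                    + rng.normal(0.0, cfg.sigma_Cq)
                )
                rows.append(
                    dict(
                        well=f"W{well:04d}",
                        target_amplicon=amp,
                        sample_id=sample_id,
                        role="calibrator-sample" if sample_id == "calibrator" else info["role"],
                        amplicon_role=info["role"],
                        technical_replicate_id=rep,
                        Cq=cq,
                        true_E=info["E"],
                        true_quantity=q,
                    )
                )
    genomic = pd.DataFrame(rows)

    # transcript assay
    E_target, E_ref = 1.88, 1.90
    rows = []
    well = 0
    for sample_id in ["calibrator"] + samples:
        if sample_id == "calibrator":
            expr = 1.0
        else:
            expr = 50.0 * float(rng.lognormal(0.0, 0.4))
        for amp, E, role, base, q in [
            ("HMA4_cdna", E_target, "target", 22.0, expr),
            ("EF1a", E_ref, "reference", 20.0, 1.0),
        ]:
            for rep in range(1, 4):  # three technical repeats per cDNA
                well += 1
                cq = base - math.log(q) / math.log(E) + rng.normal(0.0, cfg.sigma_Cq)
                rows.append(
                    dict(
                        well=f"T{well:04d}",
                        target_amplicon=amp,
                        sample_id=sample_id,
                        role="calibrator-sample" if sample_id == "calibrator" else role,
                        amplicon_role=role,
                        technical_replicate_id=rep,
                        Cq=cq,
                        true_E=E,
                        true_quantity=q,
                    )
                )
    transcript = pd.DataFrame(rows)
    return genomic, transcript


def synth_amplification_curve(
    E: float,
    quantity: float,
    n_cycles: int = 40,
    baseline: float = 0.01,
    plateau: float = 1.0,
    f0: float = 1e-7,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Saturating qPCR fluorescence curve: baseline + logistic exponential."""
    c = np.arange(1, n_cycles + 1)
    expo = f0 * quantity * E**c
    curve = baseline + expo / (1.0 + expo / plateau)
    if noise > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        curve = curve * (1.0 + rng.normal(0.0, noise, size=n_cycles))
    return curve
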