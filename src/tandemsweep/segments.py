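"""Segment map, allele sequences and alignment containers.

The analysis region is a ~150-kb stretch carrying a tandem triplication of a
heavy-metal ATPase gene (copies HMA4-1/-2/-3), sampled through 13 ordered
amplicon segments S1..S13: distant and flanking single-copy controls, the
three copy-specific promoters, the three near-identical 3' coding portions
(jointly amplified), a copy-2-specific downstream amplicon whose 5' end
overlaps the copy-2 coding frame, and downstream controls.

Coordinates are 0-based half-open internally and 1-based in reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

# nucleotide byte codes used throughout the package
_ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
A, C, G, T, N_CODE, GAP = range(6)

#: paralog labels of the tandem array
COPIES = ("HMA4-1", "HMA4-2", "HMA4-3")


class PanelError(ValueError):
    """Raised for malformed panel inputs (unmapped ids, ragged alignments)."""


@dataclass(frozen=True)
class SegmentDef:
    """One sequenced segment of the region."""

    id: str
    region_role: str  # distant-control | flanking-control | promoter | coding-3prime | downstream
    copy_link: str | None
    copy_class: str  # "unique" | "multi-copy"
    order_index: int
    approx_offset_bp: int

    @property
    def is_multicopy(self) -> bool:
        return self.copy_class == "multi-copy"


def default_segment_map() -> list[SegmentDef]:
    """The 13-segment map of the region, ordered along the chromosome.

    Offsets approximate the published layout: S1 ~116 kb upstream of the
    array, the triplicated array spanning ~150 kb, S13 ~113 kb downstream.
    Multi-copy segments are the three 3' coding portions (S5, S7, S10) and
    the repeated 5' portion of S8.
    """
    rows = [
        ("S1", "distant-control", None, "unique", 0, 0),
        ("S2", "flanking-control", None, "unique", 1, 198_000),
        ("S3", "flanking-control", None, "unique", 2, 218_000),
        ("S4", "promoter", "HMA4-1", "unique", 3, 232_000),
        ("S5", "coding-3prime", "HMA4-1", "multi-copy", 4, 238_000),
        ("S6", "promoter", "HMA4-2", "unique", 5, 268_000),
        ("S7", "coding-3prime", "HMA4-2", "multi-copy", 6, 274_000),
        ("S8", "downstream", "HMA4-2", "multi-copy", 7, 278_000),
        ("S9", "promoter", "HMA4-3", "unique", 8, 303_000),
        ("S10", "coding-3prime", "HMA4-3", "multi-copy", 9, 309_000),
        ("S11", "downstream", "HMA4-3", "unique", 10, 322_000),
        ("S12", "flanking-control", None, "unique", 11, 348_000),
        ("S13", "distant-control", None, "unique", 12, 2_818_000),
    ]
    return [SegmentDef(*r) for r in rows]


def segment_map_to_json(segments: list[SegmentDef]) -> str:
    return json.dumps([vars(s) for s in segments], indent=1)


def segment_map_from_json(text: str) -> list[SegmentDef]:
    return [SegmentDef(**d) for d in json.loads(text)]


@dataclass
class AlleleSequence:
    """One allele sequence of one individual at one segment."""

    individual_id: str  # "site.individual", e.g. "1.1"
    site_id: str
    region_id: str
    segment_id: str
    sequence: str
    inferred_homozygote: bool = False
    allele_name: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()


@dataclass
class SegmentAlignment:
    """Gap-aware multiple alignment of allele sequences for one segment."""

    segment: SegmentDef
    rows: list[AlleleSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) > 1:
            raise PanelError(
                f"ragged alignment for {self.segment.id}: lengths {sorted(lengths)}"
            )
        bad = set("".join(r.sequence for r in self.rows)) - set(_ALPHABET)
        if bad:
            raise PanelError(f"invalid characters in {self.segment.id}: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0].sequence) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix with codes A=0 C=1 G=2 T=3 N=4 gap=5."""
        return encode_alignment([r.sequence for r in self.rows])


# ASCII -> code lookup table, invalid bytes map to 255
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    codes = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(codes == 255)[0][:5]})
        raise ValueError(f"invalid sequence characters: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_ALPHABET[c] for c in codes)


def encode_alignment(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.vstack([encode(s) for s in seqs])


def materialize_inferred_alleles(aln: SegmentAlignment) -> SegmentAlignment:
    """Duplicate single observed alleles of inferred homozygotes.

    Individuals from which only one allele was recovered are treated as
    homozygous; their allele enters diversity statistics twice, and the
    duplicate is flagged (the asterisk convention of the genealogy figures).
    """
    out: list[AlleleSequence] = []
    for r in aln.rows:
        out.append(r)
        if r.inferred_homozygote:
            dup = replace(r)
            dup.allele_name = (r.allele_name or r.individual_id) + "*"
            out.append(dup)
    return SegmentAlignment(aln.segment, out)


def read_fasta_panel(
    fasta_path, metadata, segments: list[SegmentDef] | None = None
) -> list[SegmentAlignment]:
    """Read a per-segment FASTA panel into SegmentAlignments.

    ``metadata`` maps each FASTA record id to its individual, collection
    site, geographic region, segment and homozygote flag. It is either a
    pandas DataFrame or the path of a TSV with columns
    record_id, individual, site, region, segment, homozygote_flag.
    """
    import pandas as pd

    if not hasattr(metadata, "columns"):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str)
    if metadata["record_id"].duplicated().any():
        dup = metadata["record_id"][metadata["record_id"].duplicated()].iloc[0]
        raise PanelError(f"duplicate record_id in metadata: {dup!r}")
    meta = metadata.set_index("record_id")
    segments = segments or default_segment_map()
    segmap = {s.id: s for s in segments}

    per_segment: dict[str, list[AlleleSequence]] = {}
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        if rec.id not in meta.index:
            raise PanelError(f"FASTA record id not in metadata: {rec.id!r}")
        row = meta.loc[rec.id]
        seg_id = str(row["segment"])
        if seg_id not in segmap:
            raise PanelError(f"unknown segment {seg_id!r} for record {rec.id!r}")
        flag = str(row.get("homozygote_flag", "0")).strip().lower()
        per_segment.setdefault(seg_id, []).append(
            AlleleSequence(
                individual_id=str(row["individual"]),
                site_id=str(row["site"]),
                region_id=str(row["region"]),
                segment_id=seg_id,
                sequence=str(rec.seq),
                inferred_homozygote=flag in {"1", "true", "yes"},
                allele_name=rec.id,
            )
        )
    if n_records == 0:
        logger.warning("empty FASTA panel: %s", fasta_path)
        return []
    ordered = sorted(per_segment, key=lambda s: segmap[s].order_index)
    return [SegmentAlignment(segmap[s], per_segment[s]) for s in ordered]


def write_fasta_panel(panel: list[SegmentAlignment], fasta_path, meta_path) -> None:
    """Write a panel back to FASTA + metadata TSV (inverse of read_fasta_panel)."""
    import pandas as pd

    recs = []
    meta_rows = []
    seen: set[str] = set()
    for aln in panel:
        for i, r in enumerate(aln.rows):
            rid = r.allele_name or f"{aln.segment.id}_{r.individual_id}_{i}"
            if rid in seen:
                rid = f"{aln.segment.id}_{rid}"
            seen.add(rid)
            recs.append((rid, r.sequence))
            meta_rows.append(
                dict(
                    record_id=rid,
                    individual=r.individual_id,
                    site=r.site_id,
                    region=r.region_id,
                    segment=r.segment_id,
                    homozygote_flag=int(r.inferred_homozygote),
                )
            )
    with open(fasta_path, "w") as fh:
        for rid, seq in recs:
            fh.write(f">{rid}\n{seq}\n")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def complete_deletion_mask(aln: SegmentAlignment) -> tuple[SegmentAlignment, int]:
    """Restrict an alignment to columns free of gaps and Ns in every row.

    Returns the masked alignment and the number of removed columns. This is
    the complete-deletion convention of the standard diversity software;
    indel information re-enters only via gap recoding in the network module.
    """
    if not aln.rows:
        return aln, 0
    m = aln.matrix()
    keep = ~np.any((m == GAP) | (m == N_CODE), axis=0)
    removed = int((~keep).sum())
    if not keep.any():
        raise PanelError(f"no analyzable sites in {aln.segment.id} after masking")
    rows = [
        replace(r, sequence=decode(m[i, keep])) for i, r in enumerate(aln.rows)
    ]
    return SegmentAlignment(aln.segment, rows), removed


_PURINE = {A, G}


def is_transition(x: int, y: int) -> bool:
    return (x in _PURINE) == (y in _PURINE)


def pairwise_differences(
    a: str | np.ndarray,
    b: str | np.ndarray,
    ts_weight: float = 1.0,
    tv_weight: float = 1.0,
    deletion_weight: float = 0.0,
) -> float:
    """Weighted count of differing columns between two aligned sequences.

    Columns where either sequence has a gap contribute ``deletion_weight``;
    transitions and transversions are weighted separately (both default 1,
    matching the molecular-variance distance convention used downstream).
    Columns with N in either sequence are skipped.
    """
    av = a if isinstance(a, np.ndarray) else encode(a)
    bv = b if isinstance(b, np.ndarray) else encode(b)
    if av.shape != bv.shape:
        raise ValueError(f"unequal sequence lengths: {len(av)} vs {len(bv)}")
    gap = (av == GAP) | (bv == GAP)
    unknown = (av == N_CODE) | (bv == N_CODE)
    diff = (av != bv) & ~gap & ~unknown
    purine_a = (av == A) | (av == G)
    purine_b = (bv == A) | (bv == G)
    ts = diff & (purine_a == purine_b)
    tv = diff & (purine_a != purine_b)
    return (
        ts_weight * int(ts.sum())
        + tv_weight * int(tv.sum())
        + deletion_weight * int(gap.sum())
    )
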