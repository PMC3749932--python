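"""End-to-end orchestration: simulate -> clean -> assign -> stats ->
network -> tree -> amova -> qPCR, over a plain-text file bundle.

Every stage reads and writes TSV/FASTA/JSON only; a run manifest records
the config hash, input checksums and seeds so identical manifests
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova_fit, amova_permute
from .assignment import (
    anchor_from_reference,
    anchor_from_s8,
    problem_from_cleaning,
    shared_haplotype_report,
    solve_assignment,
)
from .cleaning import CloneObservation, clean_clones, infer_zygosity
from .diversity import diversity_profile
from .network import build_network, network_to_edgelist
from .phylogeny import bootstrap_support
from .qpcr import DosageResult, normalized_dosage, transcript_table
from .segments import (
    AlleleSequence,
    SegmentAlignment,
    default_segment_map,
    pairwise_differences,
    encode_alignment,
)
from .simulate import (
    CODING_SEGMENTS,
    SimConfig,
    SimResult,
    allele_panel,
    coding_haplotypes,
    emit_amplicon_clones,
    emit_qpcr_plates,
    simulate_population,
)

logger = logging.getLogger(__name__)

CODING_AMPLICON = "S5/S7/S10"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_simulation_bundle(result: SimResult, outdir: str | Path) -> Path:
    """Write every pipeline input (plus ground truth) for one simulation."""
    from .segments import write_fasta_panel

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json())
    panel = allele_panel(result)
    write_fasta_panel(panel, out / "panel.fasta", out / "panel.tsv")

    clones = emit_amplicon_clones(result)
    with open(out / "clones.fasta", "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id}\n{c.sequence}\n")
    ind_meta = {
        ind.individual_id: (ind.site_id, ind.region_id) for ind in result.sample
    }
    pd.DataFrame(
        [
            dict(
                clone_id=c.clone_id,
                individual=c.individual_id,
                site=ind_meta[c.individual_id][0],
                region=ind_meta[c.individual_id][1],
                amplicon=c.amplicon_id,
                pcr_replicate=c.pcr_replicate_id,
            )
            for c in clones
        ]
    ).to_csv(out / "clones.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(
                clone_id=c.clone_id,
                is_chimera=c.truth["is_chimera"],
                n_taq_errors=len(c.truth["taq_error_positions"]),
            )
            for c in clones
        ]
    ).to_csv(out / "clones_truth.tsv", sep="\t", index=False)
    coding_haplotypes(result).to_csv(out / "coding_truth.tsv", sep="\t", index=False)
    genomic, transcript = emit_qpcr_plates(result)
    genomic.to_csv(out / "qpcr_genomic.tsv", sep="\t", index=False)
    transcript.to_csv(out / "qpcr_transcript.tsv", sep="\t", index=False)
    return out


def read_clones(fasta_path: Path, meta_path: Path) -> tuple[list[CloneObservation], dict]:
    from Bio import SeqIO

    meta = pd.read_csv(meta_path, sep="\t", dtype={"pcr_replicate": int}).set_index(
        "clone_id"
    )
    clones = []
    ind_meta = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        clones.append(
            CloneObservation(
                clone_id=rec.id,
                individual_id=str(row["individual"]),
                amplicon_id=str(row["amplicon"]),
                pcr_replicate_id=int(row["pcr_replicate"]),
                sequence=str(rec.seq),
            )
        )
        ind_meta[str(row["individual"])] = (str(row["site"]), str(row["region"]))
    return clones, ind_meta


def cleaned_panel(
    clones: list[CloneObservation],
    ind_meta: dict[str, tuple[str, str]],
    s8_overlap: int = 200,
):
    """Clean raw clones and rebuild analysis-ready inputs.

    Returns (panel of unique-segment alignments with inferred
    homozygotes flagged, coding sequences per individual, S8 alleles per
    individual, cleaning report).
    """
    report = clean_clones(clones)
    segmap = {s.id: s for s in default_segment_map()}
    by_group: dict[tuple[str, str], list] = {}
    for cl in report.retained:
        by_group.setdefault((cl.individual_id, cl.amplicon_id), []).append(cl)

    rows_per_segment: dict[str, list[AlleleSequence]] = {}
    coding_by_ind: dict[str, list[str]] = {}
    s8_by_ind: dict[str, list[str]] = {}
    for (ind, amp), clusters in sorted(by_group.items()):
        site, region = ind_meta[ind]
        if amp == CODING_AMPLICON:
            coding_by_ind[ind] = sorted({cl.sequence for cl in clusters})
            continue
        a1, a2, inferred = infer_zygosity(clusters)
        if amp == "S8":
            s8_by_ind[ind] = sorted({a1, a2})
        for k, seq in enumerate((a1, a2)):
            rows_per_segment.setdefault(amp, []).append(
                AlleleSequence(
                    individual_id=ind,
                    site_id=site,
                    region_id=region,
                    segment_id=amp,
                    sequence=seq,
                    inferred_homozygote=inferred and k == 1,
                    allele_name=f"{amp}_{ind}-{k}",
                )
            )
    panel = [
        SegmentAlignment(segmap[seg_id], rows)
        for seg_id, rows in sorted(
            rows_per_segment.items(), key=lambda kv: segmap[kv[0]].order_index
        )
    ]
    return panel, coding_by_ind, s8_by_ind, report


def assign_coding(
    coding_by_ind: dict[str, list[str]],
    s8_by_ind: dict[str, list[str]],
    reference_copies: dict[str, str] | None = None,
    s8_overlap: int = 200,
    scope: str = "species",
):
    """Solve paralog assignment for cleaned coding haplotypes."""
    problem, sequences = problem_from_cleaning(coding_by_ind)
    anchors = anchor_from_s8(
        sequences, s8_by_ind, s8_overlap, carried_by=problem.alleles_per_individual
    )
    if reference_copies:
        anchors += anchor_from_reference(sequences, reference_copies)
    problem.anchors = anchors
    solution = solve_assignment(problem, sequences=sequences, scope=scope)
    return solution, sequences


def reference_copies_from_truth(result: SimResult) -> dict[str, str]:
    """Reference coding sequences of known position (a fully sequenced
    accession, as from BAC clones): copies 1 and 3 of the first sampled
    individual's first homolog."""
    truth = coding_haplotypes(result)
    first = truth[
        (truth.individual_id == result.sample[0].individual_id)
        & (truth.homolog == 0)
    ]
    return {
        row["copy"]: row["sequence"]
        for _, row in first.iterrows()
        if row["copy"] in ("HMA4-1", "HMA4-3")
    }


def amova_per_segment(
    panel: list[SegmentAlignment],
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Three-level AMOVA for each unique-class segment of a panel."""
    from .segments import materialize_inferred_alleles

    rows = []
    for aln in panel:
        if aln.segment.is_multicopy:
            continue
        full = materialize_inferred_alleles(aln)
        m = encode_alignment([r.sequence for r in full.rows])
        n = m.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_differences(m[i], m[j], 1, 1, 0)
        regions = np.array([r.region_id for r in full.rows])
        sites = np.array([r.site_id for r in full.rows])
        try:
            res = amova_fit(d, regions, sites)
        except ValueError as err:
            logger.warning("AMOVA skipped for %s: %s", aln.segment.id, err)
            continue
        rec = dict(
            segment=aln.segment.id,
            pct_among_regions=res.pct_among_regions,
            pct_among_sites=res.pct_among_sites,
            pct_within_sites=res.pct_within_sites,
            phi_CT=res.phi_CT,
            phi_SC=res.phi_SC,
            phi_ST=res.phi_ST,
            negative_components=res.negative_components,
        )
        if n_perm:
            p = amova_permute(d, regions, sites, n_perm=n_perm, seed=seed)
            rec.update({f"p_{k}": v for k, v in p.items()})
        rows.append(rec)
    return pd.DataFrame(rows)


def run_all(
    config: SimConfig,
    outdir: str | Path,
    n_perm: int = 200,
    bootstrap_reps: int = 200,
) -> dict:
    """Full pipeline on one simulated bundle; returns the report dict.

    Stages: simulate, write bundle, clean, assign, diversity profile,
    haplotype network, NJ tree of a control segment, per-segment AMOVA,
    copy-number and transcript quantification. Outputs are TSV/JSON in
    ``outdir`` with a manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate_population(config)
    bundle = write_simulation_bundle(result, out / "bundle")

    clones, ind_meta = read_clones(bundle / "clones.fasta", bundle / "clones.tsv")
    panel, coding_by_ind, s8_by_ind, report = cleaned_panel(
        clones, ind_meta, s8_overlap=config.s8_overlap
    )
    solution, sequences = assign_coding(
        coding_by_ind,
        s8_by_ind,
        reference_copies=reference_copies_from_truth(result),
        s8_overlap=config.s8_overlap,
    )
    shared = shared_haplotype_report(solution)
    shared.to_csv(out / "assignment.tsv", sep="\t", index=False)

    # diversity profile over cleaned unique segments + pooled coding pool
    pooled_rows = []
    segmap = {s.id: s for s in default_segment_map()}
    for ind, seqs in sorted(coding_by_ind.items()):
        site, region = ind_meta[ind]
        for k, seq in enumerate(seqs):
            pooled_rows.append(
                AlleleSequence(
                    individual_id=ind,
                    site_id=site,
                    region_id=region,
                    segment_id="S5",
                    sequence=seq,
                    allele_name=f"pool_{ind}-{k}",
                )
            )
    profile_panel = panel + [SegmentAlignment(segmap["S5"], pooled_rows)]
    profile = diversity_profile(profile_panel)
    profile.to_csv(out / "diversity_profile.tsv", sep="\t", index=False)

    # haplotype network of the pooled coding haplotypes
    sizes = {
        h: sum(ct for _, ct in hap.carriers)
        for h, hap in solution.haplotypes.items()
    }
    net = build_network(
        sorted(sequences), [sequences[h] for h in sorted(sequences)], sizes=sizes
    )
    pd.DataFrame(network_to_edgelist(net), columns=["from", "to"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False
    )

    # distance-based genealogy of a flanking control segment
    ctrl = next(a for a in panel if a.segment.id == "S2")
    names = [r.allele_name for r in ctrl.rows]
    tree, support = bootstrap_support(
        names,
        [r.sequence for r in ctrl.rows],
        reps=bootstrap_reps,
        seed=config.seed,
    )
    (out / "tree_S2.nwk").write_text(str(tree))

    amova_tab = amova_per_segment(panel, n_perm=n_perm, seed=config.seed)
    amova_tab.to_csv(out / "amova.tsv", sep="\t", index=False)

    genomic = pd.read_csv(bundle / "qpcr_genomic.tsv", sep="\t")
    eff = genomic.groupby("target_amplicon")["true_E"].first().to_dict()
    dosage = normalized_dosage(
        genomic,
        eff,
        target="HMA4_coding",
        references=["FRD3_5p", "FRD3_3p", "S13_ref"],
        calibrator="calibrator",
    )
    dosage.table.to_csv(out / "copy_number.tsv", sep="\t", index=False)
    transcript = pd.read_csv(bundle / "qpcr_transcript.tsv", sep="\t")
    tt = transcript_table(
        transcript,
        target="HMA4_cdna",
        reference="EF1a",
        calibrator="calibrator",
        E_target=1.88,
        E_ref=1.90,
    )
    tt.to_csv(out / "transcripts.tsv", sep="\t", index=False)

    manifest = dict(
        version=__version__,
        config_sha256=hashlib.sha256(config.to_json().encode()).hexdigest(),
        seed=config.seed,
        inputs={p.name: _sha256(p) for p in sorted(bundle.glob("*"))},
        outputs=sorted(p.name for p in out.glob("*.tsv")),
        cleaning=dict(
            n_input_clones=report.n_input_clones,
            n_chimeras_removed=report.n_chimeras_removed,
            chimera_fraction=report.chimera_fraction,
            n_taq_corrections=report.n_taq_corrections,
        ),
        assignment=dict(
            n_haplotypes=len(solution.haplotypes),
            n_optima=solution.n_optima,
            n_shared=int(shared["shared"].sum()),
        ),
        mean_copy_number=float(
            dosage.table[dosage.table.sample_id != "calibrator"].copy_number.mean()
        ),
        mean_fold_change=float(
            tt[tt.sample_id != "calibrator"].fold_change.mean()
        ),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
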