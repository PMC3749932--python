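"""Assignment of pooled coding haplotypes to the three array paralogs.

The 3'-coding amplicon co-amplifies all three gene copies, so each diploid
individual contributes up to six alleles with unknown locus of origin.
Assignment works like solving a puzzle with hard clues and a parsimony
objective: anchors pin some haplotypes to a copy (exact overlap with the
copy-2-specific downstream amplicon, or exact match to reference sequences
of known position), and an exact backtracking search then distributes each
individual's haplotypes over the six allele slots (two per copy) so that,
species-wide, as few haplotypes as possible must live at more than one
locus. All optima are enumerated; haplotypes whose placement differs among
optima are flagged ambiguous rather than assigned arbitrarily — never a
confidently wrong label.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .segments import COPIES


class InfeasibleError(ValueError):
    """No consistent assignment exists (slot bound or anchor conflict)."""


@dataclass
class HaplotypeConsensus:
    """A distinct cleaned coding haplotype with its carriers and solution."""

    h_id: str
    sequence: str
    carriers: list[tuple[str, int]] = field(default_factory=list)  # (individual, support)
    assigned_copies: set[str] = field(default_factory=set)
    ambiguous: bool = False
    shared: bool = False  # multi-copy in every optimum (the EGC signal)
    anchor_evidence: str = "none"  # none | S8-overlap | reference


@dataclass
class AssignmentProblem:
    """Haplotypes per individual plus anchor facts.

    ``alleles_per_individual``: individual -> list of distinct h_ids
    (1..6). ``anchors``: (individual or None, h_id, copy) facts; an anchor
    with individual None applies to every carrier of the haplotype.
    """

    alleles_per_individual: dict[str, list[str]]
    anchors: list[tuple[str | None, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        for ind, hs in self.alleles_per_individual.items():
            if len(set(hs)) > 6:
                raise InfeasibleError(
                    f"individual {ind} carries {len(set(hs))} distinct haplotypes; "
                    "a diploid with three loci has only 6 allele slots"
                )


@dataclass
class AssignmentSolution:
    optima: list[dict[str, dict[str, tuple[str, str]]]]  # per optimum: ind -> copy -> (h,h)
    cost: int
    haplotypes: dict[str, HaplotypeConsensus]
    n_optima: int


def anchor_from_s8(
    coding_haplotypes: dict[str, str],
    s8_sequences: dict[str, list[str]],
    overlap: int,
    carried_by: dict[str, list[str]] | None = None,
) -> list[tuple[str | None, str, str]]:
    """Anchor haplotypes to copy 2 via the coding/S8 amplicon overlap.

    The downstream amplicon is copy-2 specific and its 5' end reads into
    the copy-2 coding frame: a coding haplotype whose 3' ``overlap`` bases
    equal the 5' end of one of an individual's S8 alleles must be present
    at copy 2 in that individual. When ``carried_by`` (individual ->
    carried h_ids) is given, only an individual's own haplotypes are
    matched against its S8 alleles.
    """
    anchors = []
    for ind, s8_alleles in sorted(s8_sequences.items()):
        prefixes = {a[:overlap] for a in s8_alleles}
        candidates = (
            sorted(set(carried_by.get(ind, [])))
            if carried_by is not None
            else sorted(coding_haplotypes)
        )
        for h_id in candidates:
            if coding_haplotypes[h_id][-overlap:] in prefixes:
                anchors.append((ind, h_id, COPIES[1]))
    return anchors


def anchor_from_reference(
    coding_haplotypes: dict[str, str],
    reference_copies: dict[str, str],
) -> list[tuple[str | None, str, str]]:
    """Anchor haplotypes equal to a reference sequence of known position.

    ``reference_copies`` maps copy label -> reference coding sequence
    (e.g. from fully sequenced BAC clones). A reference matching two
    copies equally yields no anchor.
    """
    anchors = []
    by_seq: dict[str, list[str]] = defaultdict(list)
    for copy_label, seq in reference_copies.items():
        by_seq[seq].append(copy_label)
    for h_id, seq in sorted(coding_haplotypes.items()):
        copies = by_seq.get(seq, [])
        if len(copies) == 1:
            anchors.append((None, h_id, copies[0]))
    return anchors


def _individual_options(
    haps: list[str],
    anchors_for_ind: dict[str, set[str]],
) -> list[dict[str, tuple[str, str]]]:
    """All ways to place an individual's haplotypes into 3 x 2 slots.

    Each copy holds an unordered pair (homozygous = same haplotype twice);
    every observed haplotype must occupy at least one slot; anchored
    haplotypes must appear at their anchored copy. Pair candidates are
    generated per copy honoring its anchors, which keeps the product
    small when (as with the downstream-overlap evidence) one copy is
    fully pinned.
    """
    haps = sorted(set(haps))
    hapset = set(haps)
    pairs_per_copy: list[list[tuple[str, str]]] = []
    for copy_label in COPIES:
        required = sorted(
            h for h, cps in anchors_for_ind.items() if copy_label in cps
        )
        if len(required) > 2:
            return []
        if len(required) == 2:
            cands = [tuple(required)]
        elif len(required) == 1:
            r = required[0]
            cands = [tuple(sorted((r, x))) for x in haps]
            cands = sorted(set(cands))
        else:
            cands = list(itertools.combinations_with_replacement(haps, 2))
        pairs_per_copy.append(cands)
    options = []
    for combo in itertools.product(*pairs_per_copy):
        used = set(itertools.chain.from_iterable(combo))
        if used != hapset:
            continue
        options.append({COPIES[i]: combo[i] for i in range(3)})
    return options


def solve_assignment(
    problem: AssignmentProblem,
    sequences: dict[str, str] | None = None,
    scope: str = "species",
    max_optima: int = 20000,
) -> AssignmentSolution:
    """Exact search for all most-parsimonious assignments.

    The objective is the number of extra locus memberships summed over
    haplotypes: sum_h (|copies assigned to h| - 1), i.e. prefer every
    haplotype to live at a single locus. With ``scope='species'`` the copy
    set of a haplotype is pooled over all individuals (concerted-evolution
    sharing is penalized once per extra locus species-wide); with
    ``scope='individual'`` each individual is scored separately. All
    optima are enumerated by depth-first search with cost pruning, so the
    result is independent of input order.
    """
    problem.validate()
    if scope not in {"species", "individual"}:
        raise ValueError(f"unknown scope {scope!r}")
    # Per-individual anchors (S8 overlap) are hard: the individual's own
    # downstream allele proves presence at copy 2 in that individual.
    # Global anchors (reference accessions) are soft: they seed the
    # haplotype's known copy membership, but other carriers may hold it
    # elsewhere (that displacement is exactly what EGC produces), so they
    # steer the parsimony objective rather than constrain slots.
    anchors_by_ind: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    global_anchor: dict[str, set[str]] = defaultdict(set)
    for ind, h, copy_label in problem.anchors:
        if ind is None:
            global_anchor[h].add(copy_label)
        else:
            if ind not in problem.alleles_per_individual:
                continue
            if h not in problem.alleles_per_individual[ind]:
                raise InfeasibleError(
                    f"anchor refers to haplotype {h} absent from individual {ind}"
                )
            anchors_by_ind[ind][h].add(copy_label)

    individuals = sorted(problem.alleles_per_individual)
    options = {}
    for ind in individuals:
        opts = _individual_options(
            problem.alleles_per_individual[ind], anchors_by_ind.get(ind, {})
        )
        if not opts:
            raise InfeasibleError(
                f"no consistent slot assignment for individual {ind} "
                f"(anchors: {dict(anchors_by_ind.get(ind, {}))})"
            )
        options[ind] = opts

    # The carrier graph (individuals linked by shared haplotypes)
    # decomposes the search: the objective is additive over connected
    # components and optima combine as cartesian products, so each
    # component is solved exactly on its own.
    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ind in individuals:
        for h in problem.alleles_per_individual[ind]:
            if scope == "species":
                parent[find(("i", ind))] = find(("h", h))
    components: dict = defaultdict(list)
    for ind in individuals:
        components[find(("i", ind))].append(ind)

    truncated = {"flag": False}

    def solve_component(comp_inds: list[str]) -> tuple[int, list[dict]]:
        # most-constrained individuals first keeps the search tiny
        comp_inds = sorted(comp_inds, key=lambda i: (len(options[i]), i))
        comp_haps = {h for i in comp_inds for h in problem.alleles_per_individual[i]}
        init_copyset: dict = {}
        for h, copies in global_anchor.items():
            if h not in comp_haps:
                continue
            if scope == "species":
                init_copyset[h] = set(copies)
            else:
                for ind in comp_inds:
                    if h in problem.alleles_per_individual[ind]:
                        init_copyset[(ind, h)] = set(copies)
        best = {"cost": None}
        optima_c: list[dict] = []

        def dfs(idx: int, chosen: dict, copyset: dict, current: int) -> None:
            # cost only grows along a path, so both prunes are exact
            if best["cost"] is not None and current > best["cost"]:
                return
            if (
                best["cost"] is not None
                and current == best["cost"]
                and len(optima_c) >= max_optima
            ):
                truncated["flag"] = True
                return
            if idx == len(comp_inds):
                if best["cost"] is None or current < best["cost"]:
                    best["cost"] = current
                    optima_c.clear()
                if current == best["cost"] and len(optima_c) < max_optima:
                    optima_c.append(dict(chosen))
                return
            ind = comp_inds[idx]
            for opt in options[ind]:
                added: list[tuple] = []
                delta = 0
                for copy_label, pair in opt.items():
                    for h in set(pair):
                        key = h if scope == "species" else (ind, h)
                        cs = copyset.setdefault(key, set())
                        if copy_label not in cs:
                            cs.add(copy_label)
                            added.append((key, copy_label))
                            if len(cs) > 1:
                                delta += 1
                chosen[ind] = opt
                dfs(idx + 1, chosen, copyset, current + delta)
                del chosen[ind]
                for key, copy_label in added:
                    copyset[key].remove(copy_label)

        dfs(0, {}, init_copyset, 0)
        return best["cost"], optima_c

    total_cost = 0
    n_optima_total = 1
    comp_results: list[tuple[list[dict], list[str]]] = []
    for key in sorted(components, key=str):
        cost_c, optima_c = solve_component(components[key])
        total_cost += cost_c
        n_optima_total = min(n_optima_total * max(len(optima_c), 1), max_optima)
        comp_results.append((optima_c, components[key]))

    # materialize the cartesian product of component optima only when small
    optima: list[dict] = []
    if n_optima_total <= 2000 and not truncated["flag"]:
        optima = [{}]
        for optima_c, _ in comp_results:
            optima = [
                {**base, **comp_opt} for base in optima for comp_opt in optima_c
            ]

    # summarize per haplotype over each component's optima
    haplotypes: dict[str, HaplotypeConsensus] = {}
    all_h = sorted({h for hs in problem.alleles_per_individual.values() for h in hs})
    per_opt_copies: dict[str, list[set[str]]] = {h: [] for h in all_h}
    for optima_c, comp_inds in comp_results:
        comp_haps = sorted(
            {h for i in comp_inds for h in problem.alleles_per_individual[i]}
        )
        for opt in optima_c:
            sets: dict[str, set[str]] = defaultdict(set)
            for ind, placing in opt.items():
                for copy_label, pair in placing.items():
                    for h in set(pair):
                        sets[h].add(copy_label)
            for h in comp_haps:
                # reference knowledge counts toward the copy membership
                per_opt_copies[h].append(sets[h] | global_anchor.get(h, set()))
    for h in all_h:
        union = set().union(*per_opt_copies[h]) if per_opt_copies[h] else set()
        amb = len({frozenset(s) for s in per_opt_copies[h]}) > 1
        shared = bool(per_opt_copies[h]) and min(len(s) for s in per_opt_copies[h]) >= 2
        carriers = [
            (ind, hs.count(h))
            for ind, hs in sorted(problem.alleles_per_individual.items())
            if h in hs
        ]
        evid = "none"
        if h in global_anchor:
            evid = "reference"
        elif any(h in anchors_by_ind[i] for i in anchors_by_ind):
            evid = "S8-overlap"
        haplotypes[h] = HaplotypeConsensus(
            h_id=h,
            sequence=(sequences or {}).get(h, ""),
            carriers=carriers,
            assigned_copies=union,
            ambiguous=amb,
            shared=shared,
            anchor_evidence=evid,
        )
    if truncated["flag"]:
        # optimum set capped: treat unobserved disagreement conservatively
        for hap in haplotypes.values():
            hap.ambiguous = True
            hap.shared = False
    return AssignmentSolution(
        optima=optima,
        cost=total_cost,
        haplotypes=haplotypes,
        n_optima=n_optima_total,
    )


def shared_haplotype_report(solution: AssignmentSolution) -> pd.DataFrame:
    """Haplotype x copy table with sharing flags — the EGC evidence surface.

    A haplotype is counted shared when it occupies two or more loci in
    every optimum; a haplotype whose copy set merely varies across optima
    is ambiguous, not shared.
    """
    rows = []
    for h_id, hap in sorted(solution.haplotypes.items()):
        rows.append(
            dict(
                h_id=h_id,
                copies=",".join(sorted(hap.assigned_copies)),
                n_copies_union=len(hap.assigned_copies),
                shared=hap.shared,
                ambiguous=hap.ambiguous,
                anchor_evidence=hap.anchor_evidence,
                n_carriers=len(hap.carriers),
            )
        )
    return pd.DataFrame(rows)


def random_assignment_instance(
    rng,
    n_individuals: int = 8,
    pool_size: int = 4,
    p_share: float = 0.25,
    seq_len: int = 60,
    overlap: int = 20,
):
    """Synthetic assignment instance with ground truth.

    Emulates the data shape of the real assignment task: per copy, a pool
    of distinct haplotypes; individuals draw two alleles per copy
    (homozygotes allowed); with probability ``p_share`` one haplotype is
    additionally planted at a second copy in one individual (the
    EGC-sharing signal), heterozygously so the sharing is witnessed by a
    distinct partner allele. Copy-2 content is fully anchorable via
    per-individual downstream-overlap alleles, and one individual's
    copy-1/copy-3 alleles serve as reference anchors.

    Returns (problem, sequences, s8_by_individual, reference_copies,
    truth) where truth maps h_id -> true copy set.
    """
    import numpy as np

    bases = "ACGT"
    n_haps = 3 * pool_size
    seqs = {}
    while len(seqs) < n_haps:
        s = "".join(rng.choice(list(bases)) for _ in range(seq_len))
        seqs[s] = None
    all_seqs = sorted(seqs)
    h_ids = [f"h{i+1:02d}" for i in range(n_haps)]
    sequences = dict(zip(h_ids, all_seqs))
    pools = {
        COPIES[c]: h_ids[c * pool_size : (c + 1) * pool_size] for c in range(3)
    }
    genotypes: dict[str, dict[str, list[str]]] = {}
    for i in range(n_individuals):
        ind = f"1.{i+1}"
        genotypes[ind] = {
            copy_label: [
                pools[copy_label][rng.randrange(pool_size)] for _ in range(2)
            ]
            for copy_label in COPIES
        }
    # Plant cross-copy sharing events at the anchored copy 2, where the
    # downstream-overlap evidence makes the sharing identifiable. Sharing
    # planted into copies 1/3 of an individual with homozygosity slack is
    # indistinguishable from non-sharing under presence-only data (a
    # strictly more parsimonious non-sharing explanation always exists),
    # so it is deliberately not generated.
    planted: set[str] = set()
    for i in range(n_individuals):
        if rng.random() >= p_share:
            continue
        ind = f"1.{i+1}"
        src = rng.choice(["HMA4-1", "HMA4-3"])
        # The shared haplotype needs a home-copy witness: another
        # individual carrying it at the home copy whose own copy-2 pair is
        # two distinct (anchored) alleles, so the witness cannot stash the
        # haplotype at copy 2 instead. Without this the home membership is
        # not identifiable from presence data.
        witnessed = [
            h
            for h in pools[src]
            if h not in planted
            and any(
                h in genotypes[f"1.{j+1}"][src]
                and len(set(genotypes[f"1.{j+1}"][COPIES[1]])) == 2
                for j in range(n_individuals)
                if j != i
            )
        ]
        if not witnessed:
            continue
        h = witnessed[rng.randrange(len(witnessed))]
        planted.add(h)
        partner_pool = [x for x in pools[COPIES[1]] if x != h]
        genotypes[ind][COPIES[1]] = sorted(
            [h, partner_pool[rng.randrange(len(partner_pool))]]
        )
    truth: dict[str, set[str]] = defaultdict(set)
    alleles: dict[str, list[str]] = {}
    for ind, geno in genotypes.items():
        hs = set()
        for copy_label, pair in geno.items():
            for h in pair:
                truth[h].add(copy_label)
                hs.add(h)
        alleles[ind] = sorted(hs)
    s8_by_ind = {
        ind: sorted(
            {sequences[h][-overlap:] + "G" * 10 for h in geno[COPIES[1]]}
        )
        for ind, geno in genotypes.items()
    }
    ref_ind = genotypes["1.1"]
    reference_copies = {
        "HMA4-1": sequences[ref_ind["HMA4-1"][0]],
        "HMA4-3": sequences[ref_ind["HMA4-3"][0]],
    }
    problem = AssignmentProblem(alleles_per_individual=alleles)
    return problem, sequences, s8_by_ind, reference_copies, dict(truth)


def problem_from_cleaning(
    retained_by_individual: dict[str, list[str]],
) -> tuple[AssignmentProblem, dict[str, str]]:
    """Build an AssignmentProblem from cleaned coding-pool sequences.

    ``retained_by_individual`` maps individual -> list of distinct cleaned
    coding sequences. Returns the problem plus h_id -> sequence, with
    haplotype ids h01, h02, ... ordered by first appearance then sequence.
    """
    seq_to_id: dict[str, str] = {}
    for ind in sorted(retained_by_individual):
        for seq in sorted(set(retained_by_individual[ind])):
            if seq not in seq_to_id:
                seq_to_id[seq] = f"h{len(seq_to_id) + 1:02d}"
    alleles = {
        ind: sorted(seq_to_id[s] for s in set(seqs))
        for ind, seqs in retained_by_individual.items()
    }
    sequences = {h: s for s, h in seq_to_id.items()}
    return AssignmentProblem(alleles_per_individual=alleles), sequences
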