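"""Statistical-parsimony haplotype networks with indel recoding.

Haplotypes are connected by chains of unit mutational steps up to a
connection limit chosen so that multi-step connections are still
parsimonious (free of superimposed changes) with a given confidence
(95% by convention). Alignment gaps are recoded so that one indel event —
a maximal gap run with shared boundaries — counts as exactly one
mutational step regardless of its length. Reticulations (alternative
equally short paths) are retained: in a tandem array with ectopic gene
conversion the loops ARE the signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .segments import GAP, encode
from .diversity import jukes_cantor_distance


@dataclass
class RecodedAlignment:
    """SNP columns (gap-run columns removed) + one binary column per
    distinct indel event."""

    names: list[str]
    snp_matrix: np.ndarray  # (n, L') uint8
    indel_events: list[tuple[int, int]]  # distinct (start, end) gap runs
    indel_states: np.ndarray  # (n, n_events) 0/1: has exactly this run

    def distance(self, i: int, j: int) -> int:
        d = int(np.sum(self.snp_matrix[i] != self.snp_matrix[j]))
        d += int(np.sum(self.indel_states[i] != self.indel_states[j]))
        return d

    def distance_matrix(self) -> np.ndarray:
        n = len(self.names)
        out = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.distance(i, j)
        return out


def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    in_run = False
    start = 0
    for k, v in enumerate(row):
        if v == GAP and not in_run:
            in_run, start = True, k
        elif v != GAP and in_run:
            in_run = False
            runs.append((start, k))
    if in_run:
        runs.append((start, len(row)))
    return runs


def recode_gaps(names: list[str], seqs: list[str]) -> RecodedAlignment:
    """Collapse each distinct indel event to a single mutational state.

    Indel events are maximal gap runs; runs with identical boundaries in
    different sequences are the same event (one shared state), while any
    difference in start or length makes a distinct event. All columns
    touched by any gap run are removed from the SNP matrix, so an indel
    contributes exactly one step and never additionally as SNP columns.
    """
    m = np.vstack([encode(s) for s in seqs])
    runs_per_seq = [_gap_runs(row) for row in m]
    events = sorted({r for runs in runs_per_seq for r in runs})
    covered = np.zeros(m.shape[1], dtype=bool)
    for a, b in events:
        covered[a:b] = True
    snp = m[:, ~covered]
    states = np.zeros((m.shape[0], len(events)), dtype=np.uint8)
    for i, runs in enumerate(runs_per_seq):
        for r in runs:
            states[i, events.index(r)] = 1
    return RecodedAlignment(list(names), snp, events, states)


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a j-step difference over L sites is parsimonious.

    Model: substitutions hit sites uniformly and independently; a
    connection is parsimonious when no site was hit more than once (no
    superimposed or reversed changes), so the observed differences equal
    the true mutational steps. The number of actual substitutions M is
    estimated from the observed proportion j/L with the Jukes-Cantor
    multiple-hit correction, and the no-superimposition probability is
    prod_{i=1}^{M-1} (1 - i/L).

    This follows the logic of the classical statistical-parsimony
    estimator; exact numeric parity with the historical TCS binary is not
    promised (its internal rounding is undocumented).
    """
    if j <= 1:
        return 1.0
    j = min(j, L)
    p = j / L
    if p >= 0.75:
        M = L - 1  # correction out of domain: maximal superimposition
    else:
        M = min(max(j, int(round(L * jukes_cantor_distance(p)))), L - 1)
    logp = 0.0
    for i in range(1, M):
        logp += math.log1p(-i / L)
    return math.exp(logp)


def parsimony_connection_limit(L: int, alpha: float = 0.95) -> int:
    """Largest j with parsimony probability >= alpha for length L."""
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    j = 1
    while j < L and parsimony_probability(j + 1, L) >= alpha:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    connection_limit: int
    names: list[str]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("observed")]

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_network(
    names: list[str],
    seqs: list[str],
    limit: int | None = None,
    alpha: float = 0.95,
    sizes: dict[str, int] | None = None,
    carriers: dict[str, list] | None = None,
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network with unit-step chains.

    Pairs are joined in order of increasing recoded distance; all pairs at
    the distance level at which two components first touch are added, so
    alternative equally short connections produce retained loops. Each
    multi-step edge is expanded into a chain of unnamed intermediate
    nodes, one per mutational step. Pairs farther apart than the
    connection limit stay unconnected (separate networks).
    """
    rec = recode_gaps(names, seqs)
    L = rec.snp_matrix.shape[1] + len(rec.indel_events)
    if limit is None:
        limit = parsimony_connection_limit(max(L, 1), alpha)
    dm = rec.distance_matrix()
    g = nx.Graph()
    for name in names:
        g.add_node(
            name,
            observed=True,
            size=(sizes or {}).get(name, 1),
            carriers=(carriers or {}).get(name, []),
        )
    n = len(names)
    levels: dict[int, list[tuple[int, int]]] = {}
    for i, j in itertools.combinations(range(n), 2):
        d = int(dm[i, j])
        if 0 < d <= limit:
            levels.setdefault(d, []).append((i, j))
    mid = 0
    for d in sorted(levels):
        # a pair enters iff its endpoints are in different components at
        # the start of this level (ties all enter -> loops retained)
        comp = {name: k for k, c in enumerate(nx.connected_components(g)) for name in c}
        for i, j in levels[d]:
            if comp[names[i]] == comp[names[j]]:
                continue
            prev = names[i]
            for step in range(d - 1):
                mid += 1
                inter = f"mv{mid}"
                g.add_node(inter, observed=False, size=0, carriers=[])
                g.add_edge(prev, inter, steps=1)
                prev = inter
            g.add_edge(prev, names[j], steps=1)
        # identical sequences (d == 0) are assumed pre-collapsed by caller
    return HaplotypeNetwork(graph=g, connection_limit=limit, names=list(names))


def network_to_edgelist(net: HaplotypeNetwork) -> list[tuple[str, str]]:
    return sorted((min(a, b), max(a, b)) for a, b in net.graph.edges)
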