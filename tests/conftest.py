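"""Shared fixtures: small hand alignments plus session-scoped simulations
(forward runs are the expensive resource, so they are shared across tests)."""

from __future__ import annotations

import pytest

from tandemsweep.segments import (
    AlleleSequence,
    SegmentAlignment,
    default_segment_map,
)
from tandemsweep.simulate import SimConfig, simulate_population

SEGMAP = {s.id: s for s in default_segment_map()}


def make_alignment(seqs, segment="S1", individuals=None, sites=None, regions=None,
                   inferred=None):
    rows = []
    for i, seq in enumerate(seqs):
        rows.append(
            AlleleSequence(
                individual_id=(individuals or [f"1.{i+1}" for i in range(len(seqs))])[i],
                site_id=(sites or ["1"] * len(seqs))[i],
                region_id=(regions or ["Harz"] * len(seqs))[i],
                segment_id=segment,
                sequence=seq,
                inferred_homozygote=(inferred or [False] * len(seqs))[i],
                allele_name=f"a{i}",
            )
        )
    return SegmentAlignment(SEGMAP[segment], rows)


@pytest.fixture
def worked_alignment():
    """The 4-sequence alignment with k-bar = 7/6, S = 2, eta_s = 1."""
    return make_alignment(["AAAA", "AAAT", "AACT", "AAAA"])


@pytest.fixture(scope="session")
def sweep_result():
    """One default sweep + EGC scenario run, shared across the session."""
    return simulate_population(SimConfig(seed=7))


@pytest.fixture(scope="session")
def neutral_result():
    """One neutral (no sweep) run at default conditions."""
    return simulate_population(SimConfig(seed=3, sweep=False))
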