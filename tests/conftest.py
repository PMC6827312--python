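"""Shared fixtures: synthetic family bundles reused across test modules.

The five-family bundle (200 sequences, all-vs-all hit table) is expensive, so
it is computed once per session; everything downstream (threshold scan,
delineation, HMM library) derives from it deterministically.
"""

from __future__ import annotations

import pytest

from ssnfam import pairwise, synth


@pytest.fixture(scope="session")
def five_family_bundle():
    config = synth.preset_config("five_families_small", seed=11)
    records, truth = synth.generate_families(config)
    hits = pairwise.all_vs_all(records)
    return records, truth, hits


@pytest.fixture(scope="session")
def singleton_bundle():
    config = synth.preset_config("singletons_divergent", seed=7)
    records, truth = synth.generate_families(config)
    return records, truth


def truth_blocks(truth: synth.SynthTruth) -> set[frozenset[str]]:
    blocks: dict[str, set[str]] = {}
    for rid, label in truth.partition.items():
        blocks.setdefault(label, set()).add(rid)
    return {frozenset(v) for v in blocks.values()}
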