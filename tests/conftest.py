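"""Shared fixtures: small synthetic references and pooled read sets."""

from __future__ import annotations

import numpy as np
import pytest

from poolscan import svscan, synthio


@pytest.fixture(scope="session")
def small_ref() -> synthio.ReferenceSet:
    """A 40 kb reference with 5 genes and the default mariner-like TE."""
    return synthio.build_reference(40_000, 5, seed=11)


@pytest.fixture(scope="session")
def bac_ref() -> synthio.ReferenceSet:
    """A 120 kb BAC-scale reference with a 13-gene cluster."""
    return synthio.build_reference(120_000, 13, seed=1)


def simulate_sam(
    ref: synthio.ReferenceSet,
    edits_per_hap: list[list[synthio.StructuralEdit]],
    freqs: list[float],
    path: str,
    coverage: float = 40.0,
    seed: int = 7,
    error_rate: float = 0.0,
) -> list[svscan.AlignmentRecord]:
    """Simulate a pool (reference haplotype first), write SAM, return records."""
    haps = [synthio.apply_edits(ref, [], name="ref")]
    for i, edits in enumerate(edits_per_hap):
        haps.append(synthio.apply_edits(ref, edits, name=f"h{i}"))
    pool = synthio.HaplotypePool(haps, freqs)
    pairs = synthio.simulate_pool_reads(pool, coverage, seed=seed, error_rate=error_rate)
    synthio.write_sam(pairs, ref, path)
    return svscan.preprocess(svscan.read_alignments(path))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202409)
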