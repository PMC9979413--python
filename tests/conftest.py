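"""Shared fixtures and the independent brute-force comparison oracle.

The oracle enumerates positions one by one with plain Python dict/set
arithmetic and was written against the allele-calling and substitution
definitions directly; it shares no code with the vectorized implementation
it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from strainsift import GenomeRef, PlateDims, PositionProfile, SampleMeta, WellAddress

BASES = "ACGT"


def oracle_detected_alleles(counts, min_count=2, min_freq=0.05):
    """Reference allele-calling rule: naive, per-position."""
    total = sum(counts)
    assert total >= 1
    best = 0
    for i in range(1, 4):
        if counts[i] > counts[best]:
            best = i
    out = {BASES[best]}
    for i in range(4):
        if counts[i] >= min_count and counts[i] >= min_freq * total:
            out.add(BASES[i])
    return out


def oracle_compare(counts_a, counts_b, genome_length, min_cov=5,
                   min_count=2, min_freq=0.05):
    """Position-by-position popANI/conANI oracle.

    ``counts_a``/``counts_b`` map position -> (a, c, g, t) tuples.  Returns
    (compared, con_subs, pop_subs, conANI, popANI, pgc) with ANI values None
    when nothing was comparable.
    """
    compared = 0
    con_subs = 0
    pop_subs = 0
    for pos in set(counts_a) & set(counts_b):
        ca, cb = counts_a[pos], counts_b[pos]
        if sum(ca) < min_cov or sum(cb) < min_cov:
            continue
        compared += 1
        best_a = max(range(4), key=lambda i: (ca[i], -i))
        best_b = max(range(4), key=lambda i: (cb[i], -i))
        if best_a != best_b:
            con_subs += 1
        da = oracle_detected_alleles(ca, min_count, min_freq)
        db = oracle_detected_alleles(cb, min_count, min_freq)
        if not (da & db):
            pop_subs += 1
    if compared == 0:
        return 0, 0, 0, None, None, 0.0
    return (
        compared,
        con_subs,
        pop_subs,
        1 - con_subs / compared,
        1 - pop_subs / compared,
        compared / genome_length,
    )


def random_profile(rng, sample_id, genome, max_positions=60, max_depth=30):
    """A small random allele-count profile (sparse, noisy, tie-prone)."""
    n = int(rng.integers(0, max_positions))
    positions = rng.choice(genome.length, size=n, replace=False)
    counts = rng.integers(0, max_depth, size=(n, 4))
    keep = counts.sum(axis=1) >= 1
    return PositionProfile(sample_id, genome.genome_id, positions[keep], counts[keep])


def profile_to_dict(profile):
    return {
        int(p): tuple(int(x) for x in row)
        for p, row in zip(profile.positions, profile.counts)
    }


@pytest.fixture
def small_genome():
    return GenomeRef("g01", 100, "test species")


@pytest.fixture
def two_sample_study():
    """Minimal valid study: two samples on one plate, one genome."""
    genome = GenomeRef("g01", 10, "sp")
    samples = [
        SampleMeta("A1", "S1", "F1", "gut", "biological", 5.0, "pool1",
                   (WellAddress("P1", 0, 0),)),
        SampleMeta("B1", "S2", "F2", "gut", "biological", None, "pool1",
                   (WellAddress("P1", 1, 0),)),
    ]
    profiles = {
        ("A1", "g01"): PositionProfile(
            "A1", "g01", np.arange(10), np.tile([9, 0, 1, 0], (10, 1))
        ),
    }
    from strainsift import StudyBundle

    return StudyBundle(samples, [genome], profiles, {"P1": PlateDims()})
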