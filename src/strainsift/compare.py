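"""Genome detection by breadth and pairwise popANI/conANI strain comparison.

A genome is *present* in a sample when at least half of its positions carry
at least one read (breadth >= 0.5, inclusive).  Two samples are compared at
every position covered at >= 5x in both; a *consensus substitution* (conANI)
is counted where the majority alleles differ, and a *population substitution*
(popANI) only where the detected-allele sets are disjoint, so shared minor
alleles prevent a popANI substitution.  Samples share a strain when popANI
over the compared region meets the sharing threshold (99.999% by default)
and at least half the genome was comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BASES, GenomeRef, PositionProfile, StudyBundle

#: Default thresholds (fractions throughout).
BREADTH_THRESHOLD = 0.5
POPANI_THRESHOLD = 0.99999  # the stricter of the two study defaults
POPANI_THRESHOLD_RELAXED = 0.99995
MIN_COV = 5
MIN_PGC = 0.5
EDGE_POPANI = 5e-5  # review band: popANI within 0.005% of the threshold
EDGE_PGC = 2e-3  # review band: pgc within 0.2% of its cutoff
MIN_ALLELE_COUNT = 2
MIN_ALLELE_FREQ = 0.05


@dataclass(frozen=True)
class DetectionCall:
    """Breadth-based presence call for one (sample, genome) pair."""

    sample_id: str
    genome_id: str
    breadth: float
    present: bool


@dataclass(frozen=True)
class ComparisonResult:
    """popANI/conANI comparison of one genome between two samples.

    Sample ids are stored in lexicographic order, making the result exactly
    symmetric in argument order.  ``conANI``/``popANI`` are ``None`` when no
    position met the joint coverage requirement.
    """

    sample_a: str
    sample_b: str
    genome_id: str
    compared_positions: int
    con_subs: int
    pop_subs: int
    conANI: float | None
    popANI: float | None
    percent_genome_compared: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


@dataclass(frozen=True)
class SharingDecision:
    """Verdict on whether two samples carry the same strain of one genome."""

    comparison: ComparisonResult
    verdict: str  # shared | not_shared | insufficient_overlap
    edge_case: bool


def compute_breadth(profile: PositionProfile, genome: GenomeRef) -> float:
    """Fraction of genome positions covered by at least one read."""
    if profile.genome_id != genome.genome_id:
        raise ValueError(
            f"profile is for genome {profile.genome_id!r}, not {genome.genome_id!r}"
        )
    covered = int(np.count_nonzero(profile.total_counts() >= 1))
    return covered / genome.length


def detect_genomes(
    bundle: StudyBundle, breadth_threshold: float = BREADTH_THRESHOLD
) -> list[DetectionCall]:
    """One presence call per (sample, genome) pair that has a profile.

    Genomes without a profile for a sample are absent by definition and get
    no call.
    """
    genomes = bundle.genomes_by_id
    calls = []
    for (sid, gid), prof in sorted(bundle.profiles.items()):
        breadth = compute_breadth(prof, genomes[gid])
        calls.append(DetectionCall(sid, gid, breadth, breadth >= breadth_threshold))
    return calls


def detected_alleles(
    counts,
    min_allele_count: int = MIN_ALLELE_COUNT,
    min_allele_freq: float = MIN_ALLELE_FREQ,
) -> frozenset[str]:
    """Alleles supported at one position.

    An allele is detected when its count is >= ``min_allele_count`` and its
    frequency >= ``min_allele_freq``; the consensus allele (highest count,
    ties broken A<C<G<T) is always included.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (4,):
        raise ValueError("counts must be a length-4 sequence (A, C, G, T)")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("all-zero counts: no allele can be called")
    detected = (counts >= min_allele_count) & (counts >= min_allele_freq * total)
    detected[int(np.argmax(counts))] = True  # argmax tie-break is A<C<G<T
    return frozenset(BASES[i] for i in range(4) if detected[i])


class PreparedProfile:
    """Per-profile quantities that do not depend on the comparison partner.

    Precomputing consensus and detected-allele calls once per profile turns
    each pairwise comparison into a position intersection plus cheap boolean
    reductions; with every sample compared against every other, this is the
    difference between quadratic and linear allele-calling work.
    """

    __slots__ = ("sample_id", "genome_id", "positions", "consensus", "detected")

    def __init__(
        self,
        profile: PositionProfile,
        min_cov: int = MIN_COV,
        min_allele_count: int = MIN_ALLELE_COUNT,
        min_allele_freq: float = MIN_ALLELE_FREQ,
    ) -> None:
        totals = profile.total_counts()
        keep = totals >= min_cov
        counts = profile.counts[keep]
        self.sample_id = profile.sample_id
        self.genome_id = profile.genome_id
        self.positions = profile.positions[keep]
        self.consensus = counts.argmax(axis=1)  # first max: A<C<G<T tie-break
        detected = (counts >= min_allele_count) & (
            counts >= min_allele_freq * totals[keep, None]
        )
        detected[np.arange(counts.shape[0]), self.consensus] = True
        self.detected = detected


def compare_prepared(
    pa: PreparedProfile, pb: PreparedProfile, genome: GenomeRef
) -> ComparisonResult:
    """popANI/conANI between two prepared profiles of one genome."""
    if pa.genome_id != genome.genome_id or pb.genome_id != genome.genome_id:
        raise ValueError("both profiles must belong to the compared genome")
    if pb.sample_id < pa.sample_id:
        pa, pb = pb, pa
    common, ia, ib = np.intersect1d(
        pa.positions, pb.positions, assume_unique=True, return_indices=True
    )
    n = int(common.size)
    if n == 0:
        return ComparisonResult(
            pa.sample_id, pb.sample_id, genome.genome_id, 0, 0, 0, None, None, 0.0
        )
    con_subs = int(np.count_nonzero(pa.consensus[ia] != pb.consensus[ib]))
    pop_subs = int(
        np.count_nonzero(~np.any(pa.detected[ia] & pb.detected[ib], axis=1))
    )
    return ComparisonResult(
        pa.sample_id,
        pb.sample_id,
        genome.genome_id,
        n,
        con_subs,
        pop_subs,
        1.0 - con_subs / n,
        1.0 - pop_subs / n,
        n / genome.length,
    )


def compare_pair(
    profile_a: PositionProfile,
    profile_b: PositionProfile,
    genome: GenomeRef,
    min_cov: int = MIN_COV,
    min_allele_count: int = MIN_ALLELE_COUNT,
    min_allele_freq: float = MIN_ALLELE_FREQ,
) -> ComparisonResult:
    """popANI/conANI over positions with >= ``min_cov`` total reads in both.

    A consensus substitution is counted where the consensus alleles differ;
    a population substitution only where the detected-allele sets (see
    :func:`detected_alleles`) are disjoint.  Exactly symmetric in argument
    order.
    """
    return compare_prepared(
        PreparedProfile(profile_a, min_cov, min_allele_count, min_allele_freq),
        PreparedProfile(profile_b, min_cov, min_allele_count, min_allele_freq),
        genome,
    )


def decide_sharing(
    result: ComparisonResult,
    popani_threshold: float = POPANI_THRESHOLD,
    min_pgc: float = MIN_PGC,
    edge_popani: float = EDGE_POPANI,
    edge_pgc: float = EDGE_PGC,
) -> SharingDecision:
    """Apply the strain-sharing rule with edge-case flagging.

    Pairs below the ``min_pgc`` comparable-fraction cutoff are recorded as
    ``insufficient_overlap``; otherwise the verdict is ``shared`` iff
    popANI >= threshold (inclusive).  Results within ``edge_popani`` of the
    popANI threshold or ``edge_pgc`` of the pgc cutoff are still decided by
    the rule but flagged for manual review.
    """
    if not 0 < popani_threshold <= 1:
        raise ValueError(f"popANI threshold must be in (0, 1], got {popani_threshold}")
    pgc = result.percent_genome_compared
    edge = abs(pgc - min_pgc) <= edge_pgc
    if result.popANI is not None:
        edge = edge or abs(result.popANI - popani_threshold) <= edge_popani
    if pgc < min_pgc or result.popANI is None:
        return SharingDecision(result, "insufficient_overlap", edge)
    verdict = "shared" if result.popANI >= popani_threshold else "not_shared"
    return SharingDecision(result, verdict, edge)
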