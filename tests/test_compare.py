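"""Breadth detection, allele calling, and popANI/conANI comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsift import (
    GenomeRef,
    PositionProfile,
    compare_pair,
    compute_breadth,
    decide_sharing,
    detect_genomes,
    detected_alleles,
)
from strainsift.compare import ComparisonResult

from conftest import oracle_compare, profile_to_dict, random_profile


def _profile(sample, genome_id, counts_by_pos):
    pos = np.array(sorted(counts_by_pos))
    counts = np.array([counts_by_pos[p] for p in pos])
    return PositionProfile(sample, genome_id, pos, counts)


def _uniform_profile(sample, genome_id, n, depth=10, base=0):
    counts = np.zeros((n, 4), dtype=int)
    counts[:, base] = depth
    return PositionProfile(sample, genome_id, np.arange(n), counts)


class TestBreadth:
    @pytest.mark.parametrize(
        "covered,expected_breadth,expected_present",
        [(1000, 1.0, True), (600, 0.6, True), (500, 0.5, True), (499, 0.499, False)],
    )
    def test_breadth_and_inclusive_threshold(
        self, covered, expected_breadth, expected_present
    ):
        genome = GenomeRef("g", 1000)
        prof = _uniform_profile("A", "g", covered, depth=1)
        assert compute_breadth(prof, genome) == pytest.approx(expected_breadth)
        assert (compute_breadth(prof, genome) >= 0.5) is expected_present

    def test_detect_genomes_one_call_per_profile(self, two_sample_study):
        calls = detect_genomes(two_sample_study)
        assert len(calls) == 1  # sample without profiles gets no call
        assert calls[0].present and calls[0].sample_id == "A1"

    def test_two_samples_one_present(self):
        from strainsift import SampleMeta, StudyBundle

        genome = GenomeRef("g", 10)
        samples = [SampleMeta("A", "S1", "F1"), SampleMeta("B", "S2", "F2")]
        profiles = {
            ("A", "g"): _uniform_profile("A", "g", 7, depth=1),
            ("B", "g"): _uniform_profile("B", "g", 2, depth=1),
        }
        calls = detect_genomes(StudyBundle(samples, [genome], profiles, {}))
        assert [(c.sample_id, c.present) for c in calls] == [("A", True), ("B", False)]


class TestDetectedAlleles:
    @pytest.mark.parametrize(
        "counts,kwargs,expected",
        [
            ((100, 0, 0, 0), {}, {"A"}),
            ((60, 40, 0, 0), {}, {"A", "C"}),
            ((99, 1, 0, 0), {"min_allele_count": 2}, {"A"}),
            ((5, 5, 0, 0), {}, {"A", "C"}),  # consensus tie -> A, C passes filters
        ],
    )
    def test_allele_rule(self, counts, kwargs, expected):
        assert detected_alleles(counts, **kwargs) == expected

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            detected_alleles((0, 0, 0, 0))


class TestComparePair:
    def test_identical_profiles_full_identity(self, small_genome):
        prof = _uniform_profile("A", "g01", 10)
        prof_b = _uniform_profile("B", "g01", 10)
        res = compare_pair(prof, prof_b, small_genome)
        assert res.compared_positions == 10
        assert res.popANI == 1.0 and res.conANI == 1.0 and res.pop_subs == 0

    def test_consensus_vs_population_substitutions(self, small_genome):
        # 10 positions: one fixed difference, one consensus-only difference.
        a = {p: (10, 0, 0, 0) for p in range(10)}
        b = {p: (10, 0, 0, 0) for p in range(10)}
        a[0], b[0] = (10, 0, 0, 0), (0, 10, 0, 0)  # disjoint: con + pop sub
        a[1], b[1] = (60, 40, 0, 0), (0, 100, 0, 0)  # shared minor: con only
        res = compare_pair(_profile("A", "g01", a), _profile("B", "g01", b),
                           small_genome)
        assert (res.con_subs, res.pop_subs) == (2, 1)
        assert res.conANI == pytest.approx(0.8)
        assert res.popANI == pytest.approx(0.9)

    def test_no_joint_coverage_yields_null_anis(self, small_genome):
        a = _uniform_profile("A", "g01", 10, depth=2)  # below min_cov
        b = _uniform_profile("B", "g01", 10, depth=2)
        res = compare_pair(a, b, small_genome)
        assert res.compared_positions == 0
        assert res.popANI is None and res.percent_genome_compared == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetry_and_popani_bounds(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeRef("g01", 80)
        a = random_profile(rng, "A", genome)
        b = random_profile(rng, "B", genome)
        r1 = compare_pair(a, b, genome)
        r2 = compare_pair(b, a, genome)
        assert r1 == r2  # exactly symmetric (ids canonicalized)
        if r1.popANI is not None:
            assert r1.popANI >= r1.conANI
            assert r1.pop_subs <= r1.con_subs
        assert 0 <= r1.percent_genome_compared <= 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_min_cov_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeRef("g01", 80)
        a = random_profile(rng, "A", genome)
        b = random_profile(rng, "B", genome)
        compared = [
            compare_pair(a, b, genome, min_cov=mc).compared_positions
            for mc in (1, 3, 5, 8, 12)
        ]
        assert compared == sorted(compared, reverse=True)

    def test_matches_bruteforce_oracle_small(self, small_genome):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = random_profile(rng, "A", small_genome)
            b = random_profile(rng, "B", small_genome)
            res = compare_pair(a, b, small_genome)
            exp = oracle_compare(
                profile_to_dict(a), profile_to_dict(b), small_genome.length
            )
            got = (
                res.compared_positions,
                res.con_subs,
                res.pop_subs,
                res.conANI,
                res.popANI,
                res.percent_genome_compared,
            )
            assert got[:3] == exp[:3]
            for g, e in zip(got[3:], exp[3:]):
                assert g == pytest.approx(e) if e is not None else g is None


def _result(popani, pgc, compared=1000):
    pop_subs = round((1 - popani) * compared)
    return ComparisonResult("A", "B", "g", compared, pop_subs, pop_subs,
                            1 - pop_subs / compared, 1 - pop_subs / compared, pgc)


class TestDecideSharing:
    def test_boundary_popani_is_shared_and_edge_flagged(self):
        d = decide_sharing(_result(0.99999, 0.8, compared=100000),
                           popani_threshold=0.99999)
        assert d.verdict == "shared" and d.edge_case

    def test_below_threshold_not_shared(self):
        d = decide_sharing(_result(0.9999, 0.8, compared=100000),
                           popani_threshold=0.99999)
        assert d.verdict == "not_shared" and not d.edge_case

    def test_low_overlap_is_insufficient_even_at_full_identity(self):
        d = decide_sharing(_result(1.0, 0.4))
        assert d.verdict == "insufficient_overlap"

    def test_pgc_near_cutoff_flagged_for_review(self):
        d = decide_sharing(_result(1.0, 0.4995))
        assert d.verdict == "insufficient_overlap" and d.edge_case

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="popANI threshold"):
            decide_sharing(_result(1.0, 0.9), popani_threshold=1.5)
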