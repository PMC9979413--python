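"""Contamination classification rules and the report schema."""

import numpy as np
import pytest

import strainsift as ss
from strainsift.classify import (
    ClassifierConfig,
    biomass_association,
    classify_strain,
    flag_well_to_well,
    render_text,
    validate_report,
)
from strainsift.model import SampleMeta, WellAddress
from strainsift.network import SharingEdge, StrainScope


def _s(sid, subj=None, fam=None, role="biological", plate="P1", row=0, col=0,
       biomass=10.0, pool="pool1"):
    return SampleMeta(sid, subj, fam, "gut", role, biomass, pool,
                      (WellAddress(plate, row, col),))


def _scope(genome, carriers, samples, n_subjects=None):
    by_id = {s.sample_id: s for s in samples}
    metas = [by_id[c] for c in carriers]
    subjects = frozenset(m.subject_id for m in metas
                         if m.role == "biological" and m.subject_id)
    total = n_subjects or len(
        {s.subject_id for s in samples if s.role == "biological"}
    )
    return StrainScope(
        genome_id=genome,
        cluster_index=0,
        carriers=frozenset(carriers),
        subjects=subjects,
        families=frozenset(m.family_id for m in metas if m.family_id),
        plates=frozenset(p for m in metas for p in m.plate_ids),
        pools=frozenset(m.pool_id for m in metas if m.pool_id),
        in_negative_controls=frozenset(
            m.sample_id for m in metas if m.role == "negative_control"
        ),
        subject_fraction=len(subjects) / total if total else 0.0,
    )


class TestClassifyStrain:
    def test_multi_plate_majority_is_external(self):
        samples = [
            _s(f"X{i}", f"S{i}", f"F{i}", plate=f"P{i % 3 + 1}", row=i % 8, col=i // 8)
            for i in range(10)
        ]
        scope = _scope("g", [s.sample_id for s in samples[:6]], samples)
        call = classify_strain(scope, samples, ClassifierConfig())
        assert call is not None and call.category == "external"

    def test_single_plate_cluster_deferred_to_sample_rules(self):
        samples = [
            _s("NC1", role="negative_control", row=0),
            _s("A", "S1", "F1", row=1),
            _s("B", "S1", "F1", row=2),
            _s("C", "S2", "F2", col=5),
        ]
        scope = _scope("g", ["NC1", "A", "B"], samples)
        assert classify_strain(scope, samples, ClassifierConfig()) is None

    def test_cross_plate_minority_without_proximity_is_residual(self):
        samples = [
            _s("A", "S1", "F1", plate="P1", row=0),
            _s("B", "S2", "F2", plate="P1", row=7, col=10),
            _s("C", "S3", "F3", plate="P2", row=3, col=3),
        ] + [_s(f"Z{i}", f"S{i+10}", f"F{i+10}", plate="P2", row=i, col=8)
             for i in range(5)]
        scope = _scope("g", ["A", "B", "C"], samples)
        call = classify_strain(scope, samples, ClassifierConfig())
        assert call is not None and call.category == "residual_sharing"

    def test_residual_requires_consensus_cross_plate_link(self):
        samples = [
            _s("A", "S1", "F1", plate="P1", row=0),
            _s("B", "S2", "F2", plate="P1", row=7, col=10),
            _s("C", "S3", "F3", plate="P2", row=3, col=3),
        ] + [_s(f"Z{i}", f"S{i+10}", f"F{i+10}", plate="P2", row=i, col=8)
             for i in range(5)]
        scope = _scope("g", ["A", "B", "C"], samples)
        # All sharing is mixture-level (conANI far below threshold).
        con_map = {("A", "B", "g"): 0.995, ("A", "C", "g"): 0.995}
        call = classify_strain(scope, samples, ClassifierConfig(), con_map, 0.99999)
        assert call is None
        con_map[("A", "C", "g")] = 1.0  # consensus link P1 <-> P2
        call = classify_strain(scope, samples, ClassifierConfig(), con_map, 0.99999)
        assert call is not None and call.category == "residual_sharing"


class TestFlagWellToWell:
    def _nc3_like(self):
        """A negative control sharing strains exclusive to one neighbouring
        family, mirroring the contaminated-control pattern."""
        samples = [
            _s("NC3", role="negative_control", row=0, col=11, biomass=0.2),
            _s("I82_1", "S82", "F82", row=1, col=11),
            _s("I82_2", "S82", "F82", row=2, col=11),
            _s("I83_1", "S83", "F83", row=3, col=10),
            _s("OTH", "S99", "F99", row=7, col=0),
        ]
        edges = [
            SharingEdge("I82_1", "NC3", frozenset({"g1", "g2"})),
            SharingEdge("I82_2", "NC3", frozenset({"g1"})),
        ]
        return samples, edges

    def test_contaminated_negative_control_flagged(self):
        samples, edges = self._nc3_like()
        call = flag_well_to_well(samples[0], edges, samples, {}, ClassifierConfig())
        assert call is not None and call.category == "well_to_well"
        rules = {e.rule for e in call.evidence}
        assert {"adjacency", "source_exclusivity", "plate_confinement"} <= rules

    def test_source_samples_not_flagged(self):
        samples, edges = self._nc3_like()
        for src in (samples[1], samples[2]):
            call = flag_well_to_well(src, edges, samples, {}, ClassifierConfig())
            assert call is None  # NC partner is a single-carrier "family"

    def test_unplaced_sample_not_evaluable(self):
        samples, edges = self._nc3_like()
        floating = SampleMeta("T", "S7", "F7", "gut", "biological", 1.0, "", ())
        assert flag_well_to_well(floating, edges, samples, {}, ClassifierConfig()) is None

    def test_cross_plate_strain_not_flagged(self):
        # The candidate family's strain reaches another plate: channel C fails.
        samples = [
            _s("T", "S1", "F1", row=0, col=0),
            _s("A1", "S2", "F2", row=1, col=0),
            _s("A2", "S2", "F2", row=2, col=0),
            _s("FAR", "S3", "F3", plate="P2"),
        ]
        edges = [
            SharingEdge("A1", "T", frozenset({"g"})),
            SharingEdge("A2", "T", frozenset({"g"})),
            SharingEdge("A1", "FAR", frozenset({"g"})),
        ]
        call = flag_well_to_well(samples[0], edges, samples, {}, ClassifierConfig())
        assert call is None

    def test_shared_family_strain_not_flagged_in_either_family(self):
        # Two families legitimately carrying one strain (circulating): every
        # family has several carriers, so the direction gate blocks both.
        samples = [
            _s("A1", "S1", "F1", row=0), _s("A2", "S1", "F1", row=1),
            _s("B1", "S2", "F2", row=4), _s("B2", "S2", "F2", row=5),
        ]
        edges = [
            SharingEdge(a, b, frozenset({"g"}))
            for a in ("A1", "A2") for b in ("B1", "B2")
        ]
        for s in samples:
            assert flag_well_to_well(s, edges, samples, {}, ClassifierConfig()) is None


class TestBiomassAssociation:
    def test_separated_groups_significant(self):
        samples = [
            _s(f"L{i}", f"S{i}", f"F{i}", biomass=1.0 + 0.01 * i) for i in range(10)
        ] + [
            _s(f"H{i}", f"S{i+10}", f"F{i+10}", biomass=20.0 + i) for i in range(30)
        ]
        res = biomass_association(
            {f"L{i}" for i in range(10)},
            {f"H{i}" for i in range(30)},
            samples,
            method="permutation",
            rng=np.random.default_rng(0),
        )
        assert res["testable"] and res["p_value"] < 0.01
        assert res["median_flagged"] < res["median_unflagged"]

    def test_identical_distributions_nonsignificant(self):
        samples = [
            _s(f"X{i}", f"S{i}", f"F{i}", biomass=5.0) for i in range(8)
        ]
        res = biomass_association({"X0", "X1"}, {f"X{i}" for i in range(2, 8)}, samples)
        assert res["p_value"] == pytest.approx(1.0)

    def test_missing_biomass_excluded_and_counted(self):
        samples = [
            SampleMeta("A", "S1", "F1", biomass=None),
            _s("B", "S2", "F2", biomass=3.0),
            _s("C", "S3", "F3", biomass=4.0),
        ]
        res = biomass_association({"A"}, {"B", "C"}, samples)
        assert not res["testable"] and res["n_missing_biomass"] == 1


class TestReport:
    def test_clean_study_report_validates_with_zero_calls(self):
        cfg = ss.SimConfig(seed=21, n_subjects=6, samples_per_subject=2,
                           n_species=3, genome_length=1500)
        bundle, _ = ss.simulate_study(cfg)
        res = ss.run_pipeline(bundle)
        validate_report(res.report)  # raises on any schema violation
        assert res.report["categories"] == []
        assert res.report["exclusions"] == []
        text = render_text(res.report)
        assert "Contamination report" in text

    def test_report_round_trips_through_json(self):
        import json

        cfg = ss.scenario_well_to_well(22, n_events=1)
        bundle, _ = ss.simulate_study(cfg)
        res = ss.run_pipeline(bundle)
        validate_report(res.report)
        back = json.loads(json.dumps(res.report))
        validate_report(back)
        assert back == json.loads(json.dumps(res.report))

    def test_validator_rejects_missing_key(self):
        with pytest.raises(ValueError, match="missing key"):
            validate_report({"n_samples": 1})

    def test_validator_rejects_unknown_category(self):
        cfg = ss.SimConfig(seed=23, n_subjects=4, samples_per_subject=1,
                           n_species=2, genome_length=1000)
        bundle, _ = ss.simulate_study(cfg)
        report = ss.run_pipeline(bundle).report
        report["categories"] = ["made_up"]
        with pytest.raises(ValueError, match="unknown category"):
            validate_report(report)


class TestZymo:
    def test_spill_reported_in_zymo_section(self):
        cfg = ss.SimConfig(
            seed=24, n_subjects=6, samples_per_subject=2, n_species=2,
            genome_length=1500, pc_per_plate=1, n_zymo_species=3,
        )
        plan = ss.plan_study(cfg)
        pc = next(s for s in plan.samples if s.role == "positive_control")
        nc = next(s for s in plan.samples if s.role == "negative_control")
        cfg = ss.SimConfig(
            **{**cfg.__dict__,
               "events": (ss.ContaminationEvent.zymo_spill(
                   pc.sample_id, nc.sample_id, 0.4),)},
        )
        bundle, truth = ss.simulate_study(cfg)
        zymo = tuple(g.genome_id for g in bundle.genomes if g.label == "zymo")
        res = ss.run_pipeline(bundle, ss.RunConfig(zymo_genomes=zymo))
        carriers = {c["sample_id"] for c in res.report["zymo"]["carriers"]}
        assert nc.sample_id in carriers
        assert truth.affected[0] == (nc.sample_id,)
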