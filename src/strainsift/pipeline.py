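"""End-to-end orchestration: detection -> comparison -> network -> plate
statistics -> classification -> report.

The stage order follows the analysis workflow: evaluate controls and genome
detection first, compare strains between all unrelated sample pairs, build
the sharing network and its per-strain clusters, test each plate for
distance-correlated sharing, then classify strains and samples with the
precedence external > well_to_well > cross_plate_leakage > residual_sharing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import compare as cmp
from .classify import (
    ClassifierConfig,
    ContaminationCall,
    biomass_association,
    classify_strain,
    detect_cross_plate_leakage,
    flag_well_to_well,
    render_text,
    report_to_json,
    validate_report,
)
from .compare import (
    ComparisonResult,
    DetectionCall,
    PreparedProfile,
    SharingDecision,
    compare_prepared,
    decide_sharing,
    detect_genomes,
)
from .model import StudyBundle
from .network import (
    SharingEdge,
    StrainScope,
    build_network,
    is_unrelated,
    strain_scopes,
    write_edges_tsv,
    write_graphml,
)
from .platestats import ProximityTestResult, proximity_test, write_proximity_tsv


@dataclass(frozen=True)
class RunConfig:
    """Per-run thresholds; all values echoed into the report header."""

    breadth_threshold: float = cmp.BREADTH_THRESHOLD
    popani_threshold: float = cmp.POPANI_THRESHOLD
    min_cov: int = cmp.MIN_COV
    min_pgc: float = cmp.MIN_PGC
    min_allele_count: int = cmp.MIN_ALLELE_COUNT
    min_allele_freq: float = cmp.MIN_ALLELE_FREQ
    edge_popani: float = cmp.EDGE_POPANI
    edge_pgc: float = cmp.EDGE_PGC
    alternative: str = "two_sided"
    test_method: str = "normal_approx"
    seed: int = 0
    treat_pc_as_subject: bool = False
    zymo_genomes: tuple[str, ...] = ()
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def thresholds(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "breadth_threshold",
                "popani_threshold",
                "min_cov",
                "min_pgc",
                "min_allele_count",
                "min_allele_freq",
                "edge_popani",
                "edge_pgc",
                "alternative",
                "test_method",
                "seed",
            )
        }
        d["zymo_genomes"] = list(self.zymo_genomes)
        d["classifier"] = {
            k: getattr(self.classifier, k)
            for k in (
                "external_min_plates",
                "external_subject_fraction",
                "adjacency_radius",
                "exclusivity_max_subjects",
                "min_exclusive_strains",
                "alpha",
                "leakage_depth_ratio",
                "proximity_adjacent_fraction",
            )
        }
        return d


@dataclass
class PipelineResult:
    bundle: StudyBundle
    config: RunConfig
    detections: list[DetectionCall]
    decisions: list[SharingDecision]
    edges: list[SharingEdge]
    scopes: list[StrainScope]
    proximity: list[ProximityTestResult]
    strain_calls: list[ContaminationCall]
    sample_calls: list[ContaminationCall]
    report: dict

    def calls_by_category(self) -> dict[str, list[ContaminationCall]]:
        out: dict[str, list[ContaminationCall]] = {}
        for call in self.strain_calls + self.sample_calls:
            out.setdefault(call.category, []).append(call)
        return out

    def flagged_samples(self) -> list[str]:
        return sorted(
            c.target_id for c in self.sample_calls if c.category == "well_to_well"
        )


def compute_decisions(
    bundle: StudyBundle, config: RunConfig, detections: list[DetectionCall]
) -> list[SharingDecision]:
    """Pairwise sharing decisions for every unrelated pair where the genome
    is present (breadth above threshold) in both samples."""
    by_id = bundle.samples_by_id
    present: dict[str, list[str]] = {}
    for d in detections:
        if d.present:
            present.setdefault(d.genome_id, []).append(d.sample_id)

    decisions: list[SharingDecision] = []
    for genome in bundle.genomes:
        sids = sorted(present.get(genome.genome_id, []))
        prepared = {
            sid: PreparedProfile(
                bundle.profiles[(sid, genome.genome_id)],
                config.min_cov,
                config.min_allele_count,
                config.min_allele_freq,
            )
            for sid in sids
        }
        for a, b in itertools.combinations(sids, 2):
            if not is_unrelated(by_id[a], by_id[b], config.treat_pc_as_subject):
                continue
            result = compare_prepared(prepared[a], prepared[b], genome)
            decisions.append(
                decide_sharing(
                    result,
                    popani_threshold=config.popani_threshold,
                    min_pgc=config.min_pgc,
                    edge_popani=config.edge_popani,
                    edge_pgc=config.edge_pgc,
                )
            )
    return decisions


def classify_all(
    bundle: StudyBundle,
    config: RunConfig,
    decisions: list[SharingDecision],
    edges: list[SharingEdge],
    scopes: list[StrainScope],
    proximity: list[ProximityTestResult],
) -> tuple[list[ContaminationCall], list[ContaminationCall]]:
    """Apply strain- and sample-level rules with total precedence."""
    samples = bundle.samples
    depths = {
        (sid, gid): prof.mean_depth(bundle.genomes_by_id[gid].length)
        for (sid, gid), prof in bundle.profiles.items()
    }
    prox_by_plate = {p.plate_id: p for p in proximity}
    # conANI of every shared verdict: distinguishes consensus-identical
    # carriers from samples carrying a strain only as a mixture component.
    con_map = {
        (d.comparison.sample_a, d.comparison.sample_b, d.comparison.genome_id):
            d.comparison.conANI
        for d in decisions
        if d.verdict == "shared" and d.comparison.conANI is not None
    }

    strain_calls: list[ContaminationCall] = []
    called: set[tuple[str, int]] = set()
    residual_candidates: list = []
    for scope in scopes:
        call = classify_strain(
            scope, samples, config.classifier, con_map, config.popani_threshold
        )
        if call is not None and call.category == "external":
            strain_calls.append(call)
            called.add((scope.genome_id, scope.cluster_index))
        elif call is not None:
            residual_candidates.append((scope, call))

    remaining = [
        s for s in scopes if (s.genome_id, s.cluster_index) not in called
    ]
    leakage = detect_cross_plate_leakage(
        remaining, samples, config.classifier, depths, con_map,
        config.popani_threshold,
    )
    leak_ids = {c.target_id for c in leakage}
    strain_calls.extend(leakage)
    for scope, call in residual_candidates:
        if call.target_id not in leak_ids:
            strain_calls.append(call)

    sample_calls: list[ContaminationCall] = []
    for s in samples:
        call = flag_well_to_well(
            s, edges, samples, prox_by_plate, config.classifier
        )
        if call is not None:
            sample_calls.append(call)
    return strain_calls, sample_calls


def build_report(
    bundle: StudyBundle,
    config: RunConfig,
    detections: list[DetectionCall],
    decisions: list[SharingDecision],
    edges: list[SharingEdge],
    scopes: list[StrainScope],
    proximity: list[ProximityTestResult],
    strain_calls: list[ContaminationCall],
    sample_calls: list[ContaminationCall],
) -> dict:
    """Machine-readable summary; passes :func:`classify.validate_report`."""
    samples = bundle.samples
    by_id = bundle.samples_by_id
    detected = {(d.sample_id, d.genome_id): d for d in detections if d.present}
    shared_by_sample: dict[str, set[str]] = {}
    for e in edges:
        shared_by_sample.setdefault(e.sample_a, set()).update(e.shared_genomes)
        shared_by_sample.setdefault(e.sample_b, set()).update(e.shared_genomes)
    scoped = {(c, s.genome_id) for s in scopes for c in s.carriers}

    def _control_summary(role: str) -> list[dict]:
        out = []
        for s in samples:
            if s.role != role:
                continue
            det = sorted(g for (sid, g) in detected if sid == s.sample_id)
            out.append(
                {
                    "sample_id": s.sample_id,
                    "plates": list(s.plate_ids),
                    "n_genomes_detected": len(det),
                    "genomes_detected": det,
                    "n_shared_strains": len(shared_by_sample.get(s.sample_id, ())),
                    "shared_strains": sorted(shared_by_sample.get(s.sample_id, ())),
                }
            )
        return out

    uncategorized = [
        {"sample_id": d.sample_id, "genome_id": d.genome_id, "breadth": d.breadth}
        for d in detections
        if d.present
        and by_id[d.sample_id].role == "negative_control"
        and (d.sample_id, d.genome_id) not in scoped
    ]

    zymo_set = set(config.zymo_genomes)
    zymo_carriers = []
    if zymo_set:
        for s in samples:
            if s.role == "positive_control":
                continue
            carried = sorted(
                g for (sid, g) in detected if sid == s.sample_id and g in zymo_set
            )
            if not carried:
                continue
            non_zymo_shared = sorted(
                g
                for g in shared_by_sample.get(s.sample_id, ())
                if g not in zymo_set
            )
            zymo_carriers.append(
                {
                    "sample_id": s.sample_id,
                    "n_zymo_genomes": len(carried),
                    "zymo_genomes": carried,
                    # Sharing only mock-community strains (and none of the
                    # spiked sample's other organisms) points to aerosol or
                    # mis-pipetting rather than bulk well-to-well transfer.
                    "shares_non_zymo_strains": bool(non_zymo_shared),
                }
            )

    flagged = {
        c.target_id for c in sample_calls if c.category == "well_to_well"
    }
    unflagged = {
        s.sample_id
        for s in samples
        if s.role == "biological" and s.sample_id not in flagged
    }
    biomass = (
        biomass_association(flagged, unflagged, samples, config.alternative)
        if flagged
        else {"testable": False, "n_flagged": 0, "n_unflagged": len(unflagged),
              "n_missing_biomass": 0}
    )

    categories = sorted(
        {c.category for c in strain_calls} | {c.category for c in sample_calls}
    )
    report = {
        "thresholds": config.thresholds(),
        "n_samples": len(samples),
        "n_genomes": len(bundle.genomes),
        "n_subjects": len(bundle.subjects()),
        "proximity": [
            {
                "plate_id": p.plate_id,
                "n_sharing_pairs": p.n_sharing_pairs,
                "n_nonsharing_pairs": p.n_nonsharing_pairs,
                "statistic": p.statistic,
                "p_value": p.p_value,
                "method": p.method,
                "alternative": p.alternative,
                "testable": p.testable,
            }
            for p in proximity
        ],
        "negative_controls": _control_summary("negative_control"),
        "positive_controls": _control_summary("positive_control"),
        "zymo": {"genomes": sorted(zymo_set), "carriers": zymo_carriers},
        "strain_calls": [c.to_dict() for c in strain_calls],
        "sample_calls": [c.to_dict() for c in sample_calls],
        "uncategorized_nc_detections": uncategorized,
        "exclusions": sorted(flagged),
        "categories": categories,
        "biomass": biomass,
    }
    validate_report(report)
    return report


def run_pipeline(bundle: StudyBundle, config: RunConfig | None = None) -> PipelineResult:
    """Run every stage on an in-memory study."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    detections = detect_genomes(bundle, config.breadth_threshold)
    decisions = compute_decisions(bundle, config, detections)
    edges = build_network(decisions, bundle.samples, config.treat_pc_as_subject)
    scopes = strain_scopes(edges, bundle.samples)
    plate_ids = sorted(bundle.plates)
    proximity = [
        proximity_test(
            p,
            edges,
            bundle.samples,
            alternative=config.alternative,
            method=config.test_method,
            rng=rng,
            treat_pc_as_subject=config.treat_pc_as_subject,
        )
        for p in plate_ids
    ]
    strain_calls, sample_calls = classify_all(
        bundle, config, decisions, edges, scopes, proximity
    )
    report = build_report(
        bundle, config, detections, decisions, edges, scopes, proximity,
        strain_calls, sample_calls,
    )
    return PipelineResult(
        bundle, config, detections, decisions, edges, scopes, proximity,
        strain_calls, sample_calls, report,
    )


# ---------------------------------------------------------------------------
# file outputs


def write_detections_tsv(detections: list[DetectionCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgenome_id\tbreadth\tpresent\n")
        for d in detections:
            fh.write(f"{d.sample_id}\t{d.genome_id}\t{d.breadth!r}\t{d.present}\n")


def write_comparisons_tsv(decisions: list[SharingDecision], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "sample_a\tsample_b\tgenome_id\tcompared_positions\tcon_subs\t"
            "pop_subs\tconANI\tpopANI\tpercent_genome_compared\tverdict\tedge_case\n"
        )
        for d in decisions:
            c = d.comparison
            con = "" if c.conANI is None else repr(c.conANI)
            pop = "" if c.popANI is None else repr(c.popANI)
            fh.write(
                f"{c.sample_a}\t{c.sample_b}\t{c.genome_id}\t"
                f"{c.compared_positions}\t{c.con_subs}\t{c.pop_subs}\t{con}\t"
                f"{pop}\t{c.percent_genome_compared!r}\t{d.verdict}\t{d.edge_case}\n"
            )


def read_comparisons_tsv(path) -> list[SharingDecision]:
    decisions = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            result = ComparisonResult(
                row["sample_a"],
                row["sample_b"],
                row["genome_id"],
                int(row["compared_positions"]),
                int(row["con_subs"]),
                int(row["pop_subs"]),
                float(row["conANI"]) if row["conANI"] else None,
                float(row["popANI"]) if row["popANI"] else None,
                float(row["percent_genome_compared"]),
            )
            decisions.append(
                SharingDecision(result, row["verdict"], row["edge_case"] == "True")
            )
    return decisions


def write_calls_tsv(calls: list[ContaminationCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_kind\ttarget_id\tcategory\tscore\tn_evidence\n")
        for c in sorted(calls, key=lambda c: (-c.score, c.target_kind, c.target_id)):
            fh.write(
                f"{c.target_kind}\t{c.target_id}\t{c.category}\t"
                f"{c.score:.3f}\t{len(c.evidence)}\n"
            )


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write every stage output; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": out / "detections.tsv",
        "comparisons": out / "comparisons.tsv",
        "edges": out / "edges.tsv",
        "graphml": out / "network.graphml",
        "proximity": out / "proximity.tsv",
        "calls": out / "calls.tsv",
        "report_json": out / "report.json",
        "report_txt": out / "report.txt",
        "exclusions": out / "exclusions.txt",
    }
    write_detections_tsv(result.detections, paths["detections"])
    write_comparisons_tsv(result.decisions, paths["comparisons"])
    write_edges_tsv(result.edges, paths["edges"])
    write_graphml(result.edges, result.bundle.samples, paths["graphml"])
    write_proximity_tsv(result.proximity, paths["proximity"])
    write_calls_tsv(result.strain_calls + result.sample_calls, paths["calls"])
    paths["report_json"].write_text(report_to_json(result.report), encoding="utf-8")
    paths["report_txt"].write_text(render_text(result.report), encoding="utf-8")
    paths["exclusions"].write_text(
        "".join(f"{sid}\n" for sid in result.report["exclusions"]), encoding="utf-8"
    )
    return paths
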