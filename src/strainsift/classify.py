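"""Rule-based classification of contamination sources.

Strain clusters and samples are sorted into four mechanisms:

* ``external``            one strain across a majority of subjects and at
  least two extraction plates (or in negative controls of several plates):
  reagent/kit/handler DNA enters many wells independently.
* ``well_to_well``        a sample shares strains that are otherwise private
  to one other family, with the cluster confined to a single plate; the
  flagged sample is its own family's only carrier while the putative source
  family carries the strain in several samples (or the flagged sample is a
  negative control).  Adjacency on the plate and a significant plate-level
  proximity test strengthen the call and can substitute for exclusivity.
* ``cross_plate_leakage`` a cluster spanning plates of one sequencing pool,
  dominated by a single family's high-depth libraries with all other
  carriers at a small fraction of that depth and no plate-proximity
  structure — the signature of index switching / sample bleeding.
* ``residual_sharing``    cross-plate multi-subject sharing at normal depth
  without proximity structure and below the external fraction: plausibly a
  biologically circulating (e.g. hospital-acquired) strain.

Precedence is total: external > well_to_well > cross_plate_leakage >
residual_sharing.  Evidence that fires without completing a rule surfaces as
``ambiguous`` rather than silently vanishing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

from .model import SampleMeta
from .network import SharingEdge, StrainScope, is_unrelated
from .platestats import ProximityTestResult, rank_sum_test, sample_pair_distance

CATEGORIES = (
    "external",
    "well_to_well",
    "cross_plate_leakage",
    "residual_sharing",
    "ambiguous",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Operationalizations of the classification rules.

    ``external_subject_fraction`` encodes "the majority of subjects";
    ``adjacency_radius`` = 1.5 grid units covers the eight wells surrounding
    a well; ``exclusivity_max_subjects`` bounds how many families besides the
    putative source may carry a strain for it to count as "otherwise unique";
    ``leakage_depth_ratio`` is the maximum recipient/donor depth ratio for
    the leakage signature.
    """

    external_min_plates: int = 2
    external_subject_fraction: float = 0.5
    adjacency_radius: float = 1.5
    exclusivity_max_subjects: int = 1
    min_exclusive_strains: int = 1
    alpha: float = 0.05
    leakage_depth_ratio: float = 0.2
    proximity_adjacent_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.external_min_plates < 1 or self.min_exclusive_strains < 1:
            raise ValueError("thresholds must be positive")
        if not 0 < self.external_subject_fraction <= 1:
            raise ValueError("external_subject_fraction must be in (0, 1]")
        if self.adjacency_radius <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class Evidence:
    rule: str
    detail: str
    supporting: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"rule": self.rule, "detail": self.detail,
                "supporting": list(self.supporting)}


@dataclass(frozen=True)
class ContaminationCall:
    target_kind: str  # strain | sample
    target_id: str
    category: str
    evidence: tuple[Evidence, ...]
    score: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category != "ambiguous" and not self.evidence:
            raise ValueError("non-ambiguous call requires evidence")

    def to_dict(self) -> dict:
        return {
            "target_kind": self.target_kind,
            "target_id": self.target_id,
            "category": self.category,
            "score": self.score,
            "evidence": [e.to_dict() for e in self.evidence],
        }


def _scope_id(scope: StrainScope) -> str:
    return f"{scope.genome_id}.c{scope.cluster_index}"


def proximity_correlated(
    scope: StrainScope,
    samples: list[SampleMeta],
    radius: float = 1.5,
    min_fraction: float = 0.5,
) -> bool:
    """Whether a strain cluster's carriers cluster spatially on plates.

    True when more than ``min_fraction`` of the unrelated within-plate
    carrier pairs sit within ``radius`` grid units of each other.
    """
    by_id = {s.sample_id: s for s in samples}
    metas = [by_id[c] for c in scope.carriers if by_id[c].placed]
    n_pairs = 0
    n_adj = 0
    for a, b in itertools.combinations(metas, 2):
        if not is_unrelated(a, b):
            continue
        for plate in set(a.plate_ids) & set(b.plate_ids):
            d = sample_pair_distance(a, b, plate)
            if d is not None:
                n_pairs += 1
                if d <= radius:
                    n_adj += 1
                break
    return n_pairs > 0 and n_adj / n_pairs > min_fraction


def _has_cross_plate_consensus_edge(
    scope: StrainScope,
    samples: list[SampleMeta],
    con_map: dict[tuple[str, str, str], float],
    consensus_threshold: float,
) -> bool:
    """Whether two carriers on different plates share the strain at the
    *consensus* level (conANI above threshold).

    A popANI link between two strain mixtures says only that their
    detected-allele sets overlap; it does not demonstrate that the same
    haplotype dominates both samples.  Genuine circulating strains connect
    plates through consensus-identical carriers.
    """
    by_id = {s.sample_id: s for s in samples}
    for a, b in itertools.combinations(sorted(scope.carriers), 2):
        con = con_map.get((a, b, scope.genome_id))
        if con is None or con < consensus_threshold:
            continue
        pa, pb = set(by_id[a].plate_ids), set(by_id[b].plate_ids)
        if pa and pb and not (pa & pb):
            return True
    return False


def classify_strain(
    scope: StrainScope,
    samples: list[SampleMeta],
    config: ClassifierConfig,
    con_map: dict[tuple[str, str, str], float] | None = None,
    consensus_threshold: float = 0.99999,
) -> ContaminationCall | None:
    """Strain-level external / residual-sharing rules.

    Returns ``None`` when neither rule fires; such clusters are left for the
    sample-level well-to-well and leakage rules.  When ``con_map`` (pairwise
    conANI of shared verdicts) is supplied, a residual-sharing call requires
    the cluster to span plates through consensus-identical carriers, so
    chains of strain *mixtures* do not masquerade as a circulating strain.
    """
    nc_plates = {
        p
        for s in samples
        if s.sample_id in scope.in_negative_controls
        for p in s.plate_ids
    }
    multi_plate = len(scope.plates) >= config.external_min_plates
    majority = scope.subject_fraction >= config.external_subject_fraction
    in_many_ncs = len(nc_plates) >= 2

    if multi_plate and (majority or in_many_ncs):
        ev = [
            Evidence(
                "multi_plate",
                f"carriers on {len(scope.plates)} plates",
                tuple(sorted(scope.plates)),
            )
        ]
        if majority:
            ev.append(
                Evidence(
                    "subject_majority",
                    f"{scope.subject_fraction:.2f} of subjects carry the strain",
                    tuple(sorted(scope.subjects)),
                )
            )
        if in_many_ncs:
            ev.append(
                Evidence(
                    "nc_spread",
                    f"in negative controls of {len(nc_plates)} plates",
                    tuple(sorted(scope.in_negative_controls)),
                )
            )
        return ContaminationCall(
            "strain", _scope_id(scope), "external", tuple(ev),
            score=(1 + majority + in_many_ncs) / 3,
        )

    if (
        multi_plate
        and len(scope.subjects) >= 2
        and scope.subject_fraction < config.external_subject_fraction
        and not proximity_correlated(
            scope, samples, config.adjacency_radius, config.proximity_adjacent_fraction
        )
        and (
            con_map is None
            or _has_cross_plate_consensus_edge(
                scope, samples, con_map, consensus_threshold
            )
        )
    ):
        return ContaminationCall(
            "strain",
            _scope_id(scope),
            "residual_sharing",
            (
                Evidence(
                    "cross_plate_no_proximity",
                    f"{len(scope.subjects)} subjects on {len(scope.plates)} plates "
                    "without spatial clustering",
                    tuple(sorted(scope.carriers)),
                ),
            ),
            score=1.0,
        )
    return None


def detect_cross_plate_leakage(
    scopes: list[StrainScope],
    samples: list[SampleMeta],
    config: ClassifierConfig,
    depths: dict[tuple[str, str], float],
    con_map: dict[tuple[str, str, str], float] | None = None,
    consensus_threshold: float = 0.99999,
) -> list[ContaminationCall]:
    """Index-switching / sample-bleeding signature, per strain cluster.

    The putative leaking library is the family of the cluster's deepest
    carrier; its direct sharing partners are the recipients.  Partners that
    carry the donor strain as their *consensus* (conANI above threshold) are
    pure leaked material and must sit at low abundance (<=
    ``leakage_depth_ratio`` of the donor depth) — a consensus-identical
    partner at normal depth is a genuine co-carrier and vetoes the call.
    Partners sharing only at the popANI level carry the leaked strain as a
    minor mixture component on top of their own strain, so their total depth
    is uninformative.  The donor family plus recipients must lie in one
    sequencing pool, reach at least one plate the donors are not on, and
    show no plate-proximity structure.
    """
    by_id = {s.sample_id: s for s in samples}
    calls = []
    for scope in scopes:
        if len(scope.plates) < 2:
            continue
        d = {c: depths.get((c, scope.genome_id), 0.0) for c in scope.carriers}
        top = max(sorted(d), key=lambda c: d[c])
        donor_family = by_id[top].family_id
        if donor_family is None:
            continue
        donors = {c for c in scope.carriers if by_id[c].family_id == donor_family}
        dmax = max(d[c] for c in donors)
        if dmax <= 0:
            continue

        def _con(a: str, b: str) -> float | None:
            if con_map is None:
                return None
            x, y = sorted((a, b))
            return con_map.get((x, y, scope.genome_id))

        pure: set[str] = set()
        mixture: set[str] = set()
        genuine_cocarrier = False
        for c in sorted(scope.carriers - donors):
            if con_map is None:
                # No consensus information: classify by depth alone.
                if d[c] <= config.leakage_depth_ratio * dmax:
                    pure.add(c)
                else:
                    genuine_cocarrier = True
                    break
                continue
            cons = [v for v in (_con(c, dn) for dn in donors) if v is not None]
            if not cons:
                continue  # not a direct partner of the donor family
            if max(cons) >= consensus_threshold:
                if d[c] <= config.leakage_depth_ratio * dmax:
                    pure.add(c)
                else:
                    genuine_cocarrier = True
                    break
            else:
                mixture.add(c)
        if genuine_cocarrier:
            continue

        recipients = pure | mixture
        if not recipients:
            continue
        cluster = donors | recipients
        pools = {by_id[c].pool_id for c in cluster if by_id[c].pool_id}
        if len(pools) != 1:
            continue
        donor_plates = {p for c in donors for p in by_id[c].plate_ids}
        recipient_plates = {p for c in recipients for p in by_id[c].plate_ids}
        if not (recipient_plates - donor_plates):
            continue
        cluster_scope = replace(scope, carriers=frozenset(cluster))
        if proximity_correlated(
            cluster_scope, samples, config.adjacency_radius,
            config.proximity_adjacent_fraction,
        ):
            continue
        (pool,) = pools
        calls.append(
            ContaminationCall(
                "strain",
                _scope_id(scope),
                "cross_plate_leakage",
                (
                    Evidence(
                        "pool_confined_low_abundance",
                        f"donor library from family {donor_family} in pool "
                        f"{pool}; {len(pure)} consensus recipient(s) at <= "
                        f"{config.leakage_depth_ratio:.0%} of donor depth and "
                        f"{len(mixture)} mixture recipient(s) across "
                        f"{len(donor_plates | recipient_plates)} plates",
                        tuple(sorted(donors)) + tuple(sorted(recipients)),
                    ),
                ),
                score=1.0,
            )
        )
    return calls


def _family_key(meta: SampleMeta) -> str | None:
    return meta.family_id or meta.subject_id


def genome_partner_map(
    edges: list[SharingEdge],
) -> dict[str, dict[str, set[str]]]:
    """sample -> genome -> set of partners sharing that genome's strain."""
    out: dict[str, dict[str, set[str]]] = {}
    for e in edges:
        for g in e.shared_genomes:
            out.setdefault(e.sample_a, {}).setdefault(g, set()).add(e.sample_b)
            out.setdefault(e.sample_b, {}).setdefault(g, set()).add(e.sample_a)
    return out


def flag_well_to_well(
    sample: SampleMeta,
    edges: list[SharingEdge],
    samples: list[SampleMeta],
    proximity: dict[str, ProximityTestResult],
    config: ClassifierConfig,
) -> ContaminationCall | None:
    """Sample-level well-to-well contamination rule.

    For each genome the sample shares, every family with >= 2 carrier
    samples among the sharing partners is a candidate source.  Evidence
    channels, evaluated per candidate family F and recorded separately:

    A. adjacency — the sample shares >= 1 strain with an unrelated sample
       within ``adjacency_radius`` on the same plate;
    B. source-exclusivity — F's strain is otherwise unique to F: besides the
       flagged sample, the samples sharing the genome with F's carriers span
       at most ``exclusivity_max_subjects`` other biological families (no
       distance requirement: long-range transfer within a plate counts);
    C. plate-confinement — F's carriers and everyone sharing with them sit
       on a single plate;
    D. direction — no other sample from the flagged sample's family shares
       with F (the sample is its family's sole sharer, while F carries the
       strain in several samples; negative controls pass trivially).

    Category ``well_to_well`` when >= ``min_exclusive_strains`` genomes have
    a candidate family passing B, C and D, or when a candidate passes C and
    D with adjacency and a significant plate proximity test; ``ambiguous``
    when adjacency plus a confined directional candidate exist without the
    corroborating exclusivity or plate-level signal.

    A read-misassignment leak that happens to stay on one plate produces the
    same evidence pattern as a transfer and will be flagged here; the
    cross-plate-leakage rule takes over only when the leak demonstrably
    reaches other plates.
    """
    if not sample.placed:
        return None
    by_id = {s.sample_id: s for s in samples}
    sid = sample.sample_id
    pm = genome_partner_map(edges)
    mine = pm.get(sid, {})
    if not mine:
        return None

    all_partners = sorted(set().union(*mine.values()))
    adjacent_partners = []
    for pid in all_partners:
        other = by_id[pid]
        for plate in set(sample.plate_ids) & set(other.plate_ids):
            d = sample_pair_distance(sample, other, plate)
            if d is not None and d <= config.adjacency_radius:
                adjacent_partners.append(pid)
                break
    channel_a = bool(adjacent_partners)

    own_family = _family_key(sample)
    own_members = {
        s.sample_id for s in samples if own_family and _family_key(s) == own_family
    }

    supporting: list[tuple[str, str]] = []  # (genome, source family)
    relaxed: list[tuple[str, str]] = []
    for g in sorted(mine):
        candidates: dict[str, list[str]] = {}
        for pid in mine[g]:
            meta = by_id[pid]
            fam = _family_key(meta)
            if meta.role == "biological" and fam and fam != own_family:
                candidates.setdefault(fam, []).append(pid)
        for fam, members in sorted(candidates.items()):
            if len(members) < 2:
                continue
            # Everyone sharing this genome's strain with the candidate
            # family, anywhere in the study.
            fam_carriers = [
                s.sample_id
                for s in samples
                if _family_key(s) == fam and g in pm.get(s.sample_id, {})
            ]
            spread = set()
            for fc in fam_carriers:
                spread |= pm[fc].get(g, set())
            direction = not (spread & own_members - {sid})
            other_families = {
                _family_key(by_id[p])
                for p in spread - {sid}
                if by_id[p].role == "biological" and _family_key(by_id[p]) != fam
            }
            involved = set(fam_carriers) | spread | {sid}
            plates = {p for m in involved for p in by_id[m].plate_ids}
            confined = len(plates) == 1
            if direction and confined:
                if len(other_families) <= config.exclusivity_max_subjects:
                    supporting.append((g, fam))
                else:
                    relaxed.append((g, fam))

    plate_significant = any(
        proximity.get(p) is not None
        and proximity[p].testable
        and proximity[p].p_value < config.alpha
        for p in sample.plate_ids
    )

    def _call(channels: list[Evidence], score: float, category: str):
        return ContaminationCall("sample", sid, category, tuple(channels), score)

    channels: list[Evidence] = []
    if channel_a:
        channels.append(
            Evidence(
                "adjacency",
                f"shares strains with {len(adjacent_partners)} unrelated "
                f"sample(s) within {config.adjacency_radius} grid units",
                tuple(adjacent_partners),
            )
        )
    support_genomes = sorted({g for g, _ in supporting})
    if len(support_genomes) >= config.min_exclusive_strains:
        families = sorted({f for _, f in supporting})
        channels.append(
            Evidence(
                "source_exclusivity",
                f"{len(support_genomes)} shared strain(s) otherwise unique to "
                f"source family/families {', '.join(families)}",
                tuple(support_genomes),
            )
        )
        channels.append(
            Evidence(
                "plate_confinement",
                "supporting strains have no cross-plate carriers",
                tuple(families),
            )
        )
        score = (2 + channel_a + plate_significant) / 4
        return _call(channels, score, "well_to_well")
    if channel_a and relaxed:
        channels.append(
            Evidence(
                "plate_confinement",
                "plate-confined multi-sample source family without exclusivity",
                tuple(sorted({f for _, f in relaxed})),
            )
        )
        if plate_significant:
            channels.append(
                Evidence(
                    "plate_proximity",
                    f"plate proximity test significant at alpha={config.alpha}",
                    tuple(sample.plate_ids),
                )
            )
            return _call(channels, 3 / 4, "well_to_well")
        return _call(channels, 2 / 4, "ambiguous")
    return None


def biomass_association(
    flagged: set[str],
    unflagged: set[str],
    samples: list[SampleMeta],
    alternative: str = "two_sided",
    method: str = "normal_approx",
    rng=None,
) -> dict:
    """Rank-sum test of DNA-yield biomass, flagged vs unflagged samples.

    Samples with unknown biomass are excluded and counted.  Returns a dict
    with the test result, group sizes and medians; ``testable`` is False
    when either group is empty after exclusions.
    """
    by_id = {s.sample_id: s for s in samples}
    x = [by_id[s].biomass for s in sorted(flagged) if by_id[s].biomass is not None]
    y = [by_id[s].biomass for s in sorted(unflagged) if by_id[s].biomass is not None]
    n_missing = (len(flagged) - len(x)) + (len(unflagged) - len(y))
    if not x or not y:
        return {
            "testable": False,
            "n_flagged": len(x),
            "n_unflagged": len(y),
            "n_missing_biomass": n_missing,
        }
    res = rank_sum_test(x, y, alternative=alternative, method=method, rng=rng)
    xs = sorted(x)
    ys = sorted(y)
    return {
        "testable": True,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "method": res.method,
        "alternative": alternative,
        "n_flagged": len(x),
        "n_unflagged": len(y),
        "n_missing_biomass": n_missing,
        "median_flagged": xs[len(xs) // 2],
        "median_unflagged": ys[len(ys) // 2],
    }


# ---------------------------------------------------------------------------
# report


REPORT_SCHEMA: dict[str, type] = {
    "thresholds": dict,
    "n_samples": int,
    "n_genomes": int,
    "n_subjects": int,
    "proximity": list,
    "negative_controls": list,
    "positive_controls": list,
    "zymo": dict,
    "strain_calls": list,
    "sample_calls": list,
    "uncategorized_nc_detections": list,
    "exclusions": list,
    "categories": list,
    "biomass": dict,
}

_CALL_KEYS = {"target_kind", "target_id", "category", "score", "evidence"}


def validate_report(report: dict) -> None:
    """Structural schema check; raises ValueError on violation."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report[{key!r}] should be {typ.__name__}, "
                f"got {type(report[key]).__name__}"
            )
    for call in report["strain_calls"] + report["sample_calls"]:
        missing = _CALL_KEYS - set(call)
        if missing:
            raise ValueError(f"call missing keys {sorted(missing)}")
        if call["category"] not in CATEGORIES:
            raise ValueError(f"unknown category {call['category']!r}")
        if call["category"] != "ambiguous" and not call["evidence"]:
            raise ValueError("non-ambiguous call without evidence")
    for cat in report["categories"]:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def render_text(report: dict) -> str:
    """Human-readable summary of a contamination report."""
    lines = [
        "Contamination report",
        "====================",
        f"samples: {report['n_samples']}  genomes: {report['n_genomes']}  "
        f"subjects: {report['n_subjects']}",
        "",
        "Per-plate proximity tests (distance vs strain sharing):",
    ]
    for p in report["proximity"]:
        if p["testable"]:
            lines.append(
                f"  {p['plate_id']}: z={p['statistic']:.3f} "
                f"p={p['p_value']:.3g} ({p['n_sharing_pairs']} sharing vs "
                f"{p['n_nonsharing_pairs']} non-sharing pairs)"
            )
        else:
            lines.append(f"  {p['plate_id']}: untestable")
    lines.append("")
    lines.append("Negative controls:")
    for nc in report["negative_controls"]:
        lines.append(
            f"  {nc['sample_id']}: {nc['n_genomes_detected']} genomes detected, "
            f"{nc['n_shared_strains']} shared strain(s)"
        )
    lines.append("")
    lines.append("Calls:")
    for call in report["strain_calls"] + report["sample_calls"]:
        lines.append(
            f"  [{call['category']}] {call['target_kind']} {call['target_id']} "
            f"(score {call['score']:.2f})"
        )
        for ev in call["evidence"]:
            lines.append(f"      - {ev['rule']}: {ev['detail']}")
    if report["exclusions"]:
        lines.append("")
        lines.append("Suggested exclusions: " + ", ".join(report["exclusions"]))
    return "\n".join(lines) + "\n"
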