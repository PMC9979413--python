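"""Strain-sharing network over unrelated sample pairs.

Strain sharing between biologically related samples (same subject, or
subjects in the same family such as twins or a mother-infant pair) is
expected; only sharing between *unrelated* samples — different, unrelated
subjects, or any pair involving a negative control — is suspicious.  This
module builds the graph of unrelated pairs sharing at least one strain and
rolls each genome's sharing up into connected *strain clusters* annotated
with the carriers' subjects, plates, pools and negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .compare import SharingDecision
from .model import SampleMeta


@dataclass(frozen=True)
class SharingEdge:
    """An unrelated sample pair sharing >= 1 strain."""

    sample_a: str
    sample_b: str
    shared_genomes: frozenset[str]

    @property
    def n_strains(self) -> int:
        return len(self.shared_genomes)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.sample_a, self.sample_b))


@dataclass(frozen=True)
class StrainScope:
    """One connected strain cluster of one genome and its rollups.

    ``subject_fraction`` is the fraction of the study's biological subjects
    with at least one carrier sample; controls never enter the denominator.
    """

    genome_id: str
    cluster_index: int
    carriers: frozenset[str]
    subjects: frozenset[str]
    families: frozenset[str]
    plates: frozenset[str]
    pools: frozenset[str]
    in_negative_controls: frozenset[str]
    subject_fraction: float


def is_unrelated(
    a: SampleMeta, b: SampleMeta, treat_pc_as_subject: bool = False
) -> bool:
    """True when strain sharing between ``a`` and ``b`` would be suspicious.

    Samples are unrelated if they come from different subjects that are not
    biologically related (different families), or if either is a negative
    control.  Pairs involving a positive control are related by default (the
    mock community is not a study subject) unless ``treat_pc_as_subject``.
    """
    if a.sample_id == b.sample_id:
        return False
    if a.role == "negative_control" or b.role == "negative_control":
        return True
    for s in (a, b):
        if s.role == "positive_control" and not treat_pc_as_subject:
            return False
    if a.subject_id and b.subject_id and a.subject_id == b.subject_id:
        return False
    if a.family_id and b.family_id and a.family_id == b.family_id:
        return False
    return True


def build_network(
    decisions: list[SharingDecision],
    samples: list[SampleMeta],
    treat_pc_as_subject: bool = False,
) -> list[SharingEdge]:
    """One edge per unrelated pair with >= 1 ``shared`` verdict.

    ``shared_genomes`` is exactly the set of genomes with a shared verdict
    for the pair; edges are ordered lexicographically by sample ids.
    """
    by_id = {s.sample_id: s for s in samples}
    shared: dict[tuple[str, str], set[str]] = {}
    for d in decisions:
        if d.verdict != "shared":
            continue
        c = d.comparison
        a, b = sorted((c.sample_a, c.sample_b))
        if not is_unrelated(by_id[a], by_id[b], treat_pc_as_subject):
            continue
        shared.setdefault((a, b), set()).add(c.genome_id)
    return [
        SharingEdge(a, b, frozenset(genomes))
        for (a, b), genomes in sorted(shared.items())
    ]


def strain_scopes(
    edges: list[SharingEdge],
    samples: list[SampleMeta],
) -> list[StrainScope]:
    """Connected strain clusters per genome, with carrier rollups.

    popANI sharing is not guaranteed transitive, so "a single strain across
    many samples" is modelled conservatively as a connected component of the
    per-genome sharing graph.
    """
    by_id = {s.sample_id: s for s in samples}
    n_subjects = len(
        {s.subject_id for s in samples if s.role == "biological" and s.subject_id}
    )

    genomes = sorted({g for e in edges for g in e.shared_genomes})
    scopes: list[StrainScope] = []
    for gid in genomes:
        graph = nx.Graph()
        for e in edges:
            if gid in e.shared_genomes:
                graph.add_edge(e.sample_a, e.sample_b)
        components = sorted(nx.connected_components(graph), key=sorted)
        for k, comp in enumerate(components):
            carriers = frozenset(comp)
            metas = [by_id[c] for c in carriers]
            subjects = frozenset(
                m.subject_id for m in metas if m.role == "biological" and m.subject_id
            )
            families = frozenset(
                m.family_id for m in metas if m.role == "biological" and m.family_id
            )
            plates = frozenset(p for m in metas for p in m.plate_ids)
            pools = frozenset(m.pool_id for m in metas if m.pool_id)
            ncs = frozenset(
                m.sample_id for m in metas if m.role == "negative_control"
            )
            scopes.append(
                StrainScope(
                    genome_id=gid,
                    cluster_index=k,
                    carriers=carriers,
                    subjects=subjects,
                    families=families,
                    plates=plates,
                    pools=pools,
                    in_negative_controls=ncs,
                    subject_fraction=(len(subjects) / n_subjects) if n_subjects else 0.0,
                )
            )
    return scopes


def to_graph(
    edges: list[SharingEdge], samples: list[SampleMeta]
) -> nx.Graph:
    """Sharing network as a networkx graph with plate/well attributes."""
    by_id = {s.sample_id: s for s in samples}
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.sample_a, e.sample_b, n_strains=e.n_strains,
                       shared_genomes=",".join(sorted(e.shared_genomes)))
    for node in graph.nodes:
        s = by_id[node]
        graph.nodes[node]["role"] = s.role
        graph.nodes[node]["subject_id"] = s.subject_id or ""
        if s.wells:
            w = s.wells[0]
            graph.nodes[node]["plate_id"] = w.plate_id
            graph.nodes[node]["row"] = w.row
            graph.nodes[node]["col"] = w.col
    return graph


def write_edges_tsv(edges: list[SharingEdge], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_a\tsample_b\tn_strains\tshared_genomes\n")
        for e in edges:
            fh.write(
                f"{e.sample_a}\t{e.sample_b}\t{e.n_strains}\t"
                f"{','.join(sorted(e.shared_genomes))}\n"
            )


def write_graphml(edges: list[SharingEdge], samples: list[SampleMeta], path) -> None:
    nx.write_graphml(to_graph(edges, samples), path)
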