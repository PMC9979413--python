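"""Synthetic multi-subject plate-extracted metagenomics studies.

The generator emulates the statistical structure the contamination analysis
assumes: each subject carries private strains of a shared species pool
(twins share their family's strains), samples from one subject are loaded
sequentially along plate columns, per-sample sequencing depth scales with
DNA yield (the biomass proxy), and negative controls contain nothing unless
a planted event injects material.  Four contamination mechanisms can be
planted with full truth labels:

* ``well_to_well``       a fraction of one well's DNA spills into another;
* ``external_reagent``   a reagent strain hits samples with probability
  inversely proportional to biomass, at a depth independent of the recipient;
* ``index_switch``       pooled-lane read misassignment leaks a dominant
  library into other samples of the same sequencing pool, across plates;
* ``zymo_spill``         mock-community DNA from a positive control reaches a
  neighbouring well.

Everything is reproducible from the config seed; per-sample render streams
are derived by stable hashing of the sample id so adding a sample does not
perturb the others.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    GenomeRef,
    PlateDims,
    PositionProfile,
    SampleMeta,
    StudyBundle,
    WellAddress,
)
from .network import SharingEdge
from .platestats import sample_pair_distance

#: For each true base index, the three other base indices (error targets).
_OTHERS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.intp)

EVENT_KINDS = ("well_to_well", "external_reagent", "index_switch", "zymo_spill")


@dataclass(frozen=True)
class ContaminationEvent:
    """One planted contamination event; use the per-kind constructors."""

    kind: str
    source: str | None = None
    target: str | None = None
    fraction: float | None = None
    genome_id: str | None = None
    rate: float | None = None
    depth: float | None = None
    pool_id: str | None = None
    affected_fraction: float = 0.1
    donor_subject: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        for name in ("fraction", "rate", "affected_fraction"):
            v = getattr(self, name)
            if v is not None and not 0 <= v < 1:
                raise ValueError(f"{self.kind}: {name}={v} outside [0, 1)")

    @classmethod
    def well_to_well(cls, source: str, target: str, fraction: float):
        return cls("well_to_well", source=source, target=target, fraction=fraction)

    @classmethod
    def external_reagent(
        cls, rate: float, depth: float, genome_id: str | None = None
    ):
        return cls("external_reagent", rate=rate, depth=depth, genome_id=genome_id)

    @classmethod
    def index_switch(
        cls,
        pool_id: str,
        rate: float,
        affected_fraction: float = 0.1,
        donor_subject: str | None = None,
        genome_id: str | None = None,
    ):
        return cls(
            "index_switch",
            pool_id=pool_id,
            rate=rate,
            affected_fraction=affected_fraction,
            donor_subject=donor_subject,
            genome_id=genome_id,
        )

    @classmethod
    def zymo_spill(cls, source: str, target: str, fraction: float):
        return cls("zymo_spill", source=source, target=target, fraction=fraction)


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration.

    Defaults describe the emulated study conditions: 20 subjects (one twin
    family), three longitudinal gut samples each, two 8x12 extraction plates
    loaded column-sequentially with one reagent-only negative control per
    plate, two plates pooled per sequencing run, six species with
    subject-private strains at 0.5% pairwise divergence over 10 kb genomes,
    50x mean depth at 20 ng/uL DNA yield, and 0.1% sequencing error.
    """

    seed: int = 0
    n_subjects: int = 20
    samples_per_subject: int = 3
    n_families_with_twins: int = 1
    sample_type: str = "gut"
    n_plates: int = 2
    plate_dims: tuple[int, int] = (8, 12)
    plates_per_pool: int = 2
    placement: str = "column_sequential"  # or "random"
    nc_per_plate: int = 1
    pc_per_plate: int = 0
    n_species: int = 6
    strains_per_species: int | None = None  # None: private strain per family
    hospital_species: int = 0
    hospital_carrier_frac: float = 0.3
    carriage_prob: float = 0.7
    genome_length: int = 10_000
    strain_divergence: float = 0.005
    seq_error: float = 0.001
    depth_per_biomass: float = 2.5  # 50x at 20 ng/uL
    biomass_by_type: dict = field(
        default_factory=lambda: {
            "gut": (20.0, 0.6),
            "oral": (5.0, 0.6),
            "skin": (2.0, 0.6),
            "other": (5.0, 0.6),
        }
    )
    nc_biomass: float = 0.2
    pc_biomass: float = 20.0
    n_zymo_species: int = 0
    zymo_depth: float = 100.0
    biomass_overrides: dict = field(default_factory=dict)
    events: tuple[ContaminationEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.strain_divergence <= 0.05:
            raise ValueError(
                f"strain_divergence must be in (0, 0.05], got {self.strain_divergence}"
            )
        for name in (
            "n_subjects",
            "samples_per_subject",
            "n_plates",
            "n_species",
            "genome_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_families_with_twins * 2 > self.n_subjects:
            raise ValueError("more twin subjects than subjects")
        if self.hospital_species > self.n_species:
            raise ValueError("hospital_species exceeds n_species")
        if self.placement not in ("column_sequential", "random"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class StudyPlan:
    """Deterministic study layout before profile rendering."""

    config: SimConfig
    samples: list[SampleMeta]
    genomes: list[GenomeRef]
    plates: dict[str, PlateDims]
    family_of: dict[str, str]  # subject -> family
    carriage: dict[str, dict[str, int]]  # family -> {genome_id: strain index}
    strain_counts: dict[str, int]
    endogenous: dict[str, list[tuple[str, int, float]]]  # sample -> components
    hospital_gids: tuple[str, ...]
    zymo_gids: tuple[str, ...]


@dataclass
class SimTruth:
    """Planted ground truth for one simulated study."""

    events: tuple[ContaminationEvent, ...]
    affected: dict[int, tuple[str, ...]]  # event index -> recipient samples
    strain_labels: dict[str, dict]

    @property
    def contaminated_by(self) -> dict[str, tuple[int, ...]]:
        out: dict[str, list[int]] = {}
        for j, sids in self.affected.items():
            for sid in sids:
                out.setdefault(sid, []).append(j)
        return {sid: tuple(v) for sid, v in out.items()}

    def is_clean(self, sample_id: str) -> bool:
        return sample_id not in self.contaminated_by

    def well_to_well_targets(self) -> list[str]:
        return [
            e.target
            for e in self.events
            if e.kind == "well_to_well" and e.target is not None
        ]

    def to_dict(self) -> dict:
        return {
            "events": [
                {k: v for k, v in vars(e).items() if v is not None}
                for e in self.events
            ],
            "affected": {str(j): list(s) for j, s in self.affected.items()},
            "contaminated_by": {
                sid: list(js) for sid, js in self.contaminated_by.items()
            },
            "strain_labels": self.strain_labels,
        }


# ---------------------------------------------------------------------------
# planning


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return _rng(seed, 3, zlib.crc32(sample_id.encode()))


def plan_study(config: SimConfig) -> StudyPlan:
    """Lay out subjects, families, plates, biomass, carriage and strains.

    The plan depends only on the non-event config fields and the seed, so
    event lists can be chosen after inspecting the plan without perturbing
    placement or strain assignment.
    """
    rng = _rng(config.seed, 0)
    n_rows, n_cols = config.plate_dims
    dims = PlateDims(
        tuple(chr(ord("A") + i) for i in range(n_rows)),
        tuple(str(i + 1) for i in range(n_cols)),
    )

    # Subjects and families: twin pairs first, then singletons.
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    family_of: dict[str, str] = {}
    fam = 0
    i = 0
    for _ in range(config.n_families_with_twins):
        fam += 1
        family_of[subjects[i]] = f"F{fam:02d}"
        family_of[subjects[i + 1]] = f"F{fam:02d}"
        i += 2
    while i < config.n_subjects:
        fam += 1
        family_of[subjects[i]] = f"F{fam:02d}"
        i += 1
    families = list(dict.fromkeys(family_of.values()))

    # Species genomes: hospital species (shared single strain) first.
    genomes = [
        GenomeRef(
            f"g{k + 1:02d}",
            config.genome_length,
            "hospital" if k < config.hospital_species else "species",
        )
        for k in range(config.n_species)
    ]
    hospital_gids = tuple(g.genome_id for g in genomes[: config.hospital_species])
    zymo_gids = tuple(f"z{k + 1:02d}" for k in range(config.n_zymo_species))
    genomes += [GenomeRef(z, config.genome_length, "zymo") for z in zymo_gids]

    # Carriage and strain assignment, per family (twins share strains).
    carriage: dict[str, dict[str, int]] = {f: {} for f in families}
    strain_counts: dict[str, int] = {}
    for gid in hospital_gids:
        k = max(2, round(config.hospital_carrier_frac * len(families)))
        carriers = rng.choice(len(families), size=min(k, len(families)), replace=False)
        for ci in sorted(carriers):
            carriage[families[ci]][gid] = 0
        strain_counts[gid] = 1
    private_gids = [g.genome_id for g in genomes[config.hospital_species:config.n_species]]
    for gid in private_gids:
        order = 0
        for f in families:
            if rng.random() < config.carriage_prob:
                idx = (
                    order % config.strains_per_species
                    if config.strains_per_species
                    else order
                )
                carriage[f][gid] = idx
                order += 1
        strain_counts[gid] = (
            min(order, config.strains_per_species)
            if config.strains_per_species
            else order
        )
    for f in families:  # every family carries something
        if not carriage[f] and private_gids:
            gid = private_gids[int(rng.integers(len(private_gids)))]
            carriage[f][gid] = strain_counts[gid]
            strain_counts[gid] += 1
    for z in zymo_gids:
        strain_counts[z] = 1

    # Biomass per sample.
    median, sigma = config.biomass_by_type[config.sample_type]
    biomass: dict[str, float] = {}
    sample_ids: dict[str, list[str]] = {}
    for subj in subjects:
        sample_ids[subj] = [
            f"{subj}_T{t + 1}" for t in range(config.samples_per_subject)
        ]
        for sid in sample_ids[subj]:
            b = float(rng.lognormal(math.log(median), sigma))
            if subj in config.biomass_overrides:
                b = float(config.biomass_overrides[subj])
            biomass[sid] = b

    # Placement: subjects in contiguous blocks per plate, samples loaded
    # column-sequentially (index -> (row, col) column-major), controls after
    # the biological samples of each plate.
    plate_ids = [f"P{p + 1}" for p in range(config.n_plates)]
    plates = {p: dims for p in plate_ids}
    plate_of_subject = {
        s: plate_ids[i * config.n_plates // config.n_subjects]
        for i, s in enumerate(subjects)
    }
    load_order: dict[str, list[tuple[str, str]]] = {p: [] for p in plate_ids}
    for subj in subjects:
        for sid in sample_ids[subj]:
            load_order[plate_of_subject[subj]].append((sid, "biological"))
    for p in plate_ids:
        for k in range(config.nc_per_plate):
            load_order[p].append((f"NC{p[1:]}" + (f"_{k + 1}" if k else ""), "nc"))
        for k in range(config.pc_per_plate):
            load_order[p].append((f"PC{p[1:]}" + (f"_{k + 1}" if k else ""), "pc"))

    wells: dict[str, WellAddress] = {}
    capacity = n_rows * n_cols
    for p in plate_ids:
        n_used = len(load_order[p])
        if n_used > capacity:
            raise ValueError(
                f"plate {p}: {n_used} samples exceed capacity {capacity}"
            )
        if config.placement == "random":
            idxs = rng.choice(capacity, size=n_used, replace=False)
        else:
            idxs = np.arange(n_used)
        for (sid, _), idx in zip(load_order[p], idxs):
            wells[sid] = WellAddress(p, int(idx) % n_rows, int(idx) // n_rows)

    pool_of_plate = {
        p: f"pool{i // config.plates_per_pool + 1}" for i, p in enumerate(plate_ids)
    }

    samples: list[SampleMeta] = []
    endogenous: dict[str, list[tuple[str, int, float]]] = {}
    for p in plate_ids:
        for sid, kind in load_order[p]:
            w = wells[sid]
            if kind == "biological":
                subj = sid.rsplit("_", 1)[0]
                meta = SampleMeta(
                    sample_id=sid,
                    subject_id=subj,
                    family_id=family_of[subj],
                    sample_type=config.sample_type,
                    role="biological",
                    biomass=biomass[sid],
                    pool_id=pool_of_plate[p],
                    wells=(w,),
                )
                depth = config.depth_per_biomass * biomass[sid]
                endogenous[sid] = [
                    (gid, idx, depth)
                    for gid, idx in sorted(carriage[family_of[subj]].items())
                ]
            elif kind == "nc":
                meta = SampleMeta(
                    sample_id=sid,
                    role="negative_control",
                    sample_type="other",
                    biomass=config.nc_biomass,
                    pool_id=pool_of_plate[p],
                    wells=(w,),
                )
                endogenous[sid] = []
            else:
                meta = SampleMeta(
                    sample_id=sid,
                    role="positive_control",
                    sample_type="other",
                    biomass=config.pc_biomass,
                    pool_id=pool_of_plate[p],
                    wells=(w,),
                )
                endogenous[sid] = [(z, 0, config.zymo_depth) for z in zymo_gids]
            samples.append(meta)

    return StudyPlan(
        config=config,
        samples=samples,
        genomes=genomes,
        plates=plates,
        family_of=family_of,
        carriage=carriage,
        strain_counts=strain_counts,
        endogenous=endogenous,
        hospital_gids=hospital_gids,
        zymo_gids=zymo_gids,
    )


# ---------------------------------------------------------------------------
# genotypes


def genotype_strains(
    config: SimConfig,
    rng: np.random.Generator,
    strain_counts: dict[str, int],
) -> dict[tuple[str, int], np.ndarray]:
    """Haplotypes for every (genome, strain index) pair.

    Each species has a random reference sequence; each strain mutates the
    reference at ``Binomial(L, divergence / 2)`` private sites, so two
    strains of one species differ at an expected ``divergence`` fraction of
    positions.
    """
    L = config.genome_length
    haps: dict[tuple[str, int], np.ndarray] = {}
    for gid in sorted(strain_counts):
        ref = rng.integers(0, 4, size=L, dtype=np.int8)
        for idx in range(max(strain_counts[gid], 1)):
            hap = ref.copy()
            n_mut = rng.binomial(L, config.strain_divergence / 2)
            if n_mut:
                sites = rng.choice(L, size=n_mut, replace=False)
                hap[sites] = (hap[sites] + rng.integers(1, 4, size=n_mut)) % 4
            haps[(gid, idx)] = hap
    return haps


# ---------------------------------------------------------------------------
# events


def _apply_events(
    plan: StudyPlan, rng: np.random.Generator
) -> tuple[
    dict[str, list[tuple[str, int, float]]],
    list[GenomeRef],
    dict[tuple[str, int], np.ndarray],
    dict[int, tuple[str, ...]],
]:
    """Resolve planted events into per-sample mixture components.

    Returns (components, extra genomes, extra haplotypes, affected map).
    Transfer events copy the source's *endogenous* components only; chained
    contamination through multiple hops is not modelled.
    """
    config = plan.config
    by_id = {s.sample_id: s for s in plan.samples}
    comps = {sid: list(c) for sid, c in plan.endogenous.items()}
    extra_genomes: list[GenomeRef] = []
    extra_haps: dict[tuple[str, int], np.ndarray] = {}
    affected: dict[int, tuple[str, ...]] = {}

    bio_biomass = [
        s.biomass for s in plan.samples if s.role == "biological" and s.biomass
    ]
    harm = (
        len(bio_biomass) / sum(1.0 / b for b in bio_biomass) if bio_biomass else 1.0
    )

    for j, ev in enumerate(config.events):
        if ev.kind == "well_to_well":
            if ev.source not in comps or ev.target not in comps:
                raise ValueError(f"well_to_well event references unknown sample")
            comps[ev.target].extend(
                (gid, idx, ev.fraction * depth)
                for gid, idx, depth in plan.endogenous[ev.source]
            )
            affected[j] = (ev.target,)

        elif ev.kind == "external_reagent":
            gid = ev.genome_id or f"reagent{j + 1}"
            extra_genomes.append(GenomeRef(gid, config.genome_length, "reagent"))
            ref = rng.integers(0, 4, size=config.genome_length, dtype=np.int8)
            extra_haps[(gid, 0)] = ref
            hit: list[str] = []
            for s in plan.samples:
                b = s.biomass if s.biomass else harm
                p = min(1.0, ev.rate * harm / b) if b > 0 else 1.0
                if rng.random() < p:
                    comps[s.sample_id].append((gid, 0, ev.depth))
                    hit.append(s.sample_id)
            affected[j] = tuple(hit)

        elif ev.kind == "index_switch":
            pool = [s for s in plan.samples if s.pool_id == ev.pool_id]
            if not pool:
                raise ValueError(f"index_switch: empty pool {ev.pool_id!r}")
            # Donor: the pool's dominant library for one genome.  Detectable
            # leakage at per-read rates comes from the deepest library; the
            # contribution of ordinary-depth carriers is negligible and not
            # modelled.
            totals: dict[tuple[str, str], float] = {}
            for s in pool:
                subj = s.subject_id
                if subj is None or (ev.donor_subject and subj != ev.donor_subject):
                    continue
                for gid, _, depth in plan.endogenous[s.sample_id]:
                    if ev.genome_id and gid != ev.genome_id:
                        continue
                    totals[(gid, subj)] = totals.get((gid, subj), 0.0) + depth
            if not totals:
                raise ValueError("index_switch: no donor library in pool")
            gid, donor_subject = max(
                sorted(totals), key=lambda key: totals[key]
            )
            donors = [
                s.sample_id
                for s in pool
                if s.subject_id == donor_subject
                and any(g == gid for g, _, _ in plan.endogenous[s.sample_id])
            ]
            agg: dict[int, float] = {}
            for d in donors:
                for g, idx, depth in plan.endogenous[d]:
                    if g == gid:
                        agg[idx] = agg.get(idx, 0.0) + depth
            donor_family = by_id[donors[0]].family_id if donors else None
            hit = []
            for s in pool:
                # The donor family (twins share the donor's strains) cannot
                # receive an observable leak of its own strain.
                if s.subject_id == donor_subject or (
                    donor_family and s.family_id == donor_family
                ):
                    continue
                if rng.random() < ev.affected_fraction:
                    for idx, tot in sorted(agg.items()):
                        comps[s.sample_id].append((gid, idx, ev.rate * tot))
                    hit.append(s.sample_id)
            affected[j] = tuple(hit)

        elif ev.kind == "zymo_spill":
            src = plan.endogenous.get(ev.source)
            if src is None or ev.target not in comps:
                raise ValueError("zymo_spill event references unknown sample")
            comps[ev.target].extend(
                (gid, idx, ev.fraction * depth)
                for gid, idx, depth in src
                if gid in plan.zymo_gids
            )
            affected[j] = (ev.target,)

    return comps, extra_genomes, extra_haps, affected


# ---------------------------------------------------------------------------
# rendering


def render_profiles(
    samples: list[SampleMeta],
    genomes: list[GenomeRef],
    components: dict[str, list[tuple[str, int, float]]],
    haps: dict[tuple[str, int], np.ndarray],
    config: SimConfig,
    seed: int,
) -> dict[tuple[str, str], PositionProfile]:
    """Render allele-count profiles from per-sample strain mixtures.

    Per component, position depth is Poisson with the component's mean; a
    fraction ``seq_error`` of reads is scattered uniformly over the three
    other bases.  A sample with zero-depth components yields no profile
    (the zero-biomass / re-extraction degenerate case).
    """
    length = {g.genome_id: g.length for g in genomes}
    profiles: dict[tuple[str, str], PositionProfile] = {}
    for s in samples:
        comp = components.get(s.sample_id, [])
        if not comp:
            continue
        rng = _sample_rng(seed, s.sample_id)
        by_genome: dict[str, list[tuple[int, float]]] = {}
        for gid, idx, depth in comp:
            by_genome.setdefault(gid, []).append((idx, depth))
        for gid in sorted(by_genome):
            L = length[gid]
            counts = np.zeros((L, 4), dtype=np.int64)
            rows = np.arange(L)
            for idx, depth in by_genome[gid]:
                if depth <= 0:
                    continue
                hap = haps[(gid, idx)]
                d = rng.poisson(depth, L)
                e = rng.binomial(d, config.seq_error)
                counts[rows, hap] += d - e
                if e.any():
                    split = rng.multinomial(e, [1 / 3, 1 / 3, 1 / 3])
                    np.add.at(counts, (rows[:, None], _OTHERS[hap]), split)
            covered = counts.sum(axis=1) > 0
            if covered.any():
                profiles[(s.sample_id, gid)] = PositionProfile(
                    s.sample_id, gid, rows[covered], counts[covered]
                )
    return profiles


def simulate_study(config: SimConfig) -> tuple[StudyBundle, SimTruth]:
    """Generate a full study with planted-event truth labels."""
    plan = plan_study(config)
    geno_rng = _rng(config.seed, 1)
    haps = genotype_strains(config, geno_rng, plan.strain_counts)
    event_rng = _rng(config.seed, 2)
    comps, extra_genomes, extra_haps, affected = _apply_events(plan, event_rng)
    haps.update(extra_haps)
    genomes = plan.genomes + extra_genomes
    profiles = render_profiles(plan.samples, genomes, comps, haps, config, config.seed)
    bundle = StudyBundle(
        samples=plan.samples,
        genomes=genomes,
        profiles=profiles,
        plates=plan.plates,
    )

    strain_labels: dict[str, dict] = {}
    for g in plan.genomes:
        if g.genome_id in plan.zymo_gids:
            strain_labels[g.genome_id] = {"label": "zymo"}
        elif g.genome_id in plan.hospital_gids:
            carriers = sorted(
                f for f, c in plan.carriage.items() if g.genome_id in c
            )
            strain_labels[g.genome_id] = {"label": "hospital", "families": carriers}
        else:
            carriers = sorted(
                f for f, c in plan.carriage.items() if g.genome_id in c
            )
            strain_labels[g.genome_id] = {"label": "endogenous", "families": carriers}
    for g in extra_genomes:
        strain_labels[g.genome_id] = {"label": "reagent"}

    truth = SimTruth(
        events=config.events, affected=affected, strain_labels=strain_labels
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# null-plate generator (proximity-test calibration)


def simulate_null_plate(
    rng: np.random.Generator,
    n_samples: int = 40,
    n_sharing_pairs: int = 15,
    plate_dims: tuple[int, int] = (8, 12),
    plate_id: str = "P1",
) -> tuple[list[SampleMeta], list[SharingEdge]]:
    """A clean plate under the proximity-test null hypothesis.

    Samples are placed at random wells and sharing labels are assigned to a
    uniformly random subset of unrelated pairs, independent of geometry, so
    the proximity test's p-value should be uniform.  This isolates the
    test's calibration from the profile-rendering model.
    """
    n_rows, n_cols = plate_dims
    if n_samples > n_rows * n_cols:
        raise ValueError("more samples than wells")
    dims = PlateDims(
        tuple(chr(ord("A") + i) for i in range(n_rows)),
        tuple(str(i + 1) for i in range(n_cols)),
    )
    idxs = rng.choice(n_rows * n_cols, size=n_samples, replace=False)
    samples = [
        SampleMeta(
            sample_id=f"S{i + 1:03d}",
            subject_id=f"S{i + 1:03d}",
            family_id=f"F{i + 1:03d}",
            biomass=10.0,
            wells=(WellAddress(plate_id, int(k) % n_rows, int(k) // n_rows),),
        )
        for i, k in enumerate(idxs)
    ]
    pairs = list(itertools.combinations([s.sample_id for s in samples], 2))
    chosen = rng.choice(len(pairs), size=min(n_sharing_pairs, len(pairs)), replace=False)
    edges = [
        SharingEdge(pairs[k][0], pairs[k][1], frozenset({"g01"}))
        for k in sorted(chosen)
    ]
    return samples, edges


# ---------------------------------------------------------------------------
# scenario builders


def adjacent_unrelated_pairs(
    plan: StudyPlan,
    min_biomass: float = 8.0,
    plates: tuple[str, ...] | None = None,
    target_roles: tuple[str, ...] = ("biological",),
    radius: float = 1.0,
) -> list[tuple[str, str]]:
    """(source, target) candidates for well-to-well events.

    Sources are biological samples with depth comfortably above the joint
    5x comparison requirement (biomass >= ``min_biomass``); targets sit
    within ``radius`` grid units on the same plate and belong to a different
    family.
    """
    out: list[tuple[str, str]] = []
    placed = [s for s in plan.samples if s.placed]
    for src, tgt in itertools.permutations(placed, 2):
        if src.role != "biological" or tgt.role not in target_roles:
            continue
        if plates and src.wells[0].plate_id not in plates:
            continue
        if src.family_id and tgt.family_id and src.family_id == tgt.family_id:
            continue
        if src.biomass is None or src.biomass < min_biomass:
            continue
        if tgt.role == "biological" and (tgt.biomass is None or tgt.biomass < min_biomass):
            continue
        d = sample_pair_distance(src, tgt, src.wells[0].plate_id)
        if d is not None and 0 < d <= radius:
            out.append((src.sample_id, tgt.sample_id))
    return sorted(out)


def _pick_disjoint(
    cands: list[tuple[str, str]],
    n: int,
    rng: np.random.Generator,
    plan: StudyPlan | None = None,
) -> list[tuple[str, str]]:
    """Pick events with disjoint families so transfers are independent
    (no family acts as both a source and a recipient across events)."""
    fam = {}
    if plan is not None:
        fam = {
            s.sample_id: s.family_id or s.subject_id or s.sample_id
            for s in plan.samples
        }
    order = list(rng.permutation(len(cands)))
    chosen: list[tuple[str, str]] = []
    used: set[str] = set()
    for k in order:
        src, tgt = cands[k]
        keys = {fam.get(src, src), fam.get(tgt, tgt)}
        if keys & used:
            continue
        chosen.append((src, tgt))
        used |= keys
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} disjoint event pairs available")
    return chosen


def scenario_clean(seed: int, **overrides) -> SimConfig:
    """Default study with no planted events."""
    return SimConfig(seed=seed, **overrides)


def scenario_well_to_well(
    seed: int,
    n_events: int = 4,
    f_range: tuple[float, float] = (0.2, 0.4),
    target_roles: tuple[str, ...] = ("biological",),
    plates: tuple[str, ...] | None = None,
    **overrides,
) -> SimConfig:
    """Plant ``n_events`` adjacent-well transfer events with f in ``f_range``."""
    cfg = SimConfig(seed=seed, **overrides)
    plan = plan_study(cfg)
    rng = _rng(seed, 9001)
    cands = adjacent_unrelated_pairs(plan, plates=plates, target_roles=target_roles)
    events = tuple(
        ContaminationEvent.well_to_well(src, tgt, float(rng.uniform(*f_range)))
        for src, tgt in _pick_disjoint(cands, n_events, rng, plan)
    )
    return replace(cfg, events=events)


def scenario_external(
    seed: int, rate: float = 0.6, depth: float = 20.0, **overrides
) -> SimConfig:
    """One reagent contaminant across all plates, enriched at low biomass."""
    overrides.setdefault("n_plates", 3)
    overrides.setdefault("n_subjects", 24)
    cfg = SimConfig(seed=seed, **overrides)
    return replace(cfg, events=(ContaminationEvent.external_reagent(rate, depth),))


def scenario_index_switch(
    seed: int,
    rate: float = 0.005,
    affected_fraction: float = 0.1,
    donor_subject: str = "S01",
    donor_biomass: float = 320.0,
    **overrides,
) -> SimConfig:
    """Read leakage within one sequencing pool from a dominant library."""
    cfg = SimConfig(
        seed=seed,
        biomass_overrides={donor_subject: donor_biomass},
        **overrides,
    )
    return replace(
        cfg,
        events=(
            ContaminationEvent.index_switch(
                "pool1", rate, affected_fraction, donor_subject=donor_subject
            ),
        ),
    )


def scenario_mixed(seed: int, hospital_species: int = 0, **overrides) -> SimConfig:
    """One event of each mechanism: reagent, transfer, and pool leakage.

    Three plates; P1+P2 share a sequencing pool (leakage scope), the
    transfer event sits on P3.
    """
    overrides.setdefault("n_plates", 3)
    overrides.setdefault("n_subjects", 24)
    cfg = SimConfig(
        seed=seed,
        hospital_species=hospital_species,
        biomass_overrides={"S01": 320.0},
        **overrides,
    )
    plan = plan_study(cfg)
    rng = _rng(seed, 9002)
    cands = adjacent_unrelated_pairs(plan, plates=("P3",))
    (w2w_src, w2w_tgt), = _pick_disjoint(cands, 1, rng, plan)
    events = (
        ContaminationEvent.external_reagent(0.6, 20.0),
        ContaminationEvent.well_to_well(w2w_src, w2w_tgt, 0.3),
        ContaminationEvent.index_switch("pool1", 0.005, 0.1, donor_subject="S01"),
    )
    return replace(cfg, events=events)


def scenario_all_categories(seed: int, **overrides) -> SimConfig:
    """Mixed scenario plus an endogenous hospital strain (residual sharing)."""
    return scenario_mixed(seed, hospital_species=1, **overrides)
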