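"""Core study data model.

A *study* is a set of samples (biological samples plus extraction controls)
with plate/well addresses, a dereplicated reference genome set, and per
(sample, genome) allele-count profiles: for every covered genome position,
the number of reads supporting each of A, C, G and T.  Profiles stand in for
the read mappings a strain profiler would produce; everything downstream
(detection, popANI comparison, sharing networks, contamination calls)
operates on this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_TYPES = ("gut", "skin", "oral", "other")
ROLES = ("biological", "negative_control", "positive_control")

#: Default 96-well plate labelling: rows A-H, columns 1-12.
DEFAULT_ROW_LABELS: tuple[str, ...] = tuple("ABCDEFGH")
DEFAULT_COL_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 13))

BASES = "ACGT"


class StudyValidationError(ValueError):
    """Raised when study inputs violate a structural invariant."""


@dataclass(frozen=True)
class WellAddress:
    """A single well on an extraction plate (0-based row/column indices)."""

    plate_id: str
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise StudyValidationError(
                f"well ({self.plate_id}, {self.row}, {self.col}): negative index"
            )


@dataclass(frozen=True)
class PlateDims:
    """Row/column label declaration for one plate.

    The label order defines the integer index of each row/column; inputs may
    label rows and columns with letters or numbers in either orientation, so
    the mapping is explicit input rather than a guessed convention.
    """

    row_labels: tuple[str, ...] = DEFAULT_ROW_LABELS
    col_labels: tuple[str, ...] = DEFAULT_COL_LABELS

    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    @property
    def n_cols(self) -> int:
        return len(self.col_labels)


@dataclass(frozen=True)
class SampleMeta:
    """Identity and provenance of one sample.

    ``wells`` may hold zero addresses (single-tube extraction; excluded from
    all plate-geometry analyses), one address (the common case), or several
    (duplicate extractions merged into one library; plate analyses use every
    contributing well).  ``biomass`` is the DNA yield in ng/uL used as a
    biomass proxy; ``None`` means unknown, never zero.  Samples sharing
    ``pool_id`` were pooled for sequencing and can exchange reads through
    index switching or sample bleeding.
    """

    sample_id: str
    subject_id: str | None = None
    family_id: str | None = None
    sample_type: str = "gut"
    role: str = "biological"
    biomass: float | None = None
    pool_id: str = ""
    wells: tuple[WellAddress, ...] = ()

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise StudyValidationError(
                f"sample {self.sample_id}: unknown sample_type {self.sample_type!r}"
            )
        if self.role not in ROLES:
            raise StudyValidationError(
                f"sample {self.sample_id}: unknown role {self.role!r}"
            )
        if self.biomass is not None and self.biomass < 0:
            raise StudyValidationError(
                f"sample {self.sample_id}: negative biomass {self.biomass}"
            )
        if self.role == "biological" and not self.subject_id:
            raise StudyValidationError(
                f"sample {self.sample_id}: biological sample without subject_id"
            )

    @property
    def placed(self) -> bool:
        return len(self.wells) > 0

    @property
    def plate_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(w.plate_id for w in self.wells))


@dataclass(frozen=True)
class GenomeRef:
    """One representative genome of the dereplicated reference set."""

    genome_id: str
    length: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise StudyValidationError(
                f"genome {self.genome_id}: non-positive length {self.length}"
            )


class PositionProfile:
    """Sparse allele counts for one (sample, genome) pair.

    ``positions`` is a sorted 1-D int array of 0-based genome positions and
    ``counts`` the matching (n, 4) array of A/C/G/T read counts.  Only
    positions with at least one read are stored.
    """

    __slots__ = ("sample_id", "genome_id", "positions", "counts")

    def __init__(
        self,
        sample_id: str,
        genome_id: str,
        positions: np.ndarray,
        counts: np.ndarray,
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape != (positions.size, 4):
            raise StudyValidationError(
                f"profile ({sample_id}, {genome_id}): counts shape "
                f"{counts.shape} does not match {positions.size} positions x 4"
            )
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        counts = counts[order]
        if positions.size and np.any(np.diff(positions) == 0):
            raise StudyValidationError(
                f"profile ({sample_id}, {genome_id}): duplicate positions"
            )
        if np.any(counts < 0):
            raise StudyValidationError(
                f"profile ({sample_id}, {genome_id}): negative counts"
            )
        if positions.size and np.any(counts.sum(axis=1) < 1):
            raise StudyValidationError(
                f"profile ({sample_id}, {genome_id}): stored position with zero total count"
            )
        self.sample_id = sample_id
        self.genome_id = genome_id
        self.positions = positions
        self.counts = counts

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_covered(self) -> int:
        return int(self.positions.size)

    def mean_depth(self, genome_length: int) -> float:
        if genome_length <= 0:
            raise StudyValidationError("genome length must be positive")
        return float(self.counts.sum()) / genome_length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.genome_id == other.genome_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PositionProfile({self.sample_id!r}, {self.genome_id!r}, "
            f"n_covered={self.n_covered})"
        )


@dataclass
class StudyBundle:
    """A validated study: samples, genomes, profiles, plate geometry."""

    samples: list[SampleMeta]
    genomes: list[GenomeRef]
    profiles: dict[tuple[str, str], PositionProfile]
    plates: dict[str, PlateDims] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    @property
    def samples_by_id(self) -> dict[str, SampleMeta]:
        return {s.sample_id: s for s in self.samples}

    @property
    def genomes_by_id(self) -> dict[str, GenomeRef]:
        return {g.genome_id: g for g in self.genomes}

    def profiles_for_sample(self, sample_id: str) -> list[PositionProfile]:
        return [p for (sid, _), p in self.profiles.items() if sid == sample_id]

    def subjects(self) -> list[str]:
        """Distinct subject ids among biological samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.role == "biological" and s.subject_id:
                seen.setdefault(s.subject_id, None)
        return list(seen)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise StudyValidationError(
                f"duplicate sample_id: {', '.join(sorted(dupes))}"
            )
        gids = [g.genome_id for g in self.genomes]
        gdupes = {i for i in gids if gids.count(i) > 1}
        if gdupes:
            raise StudyValidationError(
                f"duplicate genome_id: {', '.join(sorted(gdupes))}"
            )

        occupied: dict[tuple[str, int, int], str] = {}
        for s in self.samples:
            for w in s.wells:
                dims = self.plates.get(w.plate_id)
                if dims is None:
                    raise StudyValidationError(
                        f"sample {s.sample_id}: well on undeclared plate {w.plate_id!r}"
                    )
                if w.row >= dims.n_rows or w.col >= dims.n_cols:
                    raise StudyValidationError(
                        f"sample {s.sample_id}: well ({w.plate_id}, {w.row}, {w.col}) "
                        f"outside {dims.n_rows}x{dims.n_cols} plate"
                    )
                key = (w.plate_id, w.row, w.col)
                if key in occupied and occupied[key] != s.sample_id:
                    raise StudyValidationError(
                        f"well collision on {w.plate_id} (row {w.row}, col {w.col}): "
                        f"{occupied[key]} and {s.sample_id}"
                    )
                occupied[key] = s.sample_id

        sample_ids = set(ids)
        genome_len = {g.genome_id: g.length for g in self.genomes}
        for (sid, gid), prof in self.profiles.items():
            if prof.sample_id != sid or prof.genome_id != gid:
                raise StudyValidationError(
                    f"profile keyed ({sid}, {gid}) carries ids "
                    f"({prof.sample_id}, {prof.genome_id})"
                )
            if sid not in sample_ids:
                raise StudyValidationError(f"profile references unknown sample {sid!r}")
            if gid not in genome_len:
                raise StudyValidationError(f"profile references unknown genome {gid!r}")
            if prof.positions.size and int(prof.positions[-1]) >= genome_len[gid]:
                raise StudyValidationError(
                    f"profile ({sid}, {gid}): position {int(prof.positions[-1])} "
                    f">= genome length {genome_len[gid]}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyBundle):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.genomes == other.genomes
            and self.plates == other.plates
            and self.profiles == other.profiles
        )
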