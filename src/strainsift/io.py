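"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8 TSV with a header row; missing values are written as the
empty string and '.' is also accepted on input.  The study input set is

* ``metadata.tsv``   sample_id, subject_id, family_id, sample_type, role,
  biomass, pool_id
* ``platemap.tsv``   sample_id, plate_id, row_label, col_label (one row per
  contributing well; merged duplicate extractions list several wells)
* ``plate_dims.tsv`` plate_id, row_labels, col_labels (comma-separated label
  declarations; optional, defaults to rows A-H x columns 1-12)
* ``profiles.tsv``   sample_id, genome_id, position, count_A..count_T
* ``genomes.tsv``    genome_id, length, label

``write_study`` followed by ``read_study`` is the identity on valid bundles.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_COL_LABELS,
    DEFAULT_ROW_LABELS,
    GenomeRef,
    PlateDims,
    PositionProfile,
    SampleMeta,
    StudyBundle,
    StudyValidationError,
    WellAddress,
)

_MISSING = ("", ".")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "family_id",
    "sample_type",
    "role",
    "biomass",
    "pool_id",
)
PLATEMAP_COLUMNS = ("sample_id", "plate_id", "row_label", "col_label")
PROFILE_COLUMNS = (
    "sample_id",
    "genome_id",
    "position",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
)
GENOME_COLUMNS = ("genome_id", "length", "label")


def _read_tsv(path: str | os.PathLike, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StudyValidationError(
            f"{path.name}: missing columns {', '.join(missing)}"
        )
    return df


def _opt_str(value: str) -> str | None:
    return None if value in _MISSING else value


def _opt_float(value: str, where: str) -> float | None:
    if value in _MISSING:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise StudyValidationError(f"{where}: bad float {value!r}") from exc


def read_plate_dims(path: str | os.PathLike | None) -> dict[str, PlateDims]:
    """Read the optional per-plate label declaration."""
    if path is None or not Path(path).exists():
        return {}
    df = _read_tsv(path, ("plate_id", "row_labels", "col_labels"))
    dims: dict[str, PlateDims] = {}
    for _, row in df.iterrows():
        dims[row["plate_id"]] = PlateDims(
            row_labels=tuple(row["row_labels"].split(",")),
            col_labels=tuple(row["col_labels"].split(",")),
        )
    return dims


def read_study(
    metadata_path: str | os.PathLike,
    platemap_path: str | os.PathLike,
    profiles_path: str | os.PathLike,
    genomes_path: str | os.PathLike,
    plate_dims_path: str | os.PathLike | None = None,
) -> StudyBundle:
    """Read and validate a study from its TSV file set."""
    meta = _read_tsv(metadata_path, METADATA_COLUMNS)
    platemap = _read_tsv(platemap_path, PLATEMAP_COLUMNS)
    genome_df = _read_tsv(genomes_path, GENOME_COLUMNS)
    dims = read_plate_dims(plate_dims_path)

    seen: set[str] = set()
    for sid in meta["sample_id"]:
        if sid in seen:
            raise StudyValidationError(f"metadata.tsv: duplicate sample_id {sid!r}")
        seen.add(sid)

    # Wells, with plate labels normalized to 0-based integer indices.
    wells: dict[str, list[WellAddress]] = {}
    for i, row in platemap.iterrows():
        sid = row["sample_id"]
        if sid not in seen:
            raise StudyValidationError(
                f"platemap.tsv row {i + 2}: unknown sample {sid!r}"
            )
        plate = row["plate_id"]
        d = dims.setdefault(plate, PlateDims(DEFAULT_ROW_LABELS, DEFAULT_COL_LABELS))
        try:
            r = d.row_labels.index(row["row_label"])
            c = d.col_labels.index(row["col_label"])
        except ValueError as exc:
            raise StudyValidationError(
                f"platemap.tsv row {i + 2}: label "
                f"({row['row_label']!r}, {row['col_label']!r}) not declared for {plate}"
            ) from exc
        wells.setdefault(sid, []).append(WellAddress(plate, r, c))

    samples = [
        SampleMeta(
            sample_id=row["sample_id"],
            subject_id=_opt_str(row["subject_id"]),
            family_id=_opt_str(row["family_id"]),
            sample_type=row["sample_type"],
            role=row["role"],
            biomass=_opt_float(row["biomass"], f"metadata.tsv row {i + 2}"),
            pool_id=row["pool_id"],
            wells=tuple(wells.get(row["sample_id"], ())),
        )
        for i, row in meta.iterrows()
    ]

    genomes = [
        GenomeRef(row["genome_id"], int(row["length"]), row["label"])
        for _, row in genome_df.iterrows()
    ]
    genome_len = {g.genome_id: g.length for g in genomes}

    prof_df = pd.read_csv(
        profiles_path,
        sep="\t",
        dtype={
            "sample_id": str,
            "genome_id": str,
            "position": np.int64,
            "count_A": np.int64,
            "count_C": np.int64,
            "count_G": np.int64,
            "count_T": np.int64,
        },
    )
    missing_cols = [c for c in PROFILE_COLUMNS if c not in prof_df.columns]
    if missing_cols:
        raise StudyValidationError(
            f"profiles.tsv: missing columns {', '.join(missing_cols)}"
        )
    for i, row in enumerate(prof_df.itertuples(index=False)):
        if row.sample_id not in seen:
            raise StudyValidationError(
                f"profiles.tsv row {i + 2}: unknown sample {row.sample_id!r}"
            )
        if row.genome_id not in genome_len:
            raise StudyValidationError(
                f"profiles.tsv row {i + 2}: unknown genome {row.genome_id!r}"
            )
        if not 0 <= row.position < genome_len[row.genome_id]:
            raise StudyValidationError(
                f"profiles.tsv row {i + 2}: position {row.position} outside "
                f"[0, {genome_len[row.genome_id]}) for genome {row.genome_id}"
            )

    profiles: dict[tuple[str, str], PositionProfile] = {}
    if len(prof_df):
        for (sid, gid), grp in prof_df.groupby(["sample_id", "genome_id"], sort=False):
            profiles[(sid, gid)] = PositionProfile(
                sid,
                gid,
                grp["position"].to_numpy(),
                grp[["count_A", "count_C", "count_G", "count_T"]].to_numpy(),
            )

    # Restrict plate registry to declared/used plates so round-trips are exact.
    used_plates = {w.plate_id for s in samples for w in s.wells}
    dims = {p: d for p, d in dims.items() if p in used_plates or plate_dims_path}
    return StudyBundle(samples=samples, genomes=genomes, profiles=profiles, plates=dims)


def _fmt_opt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_study(bundle: StudyBundle, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write a study to ``out_dir``; returns the paths written.

    The output is lossless: ``read_study`` on the written files reproduces the
    bundle exactly (floats are serialized with ``repr``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "platemap": out / "platemap.tsv",
        "plate_dims": out / "plate_dims.tsv",
        "profiles": out / "profiles.tsv",
        "genomes": out / "genomes.tsv",
    }

    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for s in bundle.samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        _fmt_opt(s.subject_id),
                        _fmt_opt(s.family_id),
                        s.sample_type,
                        s.role,
                        _fmt_opt(s.biomass),
                        s.pool_id,
                    ]
                )
                + "\n"
            )

    with open(paths["platemap"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(PLATEMAP_COLUMNS) + "\n")
        for s in bundle.samples:
            for w in s.wells:
                d = bundle.plates[w.plate_id]
                fh.write(
                    f"{s.sample_id}\t{w.plate_id}\t{d.row_labels[w.row]}\t"
                    f"{d.col_labels[w.col]}\n"
                )

    with open(paths["plate_dims"], "w", encoding="utf-8") as fh:
        fh.write("plate_id\trow_labels\tcol_labels\n")
        for plate_id, d in bundle.plates.items():
            fh.write(
                f"{plate_id}\t{','.join(d.row_labels)}\t{','.join(d.col_labels)}\n"
            )

    with open(paths["genomes"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(GENOME_COLUMNS) + "\n")
        for g in bundle.genomes:
            fh.write(f"{g.genome_id}\t{g.length}\t{g.label}\n")

    with open(paths["profiles"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for (sid, gid) in sorted(bundle.profiles):
            prof = bundle.profiles[(sid, gid)]
            for pos, row in zip(prof.positions, prof.counts):
                fh.write(
                    f"{sid}\t{gid}\t{pos}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\n"
                )

    return paths


def read_study_dir(study_dir: str | os.PathLike) -> StudyBundle:
    """Read a study from a directory written by :func:`write_study`."""
    d = Path(study_dir)
    plate_dims = d / "plate_dims.tsv"
    return read_study(
        d / "metadata.tsv",
        d / "platemap.tsv",
        d / "profiles.tsv",
        d / "genomes.tsv",
        plate_dims if plate_dims.exists() else None,
    )
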