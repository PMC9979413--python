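"""Study model validation and lossless TSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strainsift as ss
from strainsift import (
    GenomeRef,
    PlateDims,
    PositionProfile,
    SampleMeta,
    StudyBundle,
    StudyValidationError,
    WellAddress,
)
from strainsift.io import read_study_dir, write_study


def _bundle(samples=None, genomes=None, profiles=None, plates=None):
    return StudyBundle(
        samples if samples is not None else [],
        genomes if genomes is not None else [],
        profiles if profiles is not None else {},
        plates if plates is not None else {"P1": PlateDims()},
    )


class TestValidation:
    def test_duplicate_sample_id_rejected(self):
        s = SampleMeta("A", "S1", "F1")
        with pytest.raises(StudyValidationError, match="duplicate sample_id: A"):
            _bundle(samples=[s, s])

    def test_negative_biomass_rejected(self):
        with pytest.raises(StudyValidationError, match="negative biomass"):
            SampleMeta("A", "S1", "F1", biomass=-1.0)

    def test_biological_sample_requires_subject(self):
        with pytest.raises(StudyValidationError, match="without subject_id"):
            SampleMeta("A", None, None, role="biological")

    def test_negative_control_needs_no_subject(self):
        nc = SampleMeta("NC1", role="negative_control")
        assert nc.subject_id is None

    def test_well_collision_rejected(self):
        w = (WellAddress("P1", 0, 0),)
        a = SampleMeta("A", "S1", "F1", wells=w)
        b = SampleMeta("B", "S2", "F2", wells=w)
        with pytest.raises(StudyValidationError, match="well collision"):
            _bundle(samples=[a, b])

    def test_well_outside_plate_rejected(self):
        s = SampleMeta("A", "S1", "F1", wells=(WellAddress("P1", 9, 0),))
        with pytest.raises(StudyValidationError, match="outside"):
            _bundle(samples=[s])

    def test_profile_position_beyond_genome_rejected(self):
        s = SampleMeta("A", "S1", "F1")
        g = GenomeRef("g01", 5)
        prof = PositionProfile("A", "g01", np.array([7]), np.array([[3, 0, 0, 0]]))
        with pytest.raises(StudyValidationError, match="genome length"):
            _bundle(samples=[s], genomes=[g], profiles={("A", "g01"): prof})

    def test_profile_unknown_sample_rejected(self):
        g = GenomeRef("g01", 5)
        prof = PositionProfile("X", "g01", np.array([0]), np.array([[3, 0, 0, 0]]))
        with pytest.raises(StudyValidationError, match="unknown sample"):
            _bundle(genomes=[g], profiles={("X", "g01"): prof})

    def test_zero_total_position_rejected(self):
        with pytest.raises(StudyValidationError, match="zero total"):
            PositionProfile("A", "g01", np.array([0]), np.array([[0, 0, 0, 0]]))

    def test_zero_length_genome_rejected(self):
        with pytest.raises(StudyValidationError, match="non-positive length"):
            GenomeRef("g01", 0)


def _random_bundle(seed: int) -> StudyBundle:
    rng = np.random.default_rng(seed)
    plates = {"P1": PlateDims(), "Px": PlateDims(("r1", "r2"), ("c1", "c2", "c3"))}
    genomes = [GenomeRef(f"g{k}", int(rng.integers(5, 40)), f"sp {k}") for k in range(3)]
    samples = []
    wells_used = set()
    for i in range(int(rng.integers(2, 8))):
        wells = []
        if rng.random() < 0.8:  # some samples stay unplaced (single-tube)
            for _ in range(1 + (rng.random() < 0.2)):  # occasional merged wells
                plate = rng.choice(list(plates))
                dims = plates[plate]
                r = int(rng.integers(dims.n_rows))
                c = int(rng.integers(dims.n_cols))
                if (plate, r, c) not in wells_used:
                    wells_used.add((plate, r, c))
                    wells.append(WellAddress(plate, r, c))
        role = ["biological", "negative_control", "positive_control"][
            int(rng.integers(3)) if i else 0
        ]
        samples.append(
            SampleMeta(
                sample_id=f"smp{i}",
                subject_id=f"S{i}" if role == "biological" else None,
                family_id=f"F{i // 2}" if role == "biological" else None,
                sample_type=str(rng.choice(["gut", "skin", "oral", "other"])),
                role=role,
                biomass=None if rng.random() < 0.3 else float(rng.lognormal(2, 1)),
                pool_id=f"pool{int(rng.integers(2))}",
                wells=tuple(wells),
            )
        )
    profiles = {}
    for s in samples:
        for g in genomes:
            if rng.random() < 0.5:
                n = int(rng.integers(1, g.length))
                pos = rng.choice(g.length, size=n, replace=False)
                counts = rng.integers(0, 20, size=(n, 4))
                counts[counts.sum(axis=1) == 0, 0] = 1
                profiles[(s.sample_id, g.genome_id)] = PositionProfile(
                    s.sample_id, g.genome_id, pos, counts
                )
    return StudyBundle(samples, genomes, profiles, plates)


class TestRoundTrip:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_write_read_identity(self, tmp_path_factory, seed):
        bundle = _random_bundle(seed)
        out = tmp_path_factory.mktemp("rt")
        write_study(bundle, out)
        assert read_study_dir(out) == bundle

    def test_missing_biomass_round_trips_as_unknown(self, tmp_path):
        bundle = _bundle(
            samples=[SampleMeta("A", "S1", "F1", biomass=None)],
        )
        write_study(bundle, tmp_path)
        back = read_study_dir(tmp_path)
        assert back.samples[0].biomass is None

    def test_empty_profiles_round_trip(self, tmp_path):
        bundle = _bundle(samples=[SampleMeta("A", "S1", "F1")])
        write_study(bundle, tmp_path)
        assert read_study_dir(tmp_path).profiles == {}

    def test_two_sample_study_reads_back(self, two_sample_study, tmp_path):
        write_study(two_sample_study, tmp_path)
        back = read_study_dir(tmp_path)
        assert len(back.samples) == 2
        assert back == two_sample_study


class TestReaderErrors:
    def test_duplicate_metadata_sample_id(self, two_sample_study, tmp_path):
        paths = write_study(two_sample_study, tmp_path)
        text = paths["metadata"].read_text()
        last = text.strip().splitlines()[-1]
        paths["metadata"].write_text(text + last + "\n")
        with pytest.raises(StudyValidationError, match="duplicate sample_id 'B1'"):
            read_study_dir(tmp_path)

    def test_profile_row_beyond_genome_cites_row(self, two_sample_study, tmp_path):
        paths = write_study(two_sample_study, tmp_path)
        with open(paths["profiles"], "a") as fh:
            fh.write("A1\tg01\t99\t5\t0\t0\t0\n")
        with pytest.raises(StudyValidationError, match=r"row 12.*position 99"):
            read_study_dir(tmp_path)

    def test_unknown_plate_label_rejected(self, two_sample_study, tmp_path):
        paths = write_study(two_sample_study, tmp_path)
        text = paths["platemap"].read_text().replace("A\t1", "Z\t1")
        paths["platemap"].write_text(text)
        with pytest.raises(StudyValidationError, match="not declared"):
            read_study_dir(tmp_path)

    def test_custom_label_declaration_maps_to_indices(self, tmp_path):
        (tmp_path / "metadata.tsv").write_text(
            "sample_id\tsubject_id\tfamily_id\tsample_type\trole\tbiomass\tpool_id\n"
            "A\tS1\tF1\tgut\tbiological\t1.0\tp1\n"
        )
        (tmp_path / "platemap.tsv").write_text(
            "sample_id\tplate_id\trow_label\tcol_label\nA\tP9\tx\tL\n"
        )
        (tmp_path / "plate_dims.tsv").write_text(
            "plate_id\trow_labels\tcol_labels\nP9\tw,x\tJ,K,L\n"
        )
        (tmp_path / "genomes.tsv").write_text("genome_id\tlength\tlabel\n")
        (tmp_path / "profiles.tsv").write_text(
            "sample_id\tgenome_id\tposition\tcount_A\tcount_C\tcount_G\tcount_T\n"
        )
        bundle = read_study_dir(tmp_path)
        (well,) = bundle.samples[0].wells
        assert (well.row, well.col) == (1, 2)
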