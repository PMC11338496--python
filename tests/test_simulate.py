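import numpy as np
import pysam
import pytest

from prescall.alignment import MateGroup, collect_genome_placements, stream_placements
from prescall.evenness import depth_profile
from prescall.simulate import (
    Bimodal,
    GenomeSpec,
    RegionRestricted,
    SimulationSpec,
    Uniform,
    make_genomes,
    sample_placements,
    simulate_scenario,
    subsample_placements,
    write_alignment,
)


def single_genome_spec(pattern, gl=100_000, paired=False, seed=0, rl=150):
    return SimulationSpec(
        genomes=(GenomeSpec("g", (gl,), pattern),),
        read_length=rl,
        paired=paired,
        seed=seed,
    )


class TestMakeGenomes:
    def test_lengths_and_record_order(self, tmp_path):
        spec = SimulationSpec(
            genomes=(GenomeSpec("g", (300, 700), Uniform(0.0)),), seed=1
        )
        (path,) = make_genomes(spec, tmp_path)
        with pysam.FastxFile(str(path)) as fx:
            recs = [(r.name, len(r.sequence)) for r in fx]
        assert recs == [("g_c0", 300), ("g_c1", 700)]

    def test_seed_determinism(self, tmp_path):
        spec = SimulationSpec(
            genomes=(GenomeSpec("g", (5000,), Uniform(0.0)),), seed=3
        )
        (a,) = make_genomes(spec, tmp_path / "a")
        (b,) = make_genomes(spec, tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()

    def test_seed_changes_sequence_not_length(self, tmp_path):
        s1 = SimulationSpec(genomes=(GenomeSpec("g", (5000,), Uniform(0.0)),), seed=3)
        s2 = SimulationSpec(genomes=(GenomeSpec("g", (5000,), Uniform(0.0)),), seed=4)
        (a,) = make_genomes(s1, tmp_path / "a")
        (b,) = make_genomes(s2, tmp_path / "b")
        assert a.read_bytes() != b.read_bytes()
        with pysam.FastxFile(str(b)) as fx:
            assert [len(r.sequence) for r in fx] == [5000]

    def test_nonpositive_length_fatal(self):
        with pytest.raises(ValueError):
            GenomeSpec("g", (0,), Uniform(1.0))


class TestSamplePlacements:
    def test_uniform_read_count_formula(self):
        spec = single_genome_spec(Uniform(1.0), gl=1500, rl=150)
        assert len(sample_placements(spec, spec.genomes[0])) == 10

    def test_paired_equal_group_sizes(self):
        spec = single_genome_spec(Uniform(2.0), paired=True)
        placements = sample_placements(spec, spec.genomes[0])
        groups = [p.mate_group for p in placements]
        assert groups.count(MateGroup.FIRST) == groups.count(MateGroup.SECOND)
        assert MateGroup.UNPAIRED not in groups

    def test_region_restriction_is_respected(self):
        spec = single_genome_spec(
            RegionRestricted(0.5, covered_fraction=0.1, n_regions=2), gl=200_000
        )
        placements = sample_placements(spec, spec.genomes[0])
        starts = np.sort([p.start for p in placements])
        # all starts inside at most 2 intervals of total span <= 0.1 * Gl + slack
        span = 0
        gap_threshold = 5000
        block_start = starts[0]
        prev = starts[0]
        for s in starts[1:]:
            if s - prev > gap_threshold:
                span += prev - block_start
                block_start = s
            prev = s
        span += prev - block_start
        assert span <= 0.11 * 200_000

    def test_empirical_coverage_matches_request(self):
        """Mean depth of a uniform fixture is within 5% of the requested
        coverage once the read count is large."""
        gl, rl, c = 300_000, 150, 1.0  # 2000 reads
        spec = single_genome_spec(Uniform(c), gl=gl, rl=rl, seed=5)
        placements = sample_placements(spec, spec.genomes[0])
        depth = depth_profile([(p.start, p.read_length) for p in placements], gl)
        assert depth.mean() == pytest.approx(c, rel=0.05)

    def test_bimodal_two_depth_modes_and_depressed_metrics(self):
        """The mismapping emulation piles a spike on top of a uniform
        background: the depth histogram shows mass far above the base
        mode, and BER drops relative to a uniform fixture with the same
        number of reads."""
        from prescall.evenness import genome_evenness

        gl = 200_000
        bim = single_genome_spec(
            Bimodal(base_coverage=1.0, spike_coverage=4.0, spike_fraction=0.05),
            gl=gl, seed=6,
        )
        placements = sample_placements(bim, bim.genomes[0])
        depth = depth_profile([(p.start, p.read_length) for p in placements], gl)
        base_mode = np.bincount(depth[depth < 10]).argmax()
        assert (depth > base_mode + 10).sum() > 0.02 * gl  # a real second mode
        uni = single_genome_spec(Uniform(5.0), gl=gl, seed=6)
        uni_placements = sample_placements(uni, uni.genomes[0])
        assert abs(len(uni_placements) - len(placements)) < 0.02 * len(placements)
        cat_b, cat_u = bim.catalog(), uni.catalog()
        ber_b = genome_evenness(
            collect_genome_placements(placements, cat_b)["g"], cat_b
        ).ber
        ber_u = genome_evenness(
            collect_genome_placements(uni_placements, cat_u)["g"], cat_u
        ).ber
        assert ber_b < ber_u

    def test_zero_coverage_warns_when_rounds_to_nothing(self):
        spec = single_genome_spec(Uniform(0.0001), gl=1000, rl=150)
        with pytest.warns(UserWarning):
            assert sample_placements(spec, spec.genomes[0]) == []

    def test_pattern_validation(self):
        with pytest.raises(ValueError):
            RegionRestricted(1.0, covered_fraction=0.0)
        with pytest.raises(ValueError):
            Bimodal(1.0, 2.0, spike_fraction=1.0)
        with pytest.raises(ValueError):
            Uniform(-1.0)


class TestSubsample:
    def test_identity_and_empty(self):
        spec = single_genome_spec(Uniform(0.5))
        placements = sample_placements(spec, spec.genomes[0])
        assert subsample_placements(placements, 1.0, 0) == placements
        assert subsample_placements(placements, 0.0, 0) == []

    def test_kept_count_binomial(self):
        """Pair-level keep decisions: kept pair count stays within 3
        binomial SDs of n*f across seeds."""
        spec = single_genome_spec(Uniform(6.0), gl=500_000, paired=True, seed=9)
        placements = sample_placements(spec, spec.genomes[0])
        n_pairs = len(placements) // 2
        assert n_pairs >= 5000
        sd = np.sqrt(n_pairs * 0.25)
        for seed in range(5):
            kept = subsample_placements(placements, 0.5, seed)
            assert len(kept) % 2 == 0
            assert abs(len(kept) // 2 - n_pairs * 0.5) <= 3 * sd
            # mates travel together
            names = [p.name for p in kept]
            assert all(names.count(n) == 2 for n in set(names))

    def test_bad_fraction_fatal(self):
        with pytest.raises(ValueError):
            subsample_placements([], 1.5, 0)


class TestWriteAlignment:
    def test_sam_is_valid_sorted_and_one_based(self, small_scenario):
        spec, paths = small_scenario
        with pysam.AlignmentFile(str(paths["alignment"]), "r") as af:
            assert af.header["HD"]["SO"] == "coordinate"
            last = (-1, -1)
            n = 0
            for rec in af:
                key = (rec.reference_id, rec.reference_start)
                assert key >= last
                last = key
                n += 1
            assert n > 0

    def test_pos_conversion_and_flags(self, tmp_path, two_contig_catalog):
        from prescall.alignment import ReadPlacement

        placements = [
            ReadPlacement("cA1", 4, 10, MateGroup.FIRST, "p"),
            ReadPlacement("cA2", 4, 10, MateGroup.SECOND, "p"),
        ]
        sam = write_alignment(placements, two_contig_catalog, tmp_path / "x.sam")
        lines = [l for l in sam.read_text().splitlines() if not l.startswith("@")]
        fields = [l.split("\t") for l in lines]
        assert [f[3] for f in fields] == ["5", "5"]  # 1-based POS
        assert int(fields[0][1]) & 0x40
        assert int(fields[1][1]) & 0x80

    def test_off_contig_placement_fatal(self, tmp_path, two_contig_catalog):
        from prescall.alignment import ReadPlacement

        with pytest.raises(ValueError):
            write_alignment(
                [ReadPlacement("cB1", 100, 10)], two_contig_catalog, tmp_path / "x.sam"
            )

    def test_scenario_determinism(self, tmp_path):
        spec = SimulationSpec(
            genomes=(
                GenomeSpec("a", (20_000,), Uniform(1.0)),
                GenomeSpec("b", (20_000,), RegionRestricted(1.0, 0.1)),
            ),
            seed=21,
        )
        p1 = simulate_scenario(spec, tmp_path / "r1")
        p2 = simulate_scenario(spec, tmp_path / "r2")
        assert p1["alignment"].read_bytes() == p2["alignment"].read_bytes()
        assert p1["truth"].read_text() == p2["truth"].read_text()

    def test_truth_labels_follow_patterns(self, small_scenario):
        spec, paths = small_scenario
        text = dict(
            line.split("\t") for line in paths["truth"].read_text().splitlines()
        )
        assert text == {"present_uniform": "1", "absent_region": "0", "no_reads": "1"}
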