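"""Unit and property tests for the synthetic genome / read / histogram generator."""

import numpy as np
import pytest

from repeatscreen.kmers import consensus_read_fraction, count_kmers
from repeatscreen.simulate import (
    GroundTruth,
    InfeasibleSpecError,
    RepeatFamily,
    SimSpec,
    build_genomes,
    simulate_histogram,
    simulate_reads,
)

from conftest import random_dna, revcomp_py


def small_spec(seed, families=(), accessions=(("A1", ("R",)),), length=100_000, **kw):
    return SimSpec(
        subgenomes=(("R", length), ("D", length)),
        accessions=accessions,
        families=tuple(families),
        seed=seed,
        **kw,
    )


def family(rng, name="fam", n=100, copies=20, **kw):
    defaults = dict(
        divergence=0.0, layout="dispersed", subgenome_scope=("R",), family_class="shared"
    )
    defaults.update(kw)
    return RepeatFamily(name, random_dna(rng, n), copies, **defaults)


class TestRepeatFamily:
    def test_rejects_bad_consensus(self):
        with pytest.raises(ValueError):
            RepeatFamily("f", "ACGTN" * 20, 1)
        with pytest.raises(ValueError):
            RepeatFamily("f", "ACGT" * 5, 1)  # below minimum unit length

    def test_telomeric_consensus_must_be_unit_concatenation(self, rng):
        RepeatFamily("t", "TTTAGGG" * 8, 5, family_class="telomeric")
        with pytest.raises(ValueError):
            RepeatFamily("t", random_dna(rng, 56), 5, family_class="telomeric")


class TestBuildGenomes:
    def test_no_families_gives_random_sequences_and_empty_truth(self):
        spec = small_spec(7)
        genomes, truth = build_genomes(spec)
        assert len(genomes["R"]) == 100_000
        assert len(genomes["D"]) == 100_000
        assert truth.realized_copies == {}
        assert truth.per_accession["A1"] == {}

    def test_copy_number_and_base_fraction_arithmetic(self, rng):
        # 200 copies x 100 bases in a 2 Mb subgenome -> base fraction 0.01
        fam = family(rng, copies=200, n=100)
        spec = SimSpec(
            subgenomes=(("R", 2_000_000),),
            accessions=(("A1", ("R",)),),
            families=(fam,),
            seed=3,
            paired=False,
        )
        genomes, truth = build_genomes(spec)
        assert truth.realized_copies["fam"]["R"] == 200
        t = truth.per_accession["A1"]["fam"]
        assert t.copies == 200
        assert t.expected_base_fraction == pytest.approx(0.01)

    def test_seed_changes_sequence_but_not_manifest(self, rng):
        fam = family(rng, copies=10)
        g1, t1 = build_genomes(small_spec(1, [fam]))
        g2, t2 = build_genomes(small_spec(2, [fam]))
        assert g1["R"] != g2["R"]
        assert t1.realized_copies == t2.realized_copies
        g1b, _ = build_genomes(small_spec(1, [fam]))
        assert g1b["R"] == g1["R"]  # identical seed -> byte-identical

    def test_tandem_family_is_one_contiguous_array(self, rng):
        fam = family(rng, copies=12, layout="tandem")
        genomes, truth = build_genomes(small_spec(5, [fam]))
        blocks = truth.placements["fam"]["R"]
        assert len(blocks) == 1
        start, blen = blocks[0]
        assert blen == 12 * 100
        assert genomes["R"][start : start + blen] == fam.consensus * 12

    def test_overfull_subgenome_raises(self, rng):
        fam = family(rng, n=5000, copies=30)
        with pytest.raises(InfeasibleSpecError):
            build_genomes(small_spec(1, [fam], length=100_000))


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        spec = SimSpec(
            subgenomes=(("R", 1_000_000),),
            accessions=(("A1", ("R",)),),
            coverage=10,
            paired=False,
            error_rate=0.0,
            seed=2,
        )
        genomes, truth = build_genomes(spec)
        reads = simulate_reads(genomes, ("R",), spec, "A1", truth)
        assert abs(len(reads) - 66_667) <= 667  # within 1 %
        assert truth.total_reads["A1"] == len(reads)

    def test_zero_error_reads_are_exact_substrings(self, rng):
        spec = small_spec(4, [family(rng, copies=5)], error_rate=0.0, coverage=2.0)
        genomes, _ = build_genomes(spec)
        reads = simulate_reads(genomes, ("R",), spec, "A1")
        genome = genomes["R"]
        rc = revcomp_py(genome)
        for r in reads[:200]:
            assert r.sequence in genome or r.sequence in rc

    def test_mate_pairs_flagged_and_deterministic(self, rng):
        spec = small_spec(9, coverage=1.0)
        genomes, _ = build_genomes(spec)
        reads1 = simulate_reads(genomes, ("R",), spec, "A1")
        reads2 = simulate_reads(genomes, ("R",), spec, "A1")
        assert [r.sequence for r in reads1] == [r.sequence for r in reads2]
        assert [r.mate for r in reads1[:4]] == [1, 2, 1, 2]
        assert reads1[0].name == reads1[1].name

    def test_fragment_longer_than_genome_raises(self, rng):
        spec = SimSpec(
            subgenomes=(("R", 300),),
            accessions=(("A1", ("R",)),),
            seed=1,
        )
        with pytest.raises(ValueError):
            simulate_reads({"R": "ACGT" * 75}, ("R",), spec, "A1")

    def test_specific_family_reads_carry_their_subgenome_label(self, rng):
        # an R-private family: >= 95 % of family-matching reads come from R
        fam = family(rng, name="rspec", copies=40, n=200)
        for seed in range(5):
            spec = SimSpec(
                subgenomes=(("R", 100_000), ("D", 100_000)),
                accessions=(("A1", ("R", "R", "D", "D")),),
                families=(fam,),
                seed=seed,
                coverage=8.0,
            )
            genomes, _ = build_genomes(spec)
            reads = simulate_reads(genomes, ("R", "R", "D", "D"), spec, "A1")
            windows = {fam.consensus[i : i + 50] for i in range(len(fam.consensus) - 49)}
            windows |= {revcomp_py(w) for w in windows}
            labels = [
                r.subgenome
                for r in reads
                if any(r.sequence[i : i + 50] in windows for i in range(0, 101, 10))
            ]
            assert labels, "no family-matching reads found"
            assert labels.count("R") / len(labels) >= 0.95

    def test_contaminant_reads_injected_at_requested_fraction(self, rng):
        cont = RepeatFamily(
            "plastid_frag", random_dna(rng, 500), 1, family_class="plastid_like"
        )
        spec = small_spec(11, [cont], contaminant_read_fraction=0.05, coverage=5.0)
        genomes, _ = build_genomes(spec)
        reads = simulate_reads(genomes, ("R",), spec, "A1")
        frac = sum(r.is_contaminant for r in reads) / len(reads)
        assert frac == pytest.approx(0.05, abs=0.005)


class TestPlantedFamilyRecovery:
    def test_exact_consensus_kmers_reach_expected_depth(self, rng):
        # with zero error and divergence, consensus 50-mers must appear at
        # >= copies x dosage x half the coverage-driven expectation
        fam = family(rng, copies=15, n=120)
        spec = small_spec(21, [fam], error_rate=0.0, coverage=6.0)
        genomes, _ = build_genomes(spec)
        reads = simulate_reads(genomes, ("R",), spec, "A1")
        profile = count_kmers(reads, k=50)
        depth = 6.0 * (120 - 49) / 150  # windows per copy x coverage / read len
        floor = 15 * depth * 0.5
        window = fam.consensus[30:80]
        assert profile.counts[window] >= floor

    def test_read_fraction_tracks_truth_within_binomial_noise(self, rng):
        # >= 95 % of (family, accession) pairs within 3 binomial sd, 10 seeds
        fam1 = family(rng, name="f1", copies=30, n=150)
        fam2 = family(
            rng, name="f2", copies=8, n=300, layout="tandem", subgenome_scope=("R", "D")
        )
        ok = total = 0
        for seed in range(10):
            spec = SimSpec(
                subgenomes=(("R", 150_000), ("D", 150_000)),
                accessions=(("DIP", ("R", "R")), ("TET", ("R", "R", "D", "D"))),
                families=(fam1, fam2),
                seed=seed,
                coverage=6.0,
            )
            genomes, truth = build_genomes(spec)
            for acc_id, dosage in spec.accessions:
                reads = simulate_reads(genomes, dosage, spec, acc_id, truth)
                n = len(reads)
                for fam in (fam1, fam2):
                    expected = truth.per_accession[acc_id][fam.name].expected_read_fraction
                    measured = consensus_read_fraction(fam.consensus, reads)
                    sd = max((expected * (1 - expected) / n) ** 0.5, 1e-9)
                    total += 1
                    ok += abs(measured - expected) <= 3 * sd
        assert ok / total >= 0.95

    def test_dosage_proportionality(self, rng):
        fam = family(rng, name="rf", copies=25, n=200)
        spec = SimSpec(
            subgenomes=(("R", 150_000), ("D", 150_000)),
            accessions=(("LOW", ("R", "D")), ("HIGH", ("R", "R", "D"))),
            families=(fam,),
            seed=6,
            coverage=8.0,
        )
        genomes, truth = build_genomes(spec)
        low = consensus_read_fraction(
            fam.consensus, simulate_reads(genomes, ("R", "D"), spec, "LOW")
        )
        high = consensus_read_fraction(
            fam.consensus, simulate_reads(genomes, ("R", "R", "D"), spec, "HIGH")
        )
        # R dosage doubles while genome grows 1.5x: expect 4/3 x, test vs truth
        ratio_expected = (
            truth.per_accession["HIGH"]["rf"].expected_read_fraction
            / truth.per_accession["LOW"]["rf"].expected_read_fraction
        )
        assert high / low == pytest.approx(ratio_expected, rel=0.2)


class TestGroundTruthSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        fam = family(rng, copies=5)
        spec = small_spec(13, [fam])
        _, truth = build_genomes(spec)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded.realized_copies == truth.realized_copies
        assert loaded.placements == truth.placements
        assert (
            loaded.per_accession["A1"]["fam"].expected_read_fraction
            == truth.per_accession["A1"]["fam"].expected_read_fraction
        )

    def test_subgenome_base_fractions_sum_to_one(self, rng):
        spec = small_spec(1, accessions=(("A1", ("R", "R", "D")),))
        _, truth = build_genomes(spec)
        assert sum(truth.subgenome_base_fraction["A1"].values()) == pytest.approx(1.0)


class TestSimulateHistogram:
    def test_main_peak_at_standard_position_for_diploid(self):
        hist = simulate_histogram(100, 2, 0.03, 20_000, seed=1)
        centers = hist.bin_centers
        assert abs(centers[np.argmax(hist.counts)] - 100) < 5

    def test_main_peak_scales_with_ploidy(self):
        hist = simulate_histogram(100, 6, 0.03, 20_000, seed=1)
        centers = hist.bin_centers
        assert abs(centers[np.argmax(hist.counts)] - 300) < 15

    def test_event_conservation_and_validation(self):
        hist = simulate_histogram(100, 2, 0.03, 5_000, seed=2)
        assert int(hist.counts.sum()) == 5_000
        with pytest.raises(ValueError):
            simulate_histogram(100, 2, 0.5, 5_000)
        with pytest.raises(ValueError):
            simulate_histogram(100, 2, 0.03, 10)

    def test_empirical_cv_close_to_planted(self):
        hist = simulate_histogram(100, 2, 0.03, 50_000, debris_fraction=0.0,
                                  g2_fraction=0.0, seed=3)
        centers = hist.bin_centers
        mean = np.average(centers, weights=hist.counts)
        sd = np.sqrt(np.average((centers - mean) ** 2, weights=hist.counts))
        assert abs(sd / mean - 0.03) / 0.03 < 0.15
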