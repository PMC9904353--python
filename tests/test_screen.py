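"""Unit tests for the comparative screen: matrix, strategies, assembly, probes."""

import numpy as np
import pandas as pd
import pytest

from repeatscreen.screen import (
    AbundanceMatrix,
    ScreenConfig,
    assemble_greedy,
    build_matrix,
    evaluate_recovery,
    score_probe,
    strategy_differential,
    strategy_shared,
)

from conftest import brute_genome_proportion, random_dna, revcomp_py


def make_matrix(values: dict[str, dict[str, float]]) -> AbundanceMatrix:
    return AbundanceMatrix(proportions=pd.DataFrame(values).T)


class TestBuildMatrix:
    def test_absent_motif_single_cell(self, rng):
        motif = "AC" * 25
        reads = [r for r in (random_dna(rng, 150) for _ in range(30)) if motif not in r]
        matrix = build_matrix([motif], {"acc": reads}, max_mismatches=0)
        assert matrix.proportions.shape == (1, 1)
        assert matrix.proportions.iat[0, 0] == 0.0

    def test_cells_match_bruteforce_oracle(self, rng):
        motifs = [random_dna(rng, 50) for _ in range(3)]
        read_sets = {}
        for acc in ("a1", "a2"):
            reads = []
            for _ in range(40):
                if rng.random() < 0.3:
                    m = motifs[int(rng.integers(0, 3))]
                    reads.append(random_dna(rng, 50) + m + random_dna(rng, 50))
                else:
                    reads.append(random_dna(rng, 150))
            read_sets[acc] = reads
        matrix = build_matrix(motifs, read_sets, max_mismatches=2)
        for m in motifs:
            for acc in read_sets:
                assert matrix.proportions.at[m, acc] == pytest.approx(
                    brute_genome_proportion(m, read_sets[acc], 2)
                )

    def test_zero_read_accession_error_names_accession(self, rng):
        with pytest.raises(ValueError, match="bad_acc"):
            build_matrix([random_dna(rng, 50)], {"bad_acc": []})

    def test_tsv_round_trip(self, rng, tmp_path):
        motifs = [random_dna(rng, 50) for _ in range(2)]
        reads = {"x": [motifs[0] + "ACGT" * 10], "y": [random_dna(rng, 100)]}
        matrix = build_matrix(motifs, reads)
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        loaded = AbundanceMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(
            loaded.proportions, matrix.proportions, check_names=False
        )


CONFIG = ScreenConfig(targets=("T1",), background=("B1", "B2"))


class TestStrategyDifferential:
    def test_accepts_when_thresholds_met(self):
        # target 1 %, background 0.005 %: ratio 200 >= 100 and 0.005 % < 0.01 %
        m = make_matrix({"A" * 50: {"T1": 0.01, "B1": 0.00005, "B2": 0.00002}})
        out = strategy_differential(m, CONFIG)
        assert [c.sequence for c in out.candidates] == ["A" * 50]

    def test_rejects_on_background_ceiling(self):
        m = make_matrix({"A" * 50: {"T1": 0.01, "B1": 0.0002, "B2": 0.0}})
        assert strategy_differential(m, CONFIG).candidates == []

    def test_rejects_on_ratio(self):
        m = make_matrix({"A" * 50: {"T1": 0.004, "B1": 0.00009, "B2": 0.0}})
        assert strategy_differential(m, CONFIG).candidates == []

    def test_zero_background_accepted_when_target_positive(self):
        m = make_matrix(
            {
                "A" * 50: {"T1": 0.003, "B1": 0.0, "B2": 0.0},
                "C" * 50: {"T1": 0.0, "B1": 0.0, "B2": 0.0},
            }
        )
        out = strategy_differential(m, CONFIG)
        assert [c.sequence for c in out.candidates] == ["A" * 50]

    def test_ranked_by_min_target_proportion(self):
        m = make_matrix(
            {
                "C" * 50: {"T1": 0.002, "B1": 0.0, "B2": 0.0},
                "A" * 50: {"T1": 0.005, "B1": 0.0, "B2": 0.0},
            }
        )
        out = strategy_differential(m, CONFIG)
        assert [c.sequence for c in out.candidates] == ["A" * 50, "C" * 50]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(targets=("X",), background=("X",))
        with pytest.raises(ValueError):
            ScreenConfig(targets=(), background=("B",))
        with pytest.raises(ValueError):
            ScreenConfig(targets=("T",), background=("B",), ratio_min=1.0)

    def test_monotone_under_stricter_thresholds(self, rng):
        accs = ["T1", "T2", "B1", "B2"]
        for _ in range(25):
            motifs = {random_dna(rng, 50): dict(zip(accs, rng.random(4) * 0.01))
                      for _ in range(20)}
            m = make_matrix(motifs)
            base = ScreenConfig(targets=("T1", "T2"), background=("B1", "B2"),
                                ratio_min=5, background_max=0.005)
            loose = {c.sequence for c in strategy_differential(m, base).candidates}
            for cfg in (
                ScreenConfig(targets=("T1", "T2"), background=("B1", "B2"),
                             ratio_min=50, background_max=0.005),
                ScreenConfig(targets=("T1", "T2"), background=("B1", "B2"),
                             ratio_min=5, background_max=0.001),
            ):
                strict = {c.sequence for c in strategy_differential(m, cfg).candidates}
                assert strict <= loose


class TestAssembleGreedy:
    def test_forced_merge_of_49_overlap(self, rng):
        seq = random_dna(rng, 51)
        contigs = assemble_greedy([seq[:50], seq[1:]], min_overlap=25)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp_py(seq))
        assert contigs[0].overlaps[0][2] == 49

    def test_disjoint_motifs_stay_singletons(self, rng):
        a, b = random_dna(rng, 50), random_dna(rng, 50)
        contigs = assemble_greedy([a, b], min_overlap=25)
        assert len(contigs) == 2
        assert {c.sequence for c in contigs} == {
            min(a, revcomp_py(a)), min(b, revcomp_py(b))
        }

    def test_tiled_windows_reconstruct_consensus(self, rng):
        consensus = random_dna(rng, 200)
        motifs = [consensus[i : i + 50] for i in range(0, 151, 5)]
        contigs = assemble_greedy(motifs, min_overlap=25)
        assert len(contigs) == 1
        joined = contigs[0].sequence
        assert consensus in joined or revcomp_py(consensus) in joined

    def test_reverse_complemented_input_assembles_identically(self, rng):
        consensus = random_dna(rng, 150)
        motifs = [consensus[i : i + 50] for i in range(0, 101, 10)]
        flipped = [revcomp_py(m) if i % 2 else m for i, m in enumerate(motifs)]
        c1 = assemble_greedy(motifs, min_overlap=25)
        c2 = assemble_greedy(flipped, min_overlap=25)
        assert [c.sequence for c in c1] == [c.sequence for c in c2]

    def test_every_motif_in_exactly_one_contig(self, rng):
        motifs = [random_dna(rng, 50) for _ in range(12)]
        consensus = random_dna(rng, 120)
        motifs += [consensus[i : i + 50] for i in range(0, 71, 7)]
        contigs = assemble_greedy(motifs, min_overlap=25)
        seen = [m for c in contigs for m in c.member_motifs]
        assert sorted(seen) == sorted(set(motifs))

    def test_layout_consistency_of_recorded_overlaps(self, rng):
        consensus = random_dna(rng, 300)
        motifs = [consensus[i : i + 50] for i in range(0, 251, 3)]
        for contig in assemble_greedy(motifs, min_overlap=25):
            seq = contig.sequence
            for left, right, ov in contig.overlaps:
                assert 25 <= ov <= 49

    def test_duplicates_collapsed_with_warning(self, rng):
        m = random_dna(rng, 50)
        with pytest.warns(UserWarning):
            contigs = assemble_greedy([m, m], min_overlap=25)
        assert len(contigs) == 1

    def test_min_overlap_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            assemble_greedy([random_dna(rng, 50)], min_overlap=10)


class TestStrategyShared:
    def _setup(self, rng, planted_in_background=False):
        consensus = random_dna(rng, 200)
        motifs = [consensus[i : i + 50] for i in range(0, 151, 5)]
        other = random_dna(rng, 120)
        target_sets = {
            "T1": motifs + [other[:50]],
            "T2": motifs + [other[10:60]],
        }
        def reads_with(frac_consensus):
            reads = []
            for _ in range(400):
                if rng.random() < frac_consensus:
                    reads.append(consensus)
                else:
                    reads.append(random_dna(rng, 200))
            return reads
        read_sets = {
            "T1": reads_with(0.05),
            "T2": reads_with(0.05),
            "B1": reads_with(0.2 if planted_in_background else 0.0),
        }
        config = ScreenConfig(targets=("T1", "T2"), background=("B1",),
                              target_min=0.005, background_max=0.01)
        return consensus, target_sets, read_sets, config

    def test_motif_missing_from_one_target_excluded(self, rng):
        consensus, target_sets, read_sets, config = self._setup(rng)
        out = strategy_shared(target_sets, read_sets, config, min_overlap=25)
        members = {m for c in out.candidates for m in c.members}
        # motifs present in only one target's set never reach assembly
        assert not any("".join(sorted(m)) == "".join(sorted(target_sets["T1"][-1]))
                       for m in members)
        assert out.candidates, "shared family should yield a candidate contig"
        top = out.candidates[0]
        assert consensus in top.sequence or revcomp_py(consensus) in top.sequence

    def test_family_abundant_in_background_rejected(self, rng):
        _, target_sets, read_sets, config = self._setup(rng, planted_in_background=True)
        out = strategy_shared(target_sets, read_sets, config, min_overlap=25)
        assert out.candidates == []

    def test_no_shared_motifs_gives_empty_set(self, rng):
        config = ScreenConfig(targets=("T1", "T2"), background=("B1",))
        out = strategy_shared(
            {"T1": [random_dna(rng, 50)], "T2": [random_dna(rng, 50)]},
            {"T1": ["A" * 100], "T2": ["A" * 100], "B1": ["A" * 100]},
            config,
        )
        assert out.candidates == []

    def test_needs_two_targets(self, rng):
        config = ScreenConfig(targets=("T1",), background=("B1",))
        with pytest.raises(ValueError):
            strategy_shared({"T1": []}, {}, config)


class TestScoreProbe:
    def test_homopolymer_and_gc_failure(self):
        report = score_probe("A" * 50)
        assert not report.suitable
        assert set(report.reasons) == {"gc_out_of_range", "homopolymer"}

    def test_balanced_sequence_suitable(self):
        probe = "ACGT" * 13  # GC 0.5, max run 1
        report = score_probe(probe)
        assert report.suitable and report.reasons == ()

    def test_telomeric_probe_rejected(self):
        report = score_probe(("TTTAGGG" * 8)[:50])
        assert not report.suitable and "telomeric" in report.reasons

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            score_probe("ACGT" * 5)


class TestEvaluateRecovery:
    def test_empty_candidates_convention(self, rng):
        report = evaluate_recovery([], {"fam": random_dna(rng, 200)})
        assert report.precision == 1.0 and report.recall == 0.0 and report.flagged

    def test_exact_candidates_perfect_score(self, rng):
        consensus = random_dna(rng, 200)
        report = evaluate_recovery([consensus[20:90]], {"fam": consensus})
        assert report.precision == 1.0 and report.recall == 1.0 and report.f1 == 1.0

    def test_empty_truth_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_recovery(["ACGT" * 20], {})

    def test_unrelated_candidates_score_zero(self, rng):
        report = evaluate_recovery(
            [random_dna(rng, 60)], {"fam": random_dna(rng, 200)}
        )
        assert report.precision == 0.0 and report.recall == 0.0
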