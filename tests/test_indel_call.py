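"""Fit alignment, CIGAR indel extraction, and spectra."""

import numpy as np
import pytest

from crispramp.errors import ValidationError
from crispramp.indel_call import (
    Alignment,
    AlignmentParams,
    IndelEvent,
    align_read,
    alignment_to_sam,
    call_reads,
    fit_align,
    fit_score,
    indel_spectra,
    indels_from_cigar,
    read_has_indel,
    reconstruct_read,
)
from crispramp.preprocess import preprocess_pairs
from crispramp.synthetic import SimulationConfig, simulate_sample
from helpers_oracles import oracle_fit_score


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFitAlign:
    def test_exact_substring_single_match_op(self, loci):
        ref = loci[0].reference
        read = ref[30:110]
        aln = fit_align(read, ref)
        assert aln.operations == [("M", 80)]
        assert aln.ref_start == 30
        assert aln.score == 80 * 2

    def test_deletion_recovered(self, loci):
        ref = loci[0].reference
        read = ref[20:100] + ref[102:180]  # 2-nt deletion at ref 100
        aln = fit_align(read, ref)
        events = indels_from_cigar(aln)
        assert len(events) == 1
        e = events[0]
        assert e.type == "deletion" and e.length == 2
        # repeats allow left-shifted placements of the same edit
        assert abs(e.position - 100) <= 2

    def test_insertion_recovered(self, loci):
        ref = loci[0].reference
        read = ref[20:100] + "TACGT" + ref[100:180]
        aln = fit_align(read, ref)
        events = indels_from_cigar(aln)
        assert len(events) == 1
        assert events[0].type == "insertion" and events[0].length == 5

    def test_read_span_covers_whole_read(self, loci, rng):
        ref = loci[0].reference
        for _ in range(10):
            start = int(rng.integers(0, 60))
            read = ref[start : start + 120]
            aln = fit_align(read, ref)
            assert aln.read_span == len(read)

    def test_score_matches_dp_oracle_on_random_pairs(self):
        """Fit-alignment scores equal an exhaustive three-state dynamic
        programming oracle on 100 random read/reference pairs
        (<= 40 / 80 nt), including edited and unrelated pairs."""
        rng = np.random.default_rng(7)
        params = AlignmentParams()
        for trial in range(100):
            ref = _random_dna(rng, int(rng.integers(30, 81)))
            kind = trial % 3
            if kind == 0:  # substring with substitutions
                lo = int(rng.integers(0, max(1, len(ref) - 25)))
                read = list(ref[lo : lo + int(rng.integers(15, 41))])
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(len(read)))
                    read[p] = "ACGT"[int(rng.integers(4))]
                read = "".join(read)
            elif kind == 1:  # substring with an indel
                lo = int(rng.integers(0, max(1, len(ref) - 30)))
                sub = ref[lo : lo + 30]
                p = int(rng.integers(5, 25))
                if rng.random() < 0.5:
                    read = sub[:p] + sub[p + int(rng.integers(1, 4)) :]
                else:
                    read = (sub[:p] + _random_dna(rng, int(rng.integers(1, 4)))
                            + sub[p:])
            else:  # unrelated
                read = _random_dna(rng, int(rng.integers(15, 41)))
            if not read:
                continue
            assert fit_score(read, ref, params) == pytest.approx(
                oracle_fit_score(ref, read)
            ), f"trial {trial}"

    def test_cigar_round_trip(self, loci, rng):
        """Reference + operations reproduce the read exactly."""
        ref = loci[0].reference
        for _ in range(20):
            start = int(rng.integers(0, 50))
            sub = ref[start : start + 150]
            p = int(rng.integers(20, 120))
            choice = int(rng.integers(3))
            if choice == 0:
                read = sub
            elif choice == 1:
                read = sub[:p] + sub[p + int(rng.integers(1, 6)) :]
            else:
                read = sub[:p] + _random_dna(rng, int(rng.integers(1, 6))) + sub[p:]
            aln = fit_align(read, ref)
            assert reconstruct_read(aln, ref, read) == read


class TestAlignRead:
    def test_assigns_source_locus(self, loci):
        read = loci[1].reference[25:200]
        aln = align_read(read, loci)
        assert aln is not None and aln.locus == loci[1].name

    def test_unrelated_read_unassigned(self, loci, rng):
        read = _random_dna(rng, 150)
        assert align_read(read, loci) is None

    def test_tie_between_duplicate_loci_unassigned(self, loci):
        import dataclasses

        twin = dataclasses.replace(loci[0], name="twin")
        read = loci[0].reference[25:200]
        assert align_read(read, [loci[0], twin]) is None

    def test_empty_inputs_rejected(self, loci):
        with pytest.raises(ValidationError):
            align_read("", loci)
        with pytest.raises(ValidationError):
            align_read("ACGT", [])

    def test_assignment_accuracy_on_simulated_pool(self, loci, samples):
        """>= 99% of error-bearing reads still map to their source
        amplicon when three loci compete."""
        correct = total = 0
        for locus, sample in zip(loci, samples):
            cfg = SimulationConfig(
                true_indel_rate=0.3, substitution_error_rate=0.001,
                n_reads=340, seed=31,
            )
            pairs, truth = simulate_sample(locus, sample, cfg)
            report = preprocess_pairs(
                ((p.read_id, p.seq1, p.qual1, p.seq2, p.qual2)
                 for p in pairs),
                list(samples),
            )
            for read in report.demux.by_sample.get(sample.sample_id, []):
                aln = align_read(read.insert, loci)
                total += 1
                if aln is not None and aln.locus == locus.name:
                    correct += 1
        assert total >= 1000
        assert correct / total >= 0.99


class TestIndelsFromCigar:
    def test_pure_match_yields_nothing(self):
        aln = Alignment("r", "l", 0, [("M", 80)], 160.0)
        assert indels_from_cigar(aln) == []

    def test_deletion_position_and_length(self):
        aln = Alignment("r", "l", 0, [("M", 20), ("D", 2), ("M", 58)], 0.0)
        assert indels_from_cigar(aln) == [IndelEvent("deletion", 20, 2)]

    def test_insertion_between_base_position(self):
        aln = Alignment("r", "l", 5, [("M", 10), ("I", 3), ("M", 67)], 0.0)
        assert indels_from_cigar(aln) == [IndelEvent("insertion", 15, 3)]

    def test_malformed_operations_rejected(self):
        with pytest.raises(ValidationError):
            Alignment("r", "l", 0, [("M", 0)], 0.0)
        with pytest.raises(ValidationError):
            Alignment("r", "l", 0, [("M", 5), ("M", 5)], 0.0)
        with pytest.raises(ValidationError):
            Alignment("r", "l", 0, [("X", 5)], 0.0)


class TestReadHasIndel:
    def test_pure_match_false(self):
        aln = Alignment("r", "l", 0, [("M", 150)], 300.0)
        assert not read_has_indel(aln)

    def test_window_containment(self):
        aln = Alignment("r", "l", 0, [("M", 100), ("D", 2), ("M", 48)], 0.0)
        assert read_has_indel(aln)
        assert read_has_indel(aln, window=(90, 110))
        assert not read_has_indel(aln, window=(0, 50))

    def test_substitutions_are_not_indels(self, loci):
        ref = loci[0].reference
        read = list(ref[20:180])
        read[50] = "A" if read[50] != "A" else "C"
        aln = fit_align("".join(read), ref)
        assert not read_has_indel(aln)


class TestSpectra:
    def test_empty(self, loci):
        pos, lengths = indel_spectra([], loci[0])
        assert not pos and not lengths

    def test_direct_count(self, loci):
        cut = loci[0].cut_position
        events = [IndelEvent("deletion", cut, 2)] * 10
        pos, lengths = indel_spectra(events, loci[0])
        assert pos == {0: 10}
        assert lengths == {-2: 10}

    def test_totals_match_truth_on_error_free_run(self, loci, samples):
        cfg = SimulationConfig(
            true_indel_rate=0.4, substitution_error_rate=0.0,
            deletion_fraction=1.0, n_reads=300, seed=41,
        )
        pairs, truth = simulate_sample(loci[0], samples[0], cfg)
        report = preprocess_pairs(
            ((p.read_id, p.seq1, p.qual1, p.seq2, p.qual2) for p in pairs),
            list(samples),
        )
        events = []
        for read in report.demux.by_sample[samples[0].sample_id]:
            aln = align_read(read.insert, loci)
            events.extend(indels_from_cigar(aln))
        pos, lengths = indel_spectra(events, loci[0])
        assert sum(pos.values()) == int(truth["edited"].sum())
        assert sum(lengths.values()) == int(truth["edited"].sum())
        assert all(k < 0 for k in lengths)  # deletions only


class TestCallReads:
    def test_calls_match_truth_exactly_without_errors(self, loci, samples):
        cfg = SimulationConfig(
            true_indel_rate=0.25, substitution_error_rate=0.0,
            n_reads=250, seed=51,
        )
        pairs, truth = simulate_sample(loci[0], samples[0], cfg)
        report = preprocess_pairs(
            ((p.read_id, p.seq1, p.qual1, p.seq2, p.qual2) for p in pairs),
            list(samples),
        )
        calls = call_reads(report.demux.by_sample, loci)
        merged = calls.merge(truth[["read_id", "edited"]], on="read_id")
        assert (merged["has_indel"] == merged["edited"]).all()
        assert (merged.loc[merged["assigned"], "locus"] == loci[0].name).all()

    def test_window_mode_restricts_to_cut_site(self, loci, samples):
        cfg = SimulationConfig(
            true_indel_rate=0.5, substitution_error_rate=0.0,
            n_reads=100, seed=52,
        )
        pairs, truth = simulate_sample(loci[0], samples[0], cfg)
        report = preprocess_pairs(
            ((p.read_id, p.seq1, p.qual1, p.seq2, p.qual2) for p in pairs),
            list(samples),
        )
        calls = call_reads(report.demux.by_sample, loci, window_halfwidth=25)
        merged = calls.merge(truth[["read_id", "edited"]], on="read_id")
        # all simulated indels sit at the cut site, so the window changes
        # nothing on clean data
        assert (merged["has_indel"] == merged["edited"]).all()


def test_sam_export_is_valid(loci, tmp_path):
    import pysam

    ref = loci[0].reference
    reads = [ref[10:150], ref[20:100] + ref[103:190]]
    alns = []
    for i, read in enumerate(reads):
        aln = fit_align(read, ref, read_id=f"read{i}", locus_name=loci[0].name)
        alns.append((aln, read, "I" * len(read)))
    sam_text = alignment_to_sam(alns, loci)
    path = tmp_path / "out.sam"
    path.write_text(sam_text)
    with pysam.AlignmentFile(str(path), "r") as fh:
        records = list(fh)
    assert len(records) == 2
    assert records[0].cigarstring == "140M"
    assert records[1].reference_start == 20
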