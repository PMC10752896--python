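"""Intron extraction and splice-flank stop-signal profiling."""

import numpy as np
import pytest

from codongc import (
    IntronSet,
    Intron,
    extract_introns,
    frame_triplet_counts,
    gc_content,
    random_intron_set,
    stop_profile,
    stop_probability,
)


def fasta_record(name, seq):
    return f">{name}\n{seq}\n"


def gff_two_exons(seqid="chr1", e1=(1, 100), e2=(201, 300), strand="+", tx="tx1"):
    lines = ["##gff-version 3"]
    lines.append(f"{seqid}\ttest\tgene\t{e1[0]}\t{e2[1]}\t.\t{strand}\t.\tID=g1")
    lines.append(f"{seqid}\ttest\tmRNA\t{e1[0]}\t{e2[1]}\t.\t{strand}\t.\tID={tx};Parent=g1")
    for i, (start, end) in enumerate((e1, e2)):
        lines.append(
            f"{seqid}\ttest\texon\t{start}\t{end}\t.\t{strand}\t.\tID={tx}.e{i};Parent={tx}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return seq, fasta_record("chr1", seq)


class TestGcContent:
    def test_pure_gc(self):
        assert gc_content(["GGCC"]) == 1.0

    def test_pure_at(self):
        assert gc_content(["ATAT"]) == 0.0

    def test_mode_difference(self):
        assert gc_content(["GC", "ATAT"], mode="per-record-mean") == 0.5
        assert gc_content(["GC", "ATAT"], mode="pooled") == pytest.approx(1 / 3)

    def test_ambiguity_codes_excluded(self):
        assert gc_content(["GCNN"], mode="pooled") == 1.0
        assert gc_content("GANN") == 0.5

    def test_errors(self):
        with pytest.raises(ValueError):
            gc_content([])
        with pytest.raises(ValueError):
            gc_content(["ACGT"], mode="median")


class TestExtractIntrons:
    def test_plus_strand_coordinates(self, toy_genome):
        seq, fasta = toy_genome
        iset = extract_introns(fasta, gff_two_exons())
        assert len(iset) == 1
        intron = iset[0]
        assert (intron.start, intron.end, intron.strand) == (101, 200, "+")
        assert intron.length == 100
        assert intron.sequence == seq[100:200]

    def test_minus_strand_reverse_complemented(self, toy_genome):
        from Bio.Seq import reverse_complement

        seq, fasta = toy_genome
        iset = extract_introns(fasta, gff_two_exons(strand="-"))
        assert len(iset) == 1
        assert iset[0].sequence == reverse_complement(seq[100:200])
        assert (iset[0].start, iset[0].end) == (101, 200)

    def test_short_intron_filtered(self, toy_genome):
        _, fasta = toy_genome
        iset = extract_introns(fasta, gff_two_exons(e2=(150, 300)))
        assert len(iset) == 0
        assert iset.min_length_filter == 100

    def test_orphan_exon_skipped_with_warning(self, toy_genome, caplog):
        _, fasta = toy_genome
        gff = (
            "##gff-version 3\n"
            "chr1\ttest\texon\t1\t100\t.\t+\t.\tID=lonely\n"
            + gff_two_exons()
        )
        with caplog.at_level("WARNING", logger="codongc.intron_miner"):
            iset = extract_introns(fasta, gff)
        assert len(iset) == 1
        assert "no resolvable parent" in caplog.text

    def test_overlapping_exons_skip_transcript(self, toy_genome, caplog):
        _, fasta = toy_genome
        gff = gff_two_exons(e1=(1, 220), e2=(201, 300))
        with caplog.at_level("WARNING", logger="codongc.intron_miner"):
            iset = extract_introns(fasta, gff)
        assert len(iset) == 0
        assert "overlapping exons" in caplog.text

    def test_cds_only_file_rejected(self, toy_genome):
        _, fasta = toy_genome
        gff = (
            "##gff-version 3\n"
            "chr1\ttest\tCDS\t1\t100\t.\t+\t0\tID=c1;Parent=tx1\n"
        )
        with pytest.raises(ValueError, match="CDS"):
            extract_introns(fasta, gff)

    def test_strand_encodings_give_same_intron_sequence(self):
        """A gene and its reverse-complement encoding yield identical introns."""
        from Bio.Seq import reverse_complement

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        plus = extract_introns(fasta_record("chr1", seq), gff_two_exons())
        flipped = reverse_complement(seq)
        n = len(seq)
        # exon (s, e) on + maps to (n-e+1, n-s+1) on - of the flipped record
        gff_minus = gff_two_exons(e1=(n - 300 + 1, n - 201 + 1), e2=(n - 100 + 1, n), strand="-")
        minus = extract_introns(fasta_record("chr1", flipped), gff_minus)
        assert len(plus) == len(minus) == 1
        assert plus[0].sequence == minus[0].sequence


class TestFrameBookkeeping:
    def test_worked_example_lengths_5_and_7(self):
        """Frames {0,1,2,0,1} and {0,1,2,0,1,2,0} give counts (3, 3, 2)."""
        assert frame_triplet_counts([5, 7]) == (3, 3, 2)

    def test_single_length(self):
        assert frame_triplet_counts([5]) == (1, 1, 1)
        assert frame_triplet_counts([7]) == (2, 2, 1)


def planted_intron(n=100):
    """100 nt intron 'GTAAGT…TTAG' with A/T filler: stop TAA planted at 2-4."""
    filler = "AT" * ((n - 10) // 2)
    seq = "GTAAGT" + filler + "TTAG"
    assert len(seq) == n
    return seq


class TestStopProfile:
    def test_planted_flank_stop(self, standard):
        iset = IntronSet(
            [
                Intron(planted_intron(), "chr1", "tx1", 1, 100, "+"),
            ]
        )
        prof = stop_profile(iset, standard)
        assert prof.flank5[1] == 1.0  # positions 2-4 = TAA
        assert prof.flank3[2] == 1.0  # last three = TAG
        assert prof.n_introns == 1

    def test_empty_set_rejected(self, standard):
        with pytest.raises(ValueError):
            stop_profile(IntronSet([]), standard)

    def test_short_intron_rejected(self, standard):
        iset = IntronSet([Intron("ACGT" * 10, "chr1", "tx1", 1, 40, "+")])
        with pytest.raises(ValueError, match="shorter"):
            stop_profile(iset, standard)

    def test_rest_frequencies_match_prediction_at_half_gc(self, standard):
        """2,000 i.i.d. introns at g=0.5: per-frame rest frequencies ≈ 3/64
        within 3 binomial SE, and ≈ the model prediction at observed GC."""
        iset = random_intron_set(2000, 150, 0.5, seed=1234)
        prof = stop_profile(iset, standard)
        expected = 3 / 64
        for f in range(3):
            se = np.sqrt(expected * (1 - expected) / prof.rest_triplet_counts[f])
            assert abs(prof.rest[f] - expected) <= 3 * se
            assert abs(prof.rest[f] - prof.predicted_rest) <= 3 * se + 1e-3
        assert prof.mean_rest_gc == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("g", [0.3, 0.5, 0.7])
    def test_parameter_recovery_all_nine_frequencies(self, standard, g):
        """All nine region×frame frequencies match the stop polynomial at g
        within 3 binomial standard errors."""
        iset = random_intron_set(2000, 150, g, seed=1234)
        prof = stop_profile(iset, standard)
        expected = stop_probability(standard, g)
        se_flank = np.sqrt(expected * (1 - expected) / prof.n_introns)
        for f in range(3):
            assert abs(prof.flank5[f] - expected) <= 3 * se_flank
            assert abs(prof.flank3[f] - expected) <= 3 * se_flank
            se_rest = np.sqrt(expected * (1 - expected) / prof.rest_triplet_counts[f])
            assert abs(prof.rest[f] - expected) <= 3 * se_rest

    def test_planted_motifs_bias_flank5_frame1(self, standard):
        """GTR 5' motifs put T at position 2 and a purine at 3, inflating the
        frame-1 flank stop frequency above the pseudo-random baseline."""
        iset = random_intron_set(2000, 150, 0.5, seed=1234, motif_mode="extended")
        prof = stop_profile(iset, standard)
        baseline = stop_probability(standard, 0.5)
        se = np.sqrt(baseline * (1 - baseline) / prof.n_introns)
        assert prof.flank5[1] > prof.flank5[0]
        assert prof.flank5[1] > baseline + 3 * se

    def test_profile_invariant_under_intron_order(self, standard):
        iset = random_intron_set(300, 120, 0.4, seed=7)
        shuffled = IntronSet(list(iset)[::-1], iset.min_length_filter)
        assert stop_profile(iset, standard) == stop_profile(shuffled, standard)

    def test_ambiguous_triplets_counted_in_denominator(self, standard):
        seq = planted_intron().replace("GTAAGT", "GTANGT")
        iset = IntronSet([Intron(seq, "chr1", "tx1", 1, 100, "+")])
        prof = stop_profile(iset, standard)
        assert prof.flank5[1] == 0.0  # TAN carries no stop weight
        assert prof.n_ambiguous_triplets >= 1

    def test_fractional_stop_weights_with_ambiguous_code(self, karyorelict):
        """Karyorelict UGA contributes 1/2 per occurrence."""
        seq = "TGA" + "C" * 94 + "TGA"
        assert len(seq) == 100
        iset = IntronSet([Intron(seq, "chr1", "tx1", 1, 100, "+")])
        prof = stop_profile(iset, karyorelict)
        assert prof.flank5[0] == 0.5
        assert prof.flank3[2] == 0.5


def test_end_to_end_mining_on_synthetic_genome(standard):
    """Full pipeline: generate, extract, profile; frequencies near prediction."""
    from codongc import GeneSpec, SyntheticGenomeSpec, generate_genome

    spec = SyntheticGenomeSpec(
        seed=2024,
        g=0.5,
        n_records=2,
        record_length=60_000,
        genes=tuple(
            GeneSpec(strand="+-"[i % 2], n_exons=6, exon_length=(50, 80), intron_length=(100, 200))
            for i in range(20)
        ),
    )
    genome = generate_genome(spec)
    iset = extract_introns(genome.fasta, genome.gff)
    assert len(iset) == len(genome.truth) == 100
    prof = stop_profile(iset, standard)
    expected = stop_probability(standard, 0.5)
    se = np.sqrt(expected * (1 - expected) / prof.n_introns)
    assert abs(prof.flank5[0] - expected) <= 4 * se
    assert prof.mean_rest_gc == pytest.approx(0.5, abs=0.02)
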