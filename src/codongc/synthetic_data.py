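"""Synthetic FASTA+GFF3 genomes with the statistical structure the model assumes.

Background, exon and intron bases are drawn i.i.d. with P(G) = P(C) = g/2
and P(A) = P(T) = (1-g)/2 — the pseudo-random sequence model — so every
mining stage can be exercised against known ground truth without external
data.  Planted multi-exon gene models are written as GFF3 with transcript
parentage, and a truth table records every planted intron (coordinates,
strand, coding-strand sequence, realized GC).

Splice-site motifs, when requested, overwrite the terminal intron bases
after i.i.d. generation: ``canonical`` plants GT…AG (2 nt each end),
``extended`` plants GTR…YAG (3 nt each end, R/Y drawn uniformly).  A
5'-flank stop can additionally be forced at intron positions 2-4 (it takes
precedence over motif bases on overlap).  Because planting perturbs the
realized GC slightly, the truth table stores realized rather than nominal
values.

One RNG stream is derived per record from the genome seed via
``SeedSequence(seed, spawn_key=(record_index,))``, so adding records never
reshuffles earlier ones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .intron_miner import Intron, IntronSet

__all__ = [
    "GeneSpec",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "LayoutError",
    "generate_genome",
    "generate_triplet_sequence",
    "random_intron_set",
]

_STOPS_DNA = ("TAA", "TAG", "TGA")
_MOTIF_MODES = ("none", "canonical", "extended")


class LayoutError(ValueError):
    """Raised when the requested gene models do not fit in their records."""


@dataclass(frozen=True)
class GeneSpec:
    """One planted gene: strand, exon count, and exon/intron length ranges.

    Length ranges are inclusive ``(lo, hi)`` in nt; introns should be kept
    at ≥ 100 nt when fixtures target the miner's default length filter.
    """

    strand: str = "+"
    n_exons: int = 3
    exon_length: tuple[int, int] = (100, 200)
    intron_length: tuple[int, int] = (100, 300)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_exons < 2:
            raise ValueError("a gene needs at least two exons to contain an intron")
        for lo, hi in (self.exon_length, self.intron_length):
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid length range ({lo}, {hi})")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome draw."""

    seed: int
    g: float = 0.5
    n_records: int = 1
    record_length: int = 20_000
    genes: tuple[GeneSpec, ...] = ()
    motif_mode: str = "none"
    planted_flank_stop_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.g <= 1:
            raise ValueError("GC content must lie in [0, 1]")
        if self.motif_mode not in _MOTIF_MODES:
            raise ValueError(f"motif_mode must be one of {_MOTIF_MODES}")
        if not 0 <= self.planted_flank_stop_rate <= 1:
            raise ValueError("planted_flank_stop_rate must lie in [0, 1]")
        if self.n_records < 1 or self.record_length < 1:
            raise ValueError("need at least one record of positive length")
        object.__setattr__(self, "genes", tuple(self.genes))


class SyntheticGenome(NamedTuple):
    """Generated genome: FASTA text, GFF3 text, and the intron truth table."""

    fasta: str
    gff: str
    truth: pd.DataFrame


_TRUTH_COLUMNS = [
    "record_id", "transcript_id", "intron_index", "start", "end", "strand",
    "length", "sequence", "motif_mode", "planted_stop", "realized_gc",
]


def _record_rng(seed: int, record_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(record_index,)))


def _random_dna(rng: np.random.Generator, n: int, g: float) -> np.ndarray:
    bases = np.array(list("ACGT"))
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    return bases[rng.choice(4, size=n, p=p)]


def _dress_intron(
    coding: np.ndarray,
    rng: np.random.Generator,
    motif_mode: str,
    stop_rate: float,
) -> tuple[np.ndarray, bool]:
    """Overwrite terminal motif bases and optionally plant a stop at positions 2-4."""
    if motif_mode == "canonical":
        coding[0:2] = list("GT")
        coding[-2:] = list("AG")
    elif motif_mode == "extended":
        coding[0:2] = list("GT")
        coding[2] = "AG"[rng.integers(2)]  # R: purine
        coding[-3] = "CT"[rng.integers(2)]  # Y: pyrimidine
        coding[-2:] = list("AG")
    planted = stop_rate > 0 and rng.random() < stop_rate
    if planted:
        coding[1:4] = list(_STOPS_DNA[rng.integers(3)])
    return coding, planted


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Draw a synthetic genome: FASTA records, GFF3 gene models, truth table.

    Genes are distributed over records round-robin and laid out left to
    right with fixed margins; a :class:`LayoutError` is raised if a record
    cannot hold its genes.  Output is deterministic given the spec.
    """
    margin, gap = 10, 20
    records: list[np.ndarray] = []
    rngs = [_record_rng(spec.seed, i) for i in range(spec.n_records)]
    for rng in rngs:
        records.append(_random_dna(rng, spec.record_length, spec.g))

    per_record: list[list[tuple[int, GeneSpec]]] = [[] for _ in range(spec.n_records)]
    for j, gene in enumerate(spec.genes):
        per_record[j % spec.n_records].append((j, gene))

    gff_lines = ["##gff-version 3"]
    truth_rows = []
    for rec_index, assigned in enumerate(per_record):
        rec_id = f"chr{rec_index + 1}"
        rng = rngs[rec_index]
        seq = records[rec_index]
        cursor = margin
        for j, gene in assigned:
            exon_lens = rng.integers(
                gene.exon_length[0], gene.exon_length[1] + 1, size=gene.n_exons
            )
            intron_lens = rng.integers(
                gene.intron_length[0], gene.intron_length[1] + 1, size=gene.n_exons - 1
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + margin > spec.record_length:
                raise LayoutError(
                    f"gene {j} (span {span} nt) does not fit in record "
                    f"{rec_id} of length {spec.record_length}"
                )
            gene_id, tx_id = f"gene{j + 1:04d}", f"tx{j + 1:04d}"
            gene_start = cursor + 1  # 1-based
            pos = gene_start
            exons: list[tuple[int, int]] = []
            gaps: list[tuple[int, int]] = []
            for k in range(gene.n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos += int(exon_lens[k])
                if k < gene.n_exons - 1:
                    gaps.append((pos, pos + int(intron_lens[k]) - 1))
                    pos += int(intron_lens[k])
            gene_end = pos - 1
            cursor = gene_end + gap

            # introns in transcript (5'→3') order
            tx_gaps = gaps if gene.strand == "+" else gaps[::-1]
            for idx, (istart, iend) in enumerate(tx_gaps):
                genomic = seq[istart - 1 : iend].copy()
                if gene.strand == "-":
                    coding = np.array(list(reverse_complement("".join(genomic))))
                else:
                    coding = genomic
                coding, planted = _dress_intron(
                    coding, rng, spec.motif_mode, spec.planted_flank_stop_rate
                )
                coding_str = "".join(coding)
                back = (
                    np.array(list(reverse_complement(coding_str)))
                    if gene.strand == "-"
                    else coding
                )
                seq[istart - 1 : iend] = back
                gc = (
                    (coding == "G").sum() + (coding == "C").sum()
                ) / len(coding)
                truth_rows.append(
                    dict(
                        record_id=rec_id,
                        transcript_id=tx_id,
                        intron_index=idx,
                        start=istart,
                        end=iend,
                        strand=gene.strand,
                        length=iend - istart + 1,
                        sequence=coding_str,
                        motif_mode=spec.motif_mode,
                        planted_stop=planted,
                        realized_gc=float(gc),
                    )
                )

            common = f"{rec_id}\tcodongc-sim"
            gff_lines.append(
                f"{common}\tgene\t{gene_start}\t{gene_end}\t.\t{gene.strand}\t.\tID={gene_id}"
            )
            gff_lines.append(
                f"{common}\tmRNA\t{gene_start}\t{gene_end}\t.\t{gene.strand}\t.\t"
                f"ID={tx_id};Parent={gene_id}"
            )
            for k, (estart, eend) in enumerate(exons):
                gff_lines.append(
                    f"{common}\texon\t{estart}\t{eend}\t.\t{gene.strand}\t.\t"
                    f"ID={tx_id}.exon{k + 1};Parent={tx_id}"
                )

    handle = io.StringIO()
    SeqIO.write(
        [
            SeqRecord(Seq("".join(rec)), id=f"chr{i + 1}", description="")
            for i, rec in enumerate(records)
        ],
        handle,
        "fasta",
    )
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return SyntheticGenome(fasta=handle.getvalue(), gff="\n".join(gff_lines) + "\n", truth=truth)


def generate_triplet_sequence(g: float, n_triplets: int, seed: int) -> list[str]:
    """Draw ``n_triplets`` i.i.d. RNA codons from the product distribution at GC ``g``."""
    if n_triplets < 0:
        raise ValueError("n_triplets must be nonnegative")
    if not 0 <= g <= 1:
        raise ValueError("GC content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    draw = bases[rng.choice(4, size=(n_triplets, 3), p=p)]
    return ["".join(row) for row in draw]


def random_intron_set(
    n_introns: int,
    length: int,
    g: float,
    seed: int,
    motif_mode: str = "none",
    planted_flank_stop_rate: float = 0.0,
) -> IntronSet:
    """I.i.d. synthetic introns of fixed length, wrapped as an :class:`IntronSet`.

    A lightweight alternative to :func:`generate_genome` for profiling tests
    that need many introns but no genome context; provenance fields mark the
    introns as synthetic.
    """
    if length < 100:
        raise ValueError("profiled introns must be at least 100 nt")
    if motif_mode not in _MOTIF_MODES:
        raise ValueError(f"motif_mode must be one of {_MOTIF_MODES}")
    rng = np.random.default_rng(seed)
    introns = []
    pos = 1
    for i in range(n_introns):
        coding = _random_dna(rng, length, g)
        coding, _ = _dress_intron(coding, rng, motif_mode, planted_flank_stop_rate)
        introns.append(
            Intron(
                sequence="".join(coding),
                record_id="synthetic",
                transcript_id=f"synthetic.tx{i + 1}",
                start=pos,
                end=pos + length - 1,
                strand="+",
            )
        )
        pos += length
    return IntronSet(introns=introns, min_length_filter=min(100, length))
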