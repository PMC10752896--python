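"""Intron extraction from FASTA+GFF3 and stop-signal profiling near splice sites.

Introns are the gaps between consecutive exons of a transcript, read 5'→3'
on the coding strand (minus-strand gaps are reverse-complemented).  For each
intron of length n, three regions are profiled for stop-signal triplets:

* 5'-flank:   the overlapping triplets at positions 1-3, 2-4, 3-5
  (frames 0, 1, 2 relative to the intron start),
* 3'-flank:   positions n-4…n-2, n-3…n-1, n-2…n,
* rest:       the intermediate sequence, positions 6 … n-5, scanned in the
  three frames anchored at the intron start (position p belongs to frame
  (p-1) mod 3); trailing positions that cannot begin a full triplet inside
  the window are dropped.

Flank frequencies are per-intron (denominator = number of introns); rest
frequencies are per-triplet within each frame.  Introns shorter than the
length filter (default 100 nt) are removed so the three regions are
well-defined and disjoint.  A triplet's contribution is its (possibly
fractional) stop weight under the chosen genetic code; triplets containing
ambiguity codes contribute 0 but stay in the denominator.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement
from Bio.SeqUtils import gc_fraction

from .frequency_model import signal_polynomial
from .genetic_codes import STOP, GeneticCode

__all__ = [
    "Intron",
    "IntronSet",
    "IntronStopProfile",
    "gc_content",
    "extract_introns",
    "stop_profile",
    "frame_triplet_counts",
]

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

PathOrContent = Union[str, os.PathLike, io.IOBase]


@dataclass(frozen=True)
class Intron:
    """One extracted intron, oriented 5'→3' on the coding strand.

    ``start``/``end`` are 1-based inclusive genomic coordinates on the
    reference (plus) strand; ``sequence`` is already reverse-complemented
    for minus-strand transcripts, so position 1 is the 5' splice end.
    """

    sequence: str
    record_id: str
    transcript_id: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class IntronSet:
    """Strand-resolved introns retained by a minimum-length filter."""

    introns: list[Intron]
    min_length_filter: int = 100

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self) -> Iterator[Intron]:
        return iter(self.introns)

    def __getitem__(self, i):
        return self.introns[i]

    def sequences(self) -> list[str]:
        return [intr.sequence for intr in self.introns]


def _as_text(source: PathOrContent, kind: str) -> str:
    """Read GFF3/FASTA input given as a path, raw content string, or handle."""
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        return Path(source).read_text()
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith((">", "##gff")):
            return source
        return Path(source).read_text()
    raise TypeError(f"cannot read {kind} from {type(source).__name__}")


def gc_content(
    sequences: Union[str, Iterable[str]],
    mode: str = "per-record-mean",
) -> float:
    """GC fraction of one or more DNA sequences.

    ``per-record-mean`` averages the per-sequence GC fractions without length
    weighting (the convention for multi-record genome summaries); ``pooled``
    computes (G+C)/(A+C+G+T) over the concatenation.  N and other ambiguity
    codes are excluded from numerator and denominator in both modes.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("gc_content requires at least one sequence")
    if mode == "pooled":
        pooled = "".join(seqs)
        if not any(b in _DNA for b in pooled):
            raise ValueError("no unambiguous bases in input")
        return gc_fraction(pooled, ambiguous="remove")
    if mode == "per-record-mean":
        fractions = []
        for s in seqs:
            if not any(b in _DNA for b in s):
                logger.warning("sequence with no unambiguous bases skipped in GC mean")
                continue
            fractions.append(gc_fraction(s, ambiguous="remove"))
        if not fractions:
            raise ValueError("no sequence with unambiguous bases in input")
        return float(np.mean(fractions))
    raise ValueError(f"unknown mode {mode!r}: expected 'per-record-mean' or 'pooled'")


def _exon_groups(db: gffutils.FeatureDB):
    """Group exon features by transcript parent (Parent attr, else transcript_id)."""
    groups: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("transcript_id")
        if not parents:
            logger.warning(
                "exon at %s:%d-%d has no resolvable parent; skipped",
                exon.seqid, exon.start, exon.end,
            )
            continue
        for parent in parents:
            groups.setdefault(parent, []).append(exon)
    return groups


def extract_introns(
    fasta: PathOrContent,
    gff: PathOrContent,
    min_len: int = 100,
) -> IntronSet:
    """Extract introns from a genome FASTA and GFF3 gene models.

    Introns are the gaps between consecutive exons of each transcript
    (grouped by the exons' ``Parent`` attribute, falling back to
    ``transcript_id``), ordered 5'→3' along the transcript, with
    minus-strand gaps reverse-complemented.  Transcripts with overlapping
    exons are skipped with a warning; introns shorter than ``min_len`` are
    dropped.  Files whose gene models carry only CDS features are rejected.

    ``fasta`` and ``gff`` may be file paths, raw content strings, or handles.
    """
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(_as_text(fasta, "FASTA")), "fasta")
    }
    if not genome:
        raise ValueError("no FASTA records found")
    db = gffutils.create_db(
        _as_text(gff, "GFF3"),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups = _exon_groups(db)
    if not groups:
        if any(True for _ in db.features_of_type("CDS")):
            raise ValueError(
                "GFF3 contains CDS features but no exon features; "
                "intron extraction requires exon features with transcript parentage"
            )
        raise ValueError("GFF3 contains no exon features")

    introns: list[Intron] = []
    for transcript_id, exons in groups.items():
        exons = sorted(exons, key=lambda e: e.start)
        strands = {e.strand for e in exons}
        seqids = {e.seqid for e in exons}
        if len(strands) > 1 or len(seqids) > 1:
            logger.warning("transcript %s mixes strands or records; skipped", transcript_id)
            continue
        if any(b.start <= a.end for a, b in zip(exons, exons[1:])):
            logger.warning("transcript %s has overlapping exons; skipped", transcript_id)
            continue
        strand = exons[0].strand
        seqid = exons[0].seqid
        if seqid not in genome:
            logger.warning("transcript %s on unknown record %s; skipped", transcript_id, seqid)
            continue
        gaps = [
            (a.end + 1, b.start - 1)
            for a, b in zip(exons, exons[1:])
            if b.start - a.end > 1
        ]
        if strand == "-":
            gaps = gaps[::-1]  # 5'→3' along the transcript
        for start, end in gaps:
            seq = genome[seqid][start - 1 : end]
            if strand == "-":
                seq = reverse_complement(seq)
            if len(seq) >= min_len:
                introns.append(
                    Intron(
                        sequence=seq,
                        record_id=seqid,
                        transcript_id=transcript_id,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
    return IntronSet(introns=introns, min_length_filter=min_len)


@dataclass(frozen=True)
class IntronStopProfile:
    """Per-frame stop-signal frequencies of an intron set.

    ``flank5``/``flank3`` have denominator ``n_introns``; ``rest`` divides
    per-frame stop counts by per-frame triplet counts over the intermediate
    windows.  ``predicted_rest`` is the profiled code's stop-frequency
    polynomial evaluated at the pooled GC of the intermediate sequences.
    """

    n_introns: int
    flank5: tuple[float, float, float]
    flank3: tuple[float, float, float]
    rest: tuple[float, float, float]
    rest_triplet_counts: tuple[int, int, int]
    mean_rest_gc: float
    predicted_rest: float
    n_ambiguous_triplets: int = field(default=0, compare=False)


def frame_triplet_counts(lengths: Sequence[int]) -> tuple[int, int, int]:
    """Number of triplet start positions per frame over full-length introns.

    Position p (1-based) belongs to frame (p-1) mod 3; the last two
    positions of each intron cannot begin a triplet and are ignored.  For
    lengths {5, 7} this yields (3, 3, 2).
    """
    counts = np.zeros(3, dtype=int)
    for n in lengths:
        for p in range(1, n - 1):
            counts[(p - 1) % 3] += 1
    return tuple(int(c) for c in counts)


def _triplet_stop_weight(code: GeneticCode, triplet: str) -> tuple[float, bool]:
    """(stop weight, had_ambiguity): ambiguous-base triplets weigh 0."""
    if set(triplet) <= _DNA:
        return float(code.stop_weight(triplet)), False
    return 0.0, True


def stop_profile(introns: IntronSet, code: GeneticCode) -> IntronStopProfile:
    """Stop-signal frequencies of an intron set at both flanks and in between.

    Requires every intron to be at least as long as the set's length filter
    (and ≥ 100 nt) so the three regions are disjoint.
    """
    n = len(introns)
    if n == 0:
        raise ValueError("cannot profile an empty intron set")
    min_required = max(introns.min_length_filter, 100)
    short = [i.length for i in introns if i.length < min_required]
    if short:
        raise ValueError(
            f"{len(short)} intron(s) shorter than {min_required} nt; the three "
            "profile regions are only defined for introns of at least that length"
        )

    flank5_w = np.zeros(3)
    flank3_w = np.zeros(3)
    rest_w = np.zeros(3)
    rest_counts = np.zeros(3, dtype=int)
    n_ambiguous = 0
    rest_parts: list[str] = []

    for intr in introns:
        seq = intr.sequence.upper()
        length = intr.length
        for f in range(3):
            w, amb = _triplet_stop_weight(code, seq[f : f + 3])
            flank5_w[f] += w
            n_ambiguous += amb
            w, amb = _triplet_stop_weight(code, seq[length - 5 + f : length - 2 + f])
            flank3_w[f] += w
            n_ambiguous += amb
        # intermediate window: positions 6 … n-5 (1-based) = seq[5 : length-5]
        rest_parts.append(seq[5 : length - 5])
        # triplet starts p ∈ [6, n-7] (1-based) so the triplet fits the window
        for i in range(5, length - 7):
            w, amb = _triplet_stop_weight(code, seq[i : i + 3])
            frame = i % 3  # == (p-1) mod 3 for p = i+1
            rest_w[frame] += w
            rest_counts[frame] += 1
            n_ambiguous += amb

    if n_ambiguous:
        logger.info(
            "%d triplet(s) containing ambiguity codes contributed 0 stop weight",
            n_ambiguous,
        )
    mean_rest_gc = gc_content(rest_parts, mode="pooled")
    predicted = float(signal_polynomial(code, STOP)(mean_rest_gc))
    with np.errstate(invalid="ignore"):
        rest = np.where(rest_counts > 0, rest_w / np.maximum(rest_counts, 1), 0.0)
    return IntronStopProfile(
        n_introns=n,
        flank5=tuple(float(x) / n for x in flank5_w),
        flank3=tuple(float(x) / n for x in flank3_w),
        rest=tuple(float(r) for r in rest),
        rest_triplet_counts=tuple(int(c) for c in rest_counts),
        mean_rest_gc=float(mean_rest_gc),
        predicted_rest=predicted,
        n_ambiguous_triplets=int(n_ambiguous),
    )
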