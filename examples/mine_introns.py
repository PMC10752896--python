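"""Mine stop signals near splice sites in a synthetic genome.

Generates a genome (i.i.d. bases at 45% GC) with 30 planted multi-exon genes
whose introns carry extended GTR…YAG splice motifs, extracts the introns
from the FASTA+GFF3 pair, and profiles stop-signal frequencies in the three
frames at the 5'-flank, the 3'-flank, and the intermediate sequence.
"""

from codongc import (
    GeneSpec,
    SyntheticGenomeSpec,
    extract_introns,
    generate_genome,
    load_code,
    stop_profile,
)

spec = SyntheticGenomeSpec(
    seed=2024,
    g=0.45,
    n_records=3,
    record_length=80_000,
    genes=tuple(
        GeneSpec(strand="+-"[i % 2], n_exons=5, exon_length=(60, 120),
                 intron_length=(100, 400))
        for i in range(30)
    ),
    motif_mode="extended",
)
genome = generate_genome(spec)
introns = extract_introns(genome.fasta, genome.gff, min_len=100)
profile = stop_profile(introns, load_code("Standard"))

print(f"introns extracted: {profile.n_introns} "
      f"(truth table planted {len(genome.truth)})")
print(f"mean GC of intermediate sequence: {profile.mean_rest_gc:.3f}")
print(f"predicted stop frequency/triplet at that GC: {profile.predicted_rest:.4f}")
print()
print(f"{'region':<10} {'frame 0':>8} {'frame 1':>8} {'frame 2':>8}")
for region, freqs in (("5'-flank", profile.flank5),
                      ("3'-flank", profile.flank3),
                      ("rest", profile.rest)):
    print(f"{region:<10} " + " ".join(f"{f:8.4f}" for f in freqs))
print()
print("The GTR motif makes positions 2-4 read T-purine-N, so the frame-1")
print("5'-flank stop frequency far exceeds the pseudo-random baseline, while")
print("the intermediate sequence stays at the predicted per-triplet rate.")
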