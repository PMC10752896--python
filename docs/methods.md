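# Methods

## Sequence model

All analytic results concern pseudo-random sequence: nucleotides i.i.d.
with P(G) = P(C) = g/2 and P(A) = P(U) = (1−g)/2, where g ∈ [0, 1] is the GC
content. This hard-wires Chargaff's second parity rule (GC skew = AT skew
= 0); skewed compositions, dinucleotide (Markov) structure, position-specific
(wobble) effects and any codon bias beyond GC dependence are out of scope.
Codon probabilities are products of base probabilities, i.e. reading-frame
independent.

## Genetic codes and the even-split rule

The 25 codes are the NCBI translation tables {1–6, 9–14, 16, 21–31, 33}
(the set catalogued as of late 2022; deprecated table 15 and later additions
excluded), bundled as package data: a 64-letter assignment string per code
plus explicit ambiguity overrides. A codon assigned to k > 1 signals
contributes weight 1/k to each:

* table 13 (ascidian mitochondrial): AGA, AGG → Gly/Arg/Ser at 1/3 each;
* tables 27, 28, 31: the dual stop/readthrough codons (27: UGA↔Trp;
  28: UAA/UAG↔Gln and UGA↔Trp; 31: UAA/UAG↔Glu) at 1/2 each.

Weights are `fractions.Fraction` values and always sum to exactly 1 per
codon. Start-codon annotations are carried as metadata only. The package
does not fetch tables at runtime; the unit tests cross-check every
unambiguous assignment and stop set against `Bio.Data.CodonTable`.

## Frequency polynomials

A signal's expected frequency is the weight-summed probability of its
codons — a cubic (or lower-degree) polynomial in g with rational
coefficients whose denominators divide 24. Coefficients stay exact until
evaluation, so closed-form identities (e.g. P_Stop = (1−g)²(1+g)/8 for the
standard code) hold symbolically, not merely numerically. Maxima over
[0, 1] are found analytically from the derivative's roots plus the
endpoints; ties (within 1e-12) report every maximizing g, with the smallest
as the representative. Requesting the maximum of a signal absent from a
code raises an explicit error rather than returning a degenerate 0.

## Entropy

I(g) = −Σ pᵢ log₂ pᵢ over the 21 signals, with 0·log 0 = 0. The entropy is
computed at the amino-acid level — synonymous codons are pooled before the
logarithm — not at the codon level, which would peak elsewhere. The
maximizer is found by a vectorized grid scan (step 1e-4) followed by bounded
scalar minimization (`scipy.optimize.minimize_scalar`, xatol 1e-7);
reported optima are conventionally rounded to 2 decimals of percent. The
curves are smooth and empirically unimodal for every bundled code (asserted
in tests, not assumed by the optimizer). Near g = 0 and g = 1 the slope
grows like |log p| as signals vanish, which bounds but does not break the
grid scan: with step 1e-4 the bracketing error is far below the reported
precision.

At g = 1 exactly four amino acids (Ala, Arg, Gly, Pro) survive at 1/4 each,
so I = 2 bits for every code — a useful exact anchor. The maximum region is
flat: for the standard code I(0.36) ≈ 4.21 and I(0.64) ≈ 4.01 bits (mean
4.11), and I stays above 4 bits down to 28% GC.

## Stop spacing and the stop-to-stop ORF definition

With per-triplet stop probability P_stop(g), the probability that c
independent triplets contain at least one stop is 1 − (1 − P_stop)^c, and
the minimum c reaching a target p is ⌈log(1−p)/log(1−P_stop)⌉. The ceiling
is verified against the defining inequality to guard float round-off at
integer boundaries. Logarithm base cancels in the ratio. Where P_stop(g) = 0
(standard code at g = 1; karyorelict at g = 0) the length diverges and an
explicit "unreachable" error is raised. Overlapping-frame corrections to the
independence assumption are deliberately not applied.

## Intron mining

Introns are gaps between consecutive exons of a transcript. Exons are
grouped by their GFF3 `Parent` attribute (falling back to `transcript_id`);
CDS-only files are rejected rather than guessed at. Minus-strand gaps are
reverse-complemented so position 1 is always the 5′ splice end; introns are
enumerated 5′→3′ along the transcript. Exon features without a resolvable
parent are skipped with a warning, as are transcripts with overlapping
exons. Identical introns shared by isoforms are *not* deduplicated: each
transcript contributes its own introns, which inflates n at multi-isoform
loci and is the documented convention here.

Profiling regions for an intron of length n (1-based positions):

* 5′-flank: triplets at 1–3, 2–4, 3–5 (frames 0, 1, 2);
* 3′-flank: n−4…n−2, n−3…n−1, n−2…n;
* rest: positions 6…n−5, scanned in the three frames anchored at the intron
  start (position p belongs to frame (p−1) mod 3); window positions that
  cannot begin a full triplet inside the window are dropped.

Flank frequencies divide by the number of introns; rest frequencies divide
per-frame stop counts by per-frame triplet counts. The default ≥ 100 nt
length filter keeps the three regions disjoint and is enforced at profiling
time. A triplet contributes its (possibly fractional) stop weight, so
profiling under an ambiguous code counts karyorelict UGA as 1/2; for the
standard code this coincides with hard 0/1 counting. Triplets containing N
or other ambiguity codes contribute 0 but remain in the denominator
(conservative), with a logged tally.

Two GC conventions are exposed because they answer different questions:
`per-record-mean` (unweighted mean of per-sequence GC, the convention for
multi-record genome summaries) and `pooled` ((G+C)/(A+C+G+T) over the
concatenation). The profile's `mean_rest_gc` pools the intermediate windows
— the natural weighting when the quantity it feeds is a per-triplet rate —
and `predicted_rest` evaluates the *profiled code's* stop polynomial there,
which generalizes the standard-code prediction without changing it in the
standard-code case.

## Synthetic genomes

The generator emulates exactly what the analysis assumes: i.i.d. background,
exons and introns at a target GC (exons get no coding constraint — the
fixtures test mining mechanics, not gene realism), planted multi-exon gene
models written as GFF3 with transcript parentage, and a truth table of every
intron. Splice motifs overwrite terminal intron bases after generation
(canonical GT…AG: 2 nt; extended GTR…YAG: 3 nt, R/Y uniform), and a 5′ stop
can be forced at positions 2–4 with a configurable rate (taking precedence
over motif bases on overlap). Planting perturbs realized GC, so the truth
table records realized values and tests compare against those. One RNG
substream per record is derived as `SeedSequence(seed, spawn_key=(record,))`,
so adding records never reshuffles earlier ones; identical spec + seed gives
byte-identical FASTA/GFF3.

Defaults used in tests and acceptance checks: 2,000 introns of 150 nt for
parameter-recovery profiles at g ∈ {0.3, 0.5, 0.7} (all nine region×frame
frequencies within 3 binomial SE of the polynomial), 10⁵ triplets for
Monte-Carlo checks of the codon-product distribution. What passing shows:
the pipeline recovers the i.i.d. model's parameters and detects planted
splice-motif bias. What it does not show: real introns have branch points,
polypyrimidine tracts, length and GC heterogeneity none of which are
emulated; empirical per-clade frequencies on real genomes are outside this
package's inputs.

## Numerical choices

* Exact rationals for weights and polynomial coefficients; floats only at
  evaluation and optimization.
* Entropy optimization tolerance 1e-7 in g (reported to 1e-4 of g); the
  printed optima are stable to well below the reporting precision.
* Frequency-maximum ties broken toward smaller g, all ties reported.
* `min_triplets` post-verifies the ceiling by the defining inequality.
* Degenerate inputs raise typed errors (`UnknownCodeError`,
  `SignalAbsentError`, `StopSignalUnreachableError`, `LayoutError`) rather
  than returning sentinel values.

## Known limitations

* The even-split weights for ambiguous codons are a modelling convention;
  real readthrough ratios are context-dependent and not 1/k.
* The geometric stop-spacing model ignores overlap between frames and any
  selection against stops in real coding sequence.
* The miner's per-intron denominators count transcripts' introns, not
  unique intron loci.
* In the rhabdopleuridae mitochondrial table AUA remains Ile, so Met keeps a
  single codon there — the one exception to the "every amino acid has ≥ 2
  codons" pattern of the AGR-repurposing mitochondrial codes.
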