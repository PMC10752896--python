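"""Minimum sequence length for a stop signal to appear by chance.

Consecutive triplets of pseudo-random sequence are independent, so the wait
for the first stop signal is geometric.  The script prints, for several GC
contents and codes, the smallest number of triplets that contains at least
one stop signal with 95% probability — the scale on which stop-to-stop ORFs
delimit random sequence.
"""

from codongc import load_code, min_triplets, stop_probability

standard = load_code(1)
print("standard code, p = 0.95:")
for g in (0.148, 0.30, 0.50, 0.703):
    c = min_triplets(standard, g, 0.95)
    print(f"  GC {g * 100:5.1f}%  P(stop/triplet) = {stop_probability(standard, g):.4f}"
          f"  ->  {c:4d} triplets ({3 * c} nt)")

print()
print("alternative codes at 50% GC, p = 0.95:")
for name in ("Thraustochytrium Mitochondrial", "Standard", "Karyorelict Nuclear"):
    code = load_code(name)
    print(f"  {name:<32} {min_triplets(code, 0.5, 0.95):4d} triplets")

print()
print("An extra stop codon (UUA) shortens the 95% length to 47 triplets; a")
print("stop codon shared with Trp (karyorelict UGA at weight 1/2) stretches")
print("it to 382. Typical introns are far longer, so in-frame stop signals")
print("are effectively guaranteed inside them.")
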