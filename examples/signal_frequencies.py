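"""Expected amino-acid and stop-signal frequencies vs GC for the standard code.

Builds the exact frequency polynomial of each signal, prints its closed-form
coefficients, its value at 50% GC, and the GC content where it peaks.  The
frequencies are expectations for i.i.d. (pseudo-random) sequence at the given
GC content — a model for high-complexity coding or unselected non-coding DNA.
"""

from fractions import Fraction

from codongc import SIGNALS, frequency_maximum, load_code, signal_polynomial

code = load_code("Standard")
print(f"{'signal':>6} {'polynomial (c0 + c1 g + c2 g^2 + c3 g^3)':>42} "
      f"{'at g=0.5':>9} {'argmax g':>9} {'max':>8}")
for signal in SIGNALS:
    poly = signal_polynomial(code, signal)
    peak = frequency_maximum(code, signal)
    coeffs = ", ".join(str(c) for c in poly.coefficients)
    print(f"{signal:>6} {coeffs:>42} {float(poly(Fraction(1, 2))):>9.5f} "
          f"{peak.argmax:>9.4f} {peak.value:>8.4f}")

print()
print("Reading: Ser peaks at 9.375% of triplets at 50% GC; Met and Trp, the")
print("single-codon amino acids, peak at 1.85% at one-third and two-thirds GC;")
print("the stop signal is most frequent (12.5%) in pure-AT sequence.")
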