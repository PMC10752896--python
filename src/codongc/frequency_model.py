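"""Expected signal frequencies in pseudo-random sequences as polynomials in GC.

The sequence model is i.i.d. nucleotides constrained only by the GC content
``g`` and Chargaff's second parity rule (zero GC and AT skew within a
strand), so

    P(G) = P(C) = g / 2,        P(A) = P(U) = (1 - g) / 2.

A codon's probability is the product of its three base probabilities, and a
signal's expected frequency is the weight-summed probability of its codons —
a polynomial in ``g`` of degree at most 3 whose coefficients are exact
rationals.  For the standard code, e.g.

    P_Stop(g) = (1 - g - g^2 + g^3) / 8,
    P_Ser(g)  = 3 g (1 - g) / 8,
    P_Lys(g)  = (1 - g)^2 / 8.

Coefficients are kept as :class:`fractions.Fraction` and converted to float
only at evaluation, so symbolic identities hold exactly.  Maxima of the
cubics over g ∈ [0, 1] are found in closed form from the derivative's roots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Union

import numpy as np

from .genetic_codes import (
    CODONS,
    GeneticCode,
    normalize_codon,
    normalize_signal,
)

__all__ = [
    "SignalFrequencyPolynomial",
    "SignalAbsentError",
    "FrequencyMaximum",
    "base_probability",
    "codon_probability",
    "codon_probability_polynomial",
    "signal_polynomial",
    "signal_frequency",
    "frequency_maximum",
]

Number = Union[float, Fraction]

_HALF = Fraction(1, 2)
# per-base probability as (c0, c1) of c0 + c1*g
_BASE_LINE = {
    "G": (Fraction(0), _HALF),
    "C": (Fraction(0), _HALF),
    "A": (_HALF, -_HALF),
    "U": (_HALF, -_HALF),
}


class SignalAbsentError(ValueError):
    """Raised when a signal carries no weight anywhere in a genetic code."""


def base_probability(base: str, g: Number) -> Number:
    """Probability of one nucleotide at GC content ``g``: g/2 for G/C, (1-g)/2 for A/U."""
    if not isinstance(base, str) or len(base) != 1:
        raise ValueError(f"invalid base {base!r}")
    b = base.upper().replace("T", "U")
    if b not in _BASE_LINE:
        raise ValueError(f"invalid base {base!r}: expected one of A, C, G, T/U")
    _check_gc(g)
    c0, c1 = _BASE_LINE[b]
    if isinstance(g, Fraction):
        return c0 + c1 * g
    return float(c0) + float(c1) * g


def _check_gc(g: Number) -> None:
    if not 0 <= g <= 1:
        raise ValueError(f"GC content must lie in [0, 1], got {g}")


@dataclass(frozen=True)
class SignalFrequencyPolynomial:
    """Exact polynomial c0 + c1·g + c2·g² + c3·g³ for one signal's expected frequency."""

    signal: str
    code_id: int
    coefficients: tuple[Fraction, Fraction, Fraction, Fraction]

    def __call__(self, g):
        """Evaluate at ``g`` (float, Fraction, or ndarray; Fractions stay exact)."""
        c0, c1, c2, c3 = self.coefficients
        if isinstance(g, Fraction):
            return c0 + c1 * g + c2 * g**2 + c3 * g**3
        g = np.asarray(g, dtype=float) if not np.isscalar(g) else g
        out = float(c0) + g * (float(c1) + g * (float(c2) + g * float(c3)))
        return out

    @property
    def degree(self) -> int:
        return max((i for i, c in enumerate(self.coefficients) if c != 0), default=0)

    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coefficients)

    def derivative_coefficients(self) -> tuple[Fraction, Fraction, Fraction]:
        c0, c1, c2, c3 = self.coefficients
        return (c1, 2 * c2, 3 * c3)


def codon_probability_polynomial(codon: str) -> tuple[Fraction, ...]:
    """Exact (c0, c1, c2, c3) of the codon-probability polynomial in g."""
    rna = normalize_codon(codon)
    coeffs = [Fraction(1)]
    for base in rna:
        line = _BASE_LINE[base]
        nxt = [Fraction(0)] * (len(coeffs) + 1)
        for i, c in enumerate(coeffs):
            nxt[i] += c * line[0]
            nxt[i + 1] += c * line[1]
        coeffs = nxt
    coeffs += [Fraction(0)] * (4 - len(coeffs))
    return tuple(coeffs)


def codon_probability(codon: str, g: Number) -> Number:
    """Probability of a codon at GC content ``g`` (product over its three bases)."""
    rna = normalize_codon(codon)
    _check_gc(g)
    p: Number = Fraction(1) if isinstance(g, Fraction) else 1.0
    for base in rna:
        p = p * base_probability(base, g)
    return p


def signal_polynomial(code: GeneticCode, signal: str) -> SignalFrequencyPolynomial:
    """Weighted sum over all 64 codons of codon-probability polynomials.

    A signal absent from the code yields the zero polynomial.
    """
    label = normalize_signal(signal)
    total = [Fraction(0)] * 4
    for codon in CODONS:
        weight = code.weights[codon].get(label)
        if weight:
            for i, c in enumerate(codon_probability_polynomial(codon)):
                total[i] += weight * c
    return SignalFrequencyPolynomial(
        signal=label, code_id=code.code_id, coefficients=tuple(total)
    )


def signal_frequency(code: GeneticCode, signal: str, g: Number) -> Number:
    """Expected frequency of ``signal`` at GC content ``g`` under ``code``."""
    _check_gc(g)
    return signal_polynomial(code, signal)(g)


class FrequencyMaximum(NamedTuple):
    """Global maximum of a signal-frequency polynomial on g ∈ [0, 1].

    ``argmax`` is the smallest maximizing g; ``argmaxima`` lists every tying
    maximizer in increasing order.
    """

    argmax: float
    value: float
    argmaxima: tuple[float, ...]


def _stationary_points(poly: SignalFrequencyPolynomial) -> list[float]:
    d1, d2, d3 = poly.derivative_coefficients()
    pts: list[float] = []
    if d3 != 0:
        disc = d2 * d2 - 4 * d3 * d1
        if disc >= 0:
            root = math.sqrt(float(disc))
            for r in ((-float(d2) + root) / (2 * float(d3)),
                      (-float(d2) - root) / (2 * float(d3))):
                if 0.0 < r < 1.0:
                    pts.append(r)
    elif d2 != 0:
        r = -d1 / d2
        if 0 < r < 1:
            pts.append(float(r))
    return pts


def frequency_maximum(code: GeneticCode, signal: str) -> FrequencyMaximum:
    """Closed-form global maximum of a signal's frequency polynomial on [0, 1].

    Candidates are the interval endpoints plus the real stationary points of
    the cubic; ties (to 1e-12) are reported with all tying arguments and the
    smallest one as ``argmax``.

    Raises
    ------
    SignalAbsentError
        If the signal carries no weight anywhere in the code.
    """
    poly = signal_polynomial(code, signal)
    if poly.is_zero():
        raise SignalAbsentError(
            f"signal {normalize_signal(signal)!r} is absent from code "
            f"{code.code_id} ({code.name})"
        )
    candidates = [0.0, 1.0] + _stationary_points(poly)
    values = [float(poly(g)) for g in candidates]
    best = max(values)
    ties = sorted(g for g, v in zip(candidates, values) if best - v <= 1e-12)
    return FrequencyMaximum(argmax=ties[0], value=best, argmaxima=tuple(ties))
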