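"""Stop-signal run-length statistics for the stop-to-stop ORF definition.

Consecutive triplets of a pseudo-random sequence are independent, so the
number of triplets up to the first stop signal is geometric with per-triplet
success probability P_stop(g) (the code's stop-frequency polynomial).  Hence

    p(c, g) = 1 - (1 - P_stop(g))^c

is the probability that a stretch of c triplets contains at least one stop
signal, and the minimum c reaching a target probability p is the ceiling of

    c(p, g) = log(1 - p) / log(1 - P_stop(g)).

As GC tends to a point where P_stop vanishes (e.g. the standard code at
g = 1), the logarithm in the denominator tends to zero and the required
length diverges; that case raises :class:`StopSignalUnreachableError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .frequency_model import SignalFrequencyPolynomial, signal_polynomial
from .genetic_codes import STOP, GeneticCode

__all__ = [
    "OrfStopStatistics",
    "StopSignalUnreachableError",
    "stop_probability",
    "prob_at_least_one_stop",
    "min_triplets",
    "orf_stop_statistics",
]


class StopSignalUnreachableError(ValueError):
    """Raised when the per-triplet stop probability is zero, so no finite
    triplet count can reach the target probability."""


def _stop_poly(code: GeneticCode) -> SignalFrequencyPolynomial:
    return signal_polynomial(code, STOP)


def stop_probability(code: GeneticCode, g: float) -> float:
    """Per-triplet stop-signal probability at GC content ``g``."""
    if not 0 <= g <= 1:
        raise ValueError(f"GC content must lie in [0, 1], got {g}")
    return float(_stop_poly(code)(g))


def prob_at_least_one_stop(code: GeneticCode, g: float, c: int) -> float:
    """Probability that ``c`` consecutive triplets contain at least one stop.

    ``c = 0`` (the empty sequence) has probability 0.
    """
    if not isinstance(c, int) or isinstance(c, bool):
        raise TypeError(f"triplet count must be an integer, got {c!r}")
    if c < 0:
        raise ValueError(f"triplet count must be nonnegative, got {c}")
    p_stop = stop_probability(code, g)
    return 1.0 - (1.0 - p_stop) ** c


def min_triplets(code: GeneticCode, g: float, p: float = 0.95) -> int:
    """Smallest triplet count whose stop-containment probability reaches ``p``.

    Computed as the ceiling of log(1-p)/log(1-P_stop(g)), then verified
    against the defining inequality to guard the exact-integer edge case.

    Raises
    ------
    StopSignalUnreachableError
        If the code's stop probability vanishes at this GC content.
    """
    if not 0 < p < 1:
        raise ValueError(f"target probability must lie strictly in (0, 1), got {p}")
    p_stop = stop_probability(code, g)
    if p_stop <= 0.0:
        raise StopSignalUnreachableError(
            f"code {code.code_id} ({code.name}) has zero stop probability at "
            f"g={g}; no finite length reaches p={p}"
        )
    c = math.ceil(math.log(1.0 - p) / math.log(1.0 - p_stop))
    # guard float round-off on either side of the ceiling
    while c > 0 and prob_at_least_one_stop(code, g, c - 1) >= p:
        c -= 1
    while prob_at_least_one_stop(code, g, c) < p:
        c += 1
    return c


@dataclass(frozen=True)
class OrfStopStatistics:
    """Stop-signal statistics for a stretch of ``c`` triplets at GC ``g``."""

    code_id: int
    g: float
    p_stop_per_triplet: float
    c: int
    p_at_least_one: float


def orf_stop_statistics(code: GeneticCode, g: float, c: int) -> OrfStopStatistics:
    """Bundle per-triplet and run-length stop probabilities for ``c`` triplets."""
    return OrfStopStatistics(
        code_id=code.code_id,
        g=float(g),
        p_stop_per_triplet=stop_probability(code, g),
        c=c,
        p_at_least_one=prob_at_least_one_stop(code, g, c),
    )
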