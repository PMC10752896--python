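"""The 25 NCBI genetic codes as weighted codon-to-signal assignments.

A *signal* is one of the 20 canonical amino acids or translation STOP — the
21 outcomes a codon can encode.  Most codons map to a single signal, but a
handful of alternative codes assign one codon to several signals (e.g. the
karyorelict nuclear UGA, read as both STOP and Trp).  Following the even-split
convention, such a codon distributes its frequency uniformly over its k
signals at weight 1/k, kept as exact :class:`fractions.Fraction` values so
downstream polynomial algebra stays exact.

Codons are stored in the RNA alphabet (A, C, G, U); DNA input is
transliterated T→U at the boundary.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from types import MappingProxyType
from typing import Iterable, Mapping

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "SIGNALS",
    "GeneticCode",
    "UnknownCodeError",
    "available_codes",
    "load_code",
    "stop_weight",
]

#: Canonical three-letter amino-acid labels, alphabetical.
AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: Label of the translation-stop signal.
STOP = "STOP"

#: All 21 signals a codon can encode.
SIGNALS: tuple[str, ...] = AMINO_ACIDS + (STOP,)

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": STOP,
}

#: All 64 RNA codons in NCBI order (first base slowest; bases U, C, A, G).
CODONS: tuple[str, ...] = tuple(
    "".join(bases) for bases in itertools.product("UCAG", repeat=3)
)

_RNA_BASES = frozenset("ACGU")
_DATA_FILE = "translation_tables.tsv"


class UnknownCodeError(KeyError):
    """Raised when a translation-table identifier is not one of the 25 bundled codes."""


def normalize_codon(codon: str) -> str:
    """Return ``codon`` uppercased in the RNA alphabet; reject malformed input.

    Accepts DNA (T) or RNA (U) spelling.
    """
    if not isinstance(codon, str):
        raise TypeError(f"codon must be a string, got {type(codon).__name__}")
    rna = codon.upper().replace("T", "U")
    if len(rna) != 3 or not set(rna) <= _RNA_BASES:
        raise ValueError(f"malformed codon {codon!r}: expected a triplet over ACGT/ACGU")
    return rna


def normalize_signal(signal: str) -> str:
    """Map a one- or three-letter amino-acid code (or STOP/'*') to its canonical label."""
    if signal in SIGNALS:
        return signal
    key = signal.upper() if len(signal) <= 1 else signal.capitalize()
    if key in _ONE_TO_THREE:
        return _ONE_TO_THREE[key]
    if key == "Stop":
        return STOP
    raise ValueError(f"unknown signal {signal!r}; expected one of {SIGNALS}")


@dataclass(frozen=True)
class GeneticCode:
    """A weighted codon→signal mapping for one NCBI translation table.

    ``weights[codon]`` maps each encoded signal to its weight; weights over a
    codon always sum to exactly 1.  Unambiguous codons carry a single signal
    at weight 1; ambiguous codons split evenly (1/k over k signals).
    """

    code_id: int
    name: str
    weights: Mapping[str, Mapping[str, Fraction]]
    start_codons: tuple[str, ...] = field(default=(), compare=False)

    def signal_weights(self, codon: str) -> Mapping[str, Fraction]:
        """Weight mapping for one codon (DNA or RNA spelling)."""
        return self.weights[normalize_codon(codon)]

    def stop_weight(self, codon: str) -> Fraction:
        """STOP component of the codon's weight mapping (0 if none)."""
        return self.signal_weights(codon).get(STOP, Fraction(0))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        """Codons with positive STOP weight, in NCBI codon order."""
        return tuple(c for c in CODONS if STOP in self.weights[c])

    def codons_for(self, signal: str) -> tuple[str, ...]:
        """Codons carrying positive weight for ``signal``, in NCBI codon order."""
        label = normalize_signal(signal)
        return tuple(c for c in CODONS if label in self.weights[c])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode(code_id={self.code_id}, name={self.name!r})"


def _read_table_file() -> dict[int, dict]:
    raw: dict[int, dict] = {}
    path = resources.files("codongc.data").joinpath(_DATA_FILE)
    with path.open("r", encoding="utf-8") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    for rec in csv.DictReader(rows, delimiter="\t"):
        code_id = int(rec["code_id"])
        aa = rec["amino_acids"]
        if len(aa) != 64:
            raise ValueError(
                f"table {code_id}: expected 64 codon assignments, got {len(aa)}"
            )
        overrides: dict[str, tuple[str, ...]] = {}
        if rec["ambiguities"]:
            for item in rec["ambiguities"].split(";"):
                codon, sigs = item.split("=")
                overrides[codon] = tuple(
                    normalize_signal(s) for s in sigs.split("|")
                )
        raw[code_id] = {
            "name": rec["name"],
            "amino_acids": aa,
            "start_codons": tuple(rec["start_codons"].split(",")) if rec["start_codons"] else (),
            "ambiguities": overrides,
        }
    return raw


_RAW_TABLES: dict[int, dict] | None = None


def _raw_tables() -> dict[int, dict]:
    global _RAW_TABLES
    if _RAW_TABLES is None:
        _RAW_TABLES = _read_table_file()
    return _RAW_TABLES


def available_codes() -> dict[int, str]:
    """Mapping of bundled translation-table identifiers to display names."""
    return {cid: rec["name"] for cid, rec in sorted(_raw_tables().items())}


def _resolve_code_id(code_id: int | str) -> int:
    tables = _raw_tables()
    if isinstance(code_id, int) and not isinstance(code_id, bool):
        if code_id in tables:
            return code_id
    elif isinstance(code_id, str):
        if code_id.strip().isdigit() and int(code_id) in tables:
            return int(code_id)
        wanted = code_id.strip().lower()
        for cid, rec in tables.items():
            if rec["name"].lower() == wanted:
                return cid
        # forgiving match: ignore punctuation differences in display names
        simple = "".join(ch for ch in wanted if ch.isalnum())
        for cid, rec in tables.items():
            if "".join(ch for ch in rec["name"].lower() if ch.isalnum()) == simple:
                return cid
    valid = ", ".join(f"{cid} ({name})" for cid, name in available_codes().items())
    raise UnknownCodeError(
        f"unknown genetic code {code_id!r}; valid identifiers: {valid}"
    )


def load_code(code_id: int | str) -> GeneticCode:
    """Load one of the 25 bundled NCBI genetic codes.

    Parameters
    ----------
    code_id
        NCBI translation-table number (e.g. ``1``) or display name
        (case-insensitive, e.g. ``"Karyorelict Nuclear"``).

    Raises
    ------
    UnknownCodeError
        If ``code_id`` does not name a bundled table.
    """
    cid = _resolve_code_id(code_id)
    rec = _raw_tables()[cid]
    weights: dict[str, Mapping[str, Fraction]] = {}
    for codon, letter in zip(CODONS, rec["amino_acids"]):
        signals = rec["ambiguities"].get(codon) or (normalize_signal(letter),)
        share = Fraction(1, len(signals))
        weights[codon] = MappingProxyType({s: share for s in signals})
    return GeneticCode(
        code_id=cid,
        name=rec["name"],
        weights=MappingProxyType(weights),
        start_codons=rec["start_codons"],
    )


def stop_weight(code: GeneticCode, codon: str) -> Fraction:
    """STOP weight of ``codon`` under ``code`` (0 if the codon never terminates)."""
    return code.stop_weight(codon)


def iter_codes() -> Iterable[GeneticCode]:
    """Iterate over all 25 bundled genetic codes in table-number order."""
    for cid in sorted(_raw_tables()):
        yield load_code(cid)
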