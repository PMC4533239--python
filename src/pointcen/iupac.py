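"""IUPAC degenerate nucleotide alphabet: base sets, complements, match tables.

Shared by the synthetic generator (element sampling), the consensus builder
(degenerate consensus emission) and the genome scanner (set-aware matching).
"""

from __future__ import annotations

import numpy as np

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: base set -> IUPAC code (inverse of IUPAC_SETS).
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

#: code-level complement (covers all degenerate codes, e.g. R<->Y, S<->S).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: order used for integer encoding of sequences (N last).
BASES = "ACGT"
_ALPHABET = "ACGTN"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def is_iupac(pattern: str) -> bool:
    """True iff every character of ``pattern`` is an IUPAC nucleotide code."""
    return len(pattern) > 0 and all(c.upper() in IUPAC_SETS for c in pattern)


def validate_pattern(pattern: str) -> str:
    """Uppercase ``pattern`` after checking it is a non-empty IUPAC string."""
    if not is_iupac(pattern):
        raise ValueError(f"not a valid IUPAC pattern: {pattern!r}")
    return pattern.upper()


def code_for_bases(bases) -> str:
    """IUPAC code for a set of concrete bases; the empty set maps to 'N'."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        return "N"
    try:
        return CODE_FOR_SET[key]
    except KeyError:
        raise ValueError(f"not a nucleotide base set: {sorted(key)}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None


def encode(seq: str) -> np.ndarray:
    """Encode a sequence over A/C/G/T/N as uint8 codes 0..4 (case-insensitive)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


def match_table(pattern: str) -> np.ndarray:
    """Boolean table ``t[j, b]``: does encoded base ``b`` satisfy pattern column j.

    A sequence 'N' (code 4) satisfies only a pattern 'N', so an undetermined
    genome position never silently matches a constrained motif column.
    """
    pattern = validate_pattern(pattern)
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, code in enumerate(pattern):
        for base in IUPAC_SETS[code]:
            table[j, BASES.index(base)] = True
        table[j, 4] = code == "N"
    return table
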