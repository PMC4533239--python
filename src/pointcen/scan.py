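"""Degenerate-motif scanning, uniqueness reporting and window mutations.

Matching is set-aware: a window position counts as a mismatch when its base
falls outside the IUPAC code's base set, so mismatch counting is meaningful
against degenerate columns.  Long patterns (e.g. a 70-bp consensus core) are
scanned by per-window set comparison rather than by expanding the pattern,
whose concrete expansion count is astronomically large.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .iupac import encode, match_table, reverse_complement, validate_pattern

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegenerateMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_pattern(self.pattern))

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MutationSpec:
    """A block substitution in 1-based centromere-window coordinates."""

    start: int
    end: int
    base: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid mutation span {self.start}-{self.end}")
        if self.base.lower() not in "acgt":
            raise ValueError(f"invalid mutation base {self.base!r}")
        object.__setattr__(self, "base", self.base.lower())

    @property
    def name(self) -> str:
        return f"{self.start}-{self.end}{self.base}"


@dataclass(frozen=True)
class MotifHit:
    chromosome: str
    position: int  # 1-based forward-strand start of the match window
    strand: str  # "+" | "-"
    mismatches: int


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base lies in the pattern column's base set.

    The window may contain 'N', which matches only a pattern 'N'.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    table = match_table(pattern)
    enc = encode(window)
    return bool(table[np.arange(len(pattern)), enc].all())


def _mismatch_profile(enc: np.ndarray, pattern: str) -> np.ndarray:
    """Set-aware Hamming mismatches of every window of len(pattern) in enc."""
    m = len(pattern)
    n = enc.size - m + 1
    table = match_table(pattern)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(m):
        mism += ~table[j, enc[j : j + n]]
    return mism


def scan_genome(
    genome: Mapping[str, str],
    motif: DegenerateMotif,
    max_mismatch: int = 0,
    strands: str = "both",
) -> list[MotifHit]:
    """All motif occurrences with at most ``max_mismatch`` set-aware mismatches.

    Reverse-strand hits are located by scanning the reverse-complemented
    pattern on the forward strand and are reported at the forward coordinate
    of the window start.  Overlapping hits are all reported; a palindromic
    locus yields one hit per strand.
    """
    if not genome:
        raise ValueError("empty genome")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    patterns = [(motif.pattern, "+")]
    if strands == "both":
        patterns.append((reverse_complement(motif.pattern), "-"))

    hits: list[MotifHit] = []
    any_scanned = False
    for chrom in sorted(genome):
        enc = encode(genome[chrom])
        if enc.size < len(motif):
            continue
        any_scanned = True
        for pattern, strand in patterns:
            mism = _mismatch_profile(enc, pattern)
            for pos in np.flatnonzero(mism <= max_mismatch):
                hits.append(
                    MotifHit(chrom, int(pos) + 1, strand, int(mism[pos]))
                )
    if not any_scanned:
        log.warning(
            "pattern %s longer than every chromosome; no windows scanned",
            motif.name,
        )
    hits.sort(key=lambda h: (h.chromosome, h.position, h.strand))
    return hits


@dataclass
class UniquenessReport:
    at_centromere: int
    elsewhere: int
    assignments: list[tuple[MotifHit, bool]]  # (hit, is_at_centromere)


def uniqueness_report(
    hits: Sequence[MotifHit],
    centromere_intervals: Mapping[str, Sequence[tuple[int, int]]],
    motif_length: int,
) -> UniquenessReport:
    """Partition hits by whether the match window intersects a centromere.

    Intervals are 0-based half-open genome coordinates.
    """
    assignments = []
    at_cen = 0
    for hit in hits:
        w_start = hit.position - 1
        w_end = w_start + motif_length
        inside = any(
            w_start < e and s < w_end
            for s, e in centromere_intervals.get(hit.chromosome, ())
        )
        at_cen += inside
        assignments.append((hit, inside))
    return UniquenessReport(at_cen, len(hits) - at_cen, assignments)


def apply_mutation(window: str, spec: MutationSpec) -> str:
    """Replace window columns spec.start..spec.end (1-based) with spec.base."""
    if spec.end > len(window):
        raise ValueError(
            f"mutation {spec.name} out of range for {len(window)}-bp window"
        )
    n = spec.end - spec.start + 1
    return window[: spec.start - 1] + spec.base.upper() * n + window[spec.end :]


_MUTATION_RE = re.compile(r"^(\d+)[-–](\d+)([acgtACGT])$")


def parse_mutation_spec(text: str) -> MutationSpec:
    """Parse mutation names like '21-23a' (hyphen or en-dash, any base case)."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed mutation spec: {text!r}")
    start, end, base = int(m.group(1)), int(m.group(2)), m.group(3)
    if start > end:
        raise ValueError(f"mutation spec start > end: {text!r}")
    return MutationSpec(start, end, base)
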