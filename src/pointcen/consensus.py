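"""Ungapped alignment, position-frequency matrix and consensus annotation.

Point-centromere elements sit at fixed spacings, so candidate sequences are
aligned without gaps: each sequence gets one integer offset and contributes a
fixed-length window to the alignment.  Columns of the resulting position
frequency matrix (PFM) are classified by conservation:

* ``invariant`` - one base in 100% of sequences,
* ``high``      - one base in 80-90% of sequences (inclusive at both ends),
* ``at_only``   - only A and T observed,
* ``gc_rich``   - G+C in at least 80% of sequences,
* ``unclassified`` otherwise,

with precedence invariant > high > at_only > gc_rich.  Conserved elements are
maximal invariant/high runs of at least ``element_min_len`` columns; the
consensus core spans the first to the last classified column, counting only
classified columns that sit in runs of at least ``core_min_run`` so isolated
chance-conserved columns do not inflate the core.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .iupac import BASES, code_for_bases, encode

log = logging.getLogger(__name__)

EXACT_SEARCH_LIMIT = 1_000_000

Classes = Sequence[str]
CLASS_NAMES = ("invariant", "high", "at_only", "gc_rich", "unclassified")


@dataclass(frozen=True)
class UngappedAlignment:
    """One window offset per sequence (0-based into the source sequence)."""

    offsets: tuple[int, ...]
    window_length: int


@dataclass
class PositionFrequencyMatrix:
    """Per-column base counts; rows ordered A, C, G, T."""

    counts: np.ndarray  # shape (4, width), non-negative ints
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, width)")
        if self.n_sequences > 0 and not np.all(
            self.counts.sum(axis=0) == self.n_sequences
        ):
            raise ValueError("column sums must equal n_sequences")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def fractions(self) -> np.ndarray:
        if self.n_sequences == 0:
            raise ValueError("empty PFM has no fractions")
        return self.counts / self.n_sequences


@dataclass(frozen=True)
class ClassifyThresholds:
    invariant_min: float = 1.0
    high_min: float = 0.80
    high_max: float = 0.90
    gc_rich_min: float = 0.80
    element_min_len: int = 5
    core_min_run: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.high_min <= self.high_max < self.invariant_min <= 1:
            raise ValueError("need 0 < high_min <= high_max < invariant_min <= 1")
        if self.element_min_len < 1 or self.core_min_run < 1:
            raise ValueError("run lengths must be positive")


@dataclass(frozen=True)
class ConsensusElement:
    start: int  # 1-based inclusive alignment column
    end: int
    pattern: str


@dataclass
class ConsensusAnnotation:
    classes: list[str]
    degenerate: str
    elements: list[ConsensusElement]
    core: Optional[tuple[int, int]]  # 1-based inclusive, None if undefined

    @property
    def core_length(self) -> Optional[int]:
        if self.core is None:
            return None
        return self.core[1] - self.core[0] + 1


# ---------------------------------------------------------------------------
# alignment


def _window_matrix(encoded: list[np.ndarray], offsets, window: int) -> np.ndarray:
    return np.stack([s[o : o + window] for s, o in zip(encoded, offsets)])


def _consensus_score(block: np.ndarray) -> int:
    """Sum over columns of the count of the most frequent base."""
    counts = np.stack([(block == b).sum(axis=0) for b in range(4)])
    return int(counts.max(axis=0).sum())


def anchor_align(
    sequences: Sequence[tuple[str, str]], window_length: int
) -> UngappedAlignment:
    """Choose per-sequence offsets maximizing the column-consensus score.

    When the product of offset choices is small the optimum is found by exact
    enumeration (ties broken toward the lexicographically smallest offset
    vector).  Otherwise a deterministic multi-restart refinement is used: one
    centered start plus one start anchored on each sequence's centered window,
    each refined by align-to-profile coordinate ascent with global-shift
    moves; the best-scoring final alignment wins.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    names = [n for n, _ in sequences]
    if len(set(names)) != len(names):
        raise ValueError("sequence names must be unique")
    encoded = []
    for name, seq in sequences:
        if len(seq) < window_length:
            raise ValueError(
                f"sequence {name!r} shorter than window ({len(seq)} < {window_length})"
            )
        encoded.append(encode(seq))
    choices = [len(s) - window_length + 1 for s in encoded]

    if math.prod(choices) <= EXACT_SEARCH_LIMIT:
        best_score, best_offsets = -1, None
        for offsets in itertools.product(*(range(c) for c in choices)):
            score = _consensus_score(_window_matrix(encoded, offsets, window_length))
            if score > best_score:  # lex-smallest wins ties by iteration order
                best_score, best_offsets = score, offsets
        return UngappedAlignment(tuple(best_offsets), window_length)

    best: Optional[tuple[int, list[int]]] = None
    for init in _refinement_inits(encoded, choices, window_length):
        offsets, score = _refine_offsets(encoded, init, choices, window_length)
        if best is None or score > best[0] or (score == best[0] and offsets < best[1]):
            best = (score, offsets)
    return UngappedAlignment(tuple(int(o) for o in best[1]), window_length)


def _anchor_match_counts(enc_seq: np.ndarray, ref_window: np.ndarray) -> np.ndarray:
    """Match counts of every window of enc_seq against one fixed window."""
    sw = np.lib.stride_tricks.sliding_window_view(enc_seq, ref_window.size)
    return (sw == ref_window).sum(axis=1)


def _refinement_inits(encoded, choices, window):
    """Deterministic starting offset vectors: centered, plus one per anchor.

    Anchored starts initialize every sequence at its best match against the
    anchor sequence's centered window; multiple restarts let refinement escape
    poor local optima when sequences share only a short conserved region.
    """
    yield [int(c - 1) // 2 for c in choices]
    for k in range(len(encoded)):
        ck = (choices[k] - 1) // 2
        ref = encoded[k][ck : ck + window]
        init = [int(np.argmax(_anchor_match_counts(e, ref))) for e in encoded]
        init[k] = ck
        yield init


def _refine_offsets(encoded, offsets, choices, window):
    """Coordinate ascent on the consensus score plus global-shift moves.

    Per-sequence moves realign one window against the profile of the others;
    the global shift handles the translation ridge a single-sequence move
    cannot cross.  Deterministic: leftmost offset wins ties.
    """
    cols = np.arange(window)
    counts = np.zeros((4, window), dtype=np.int64)
    for s, o in zip(encoded, offsets):
        np.add.at(counts, (s[o : o + window], cols), 1)

    for _ in range(100):
        changed = False
        for i, seq in enumerate(encoded):
            win = seq[offsets[i] : offsets[i] + window]
            np.add.at(counts, (win, cols), -1)
            sw = np.lib.stride_tricks.sliding_window_view(seq, window)
            scores = counts[sw, cols].sum(axis=1)
            best_o = int(np.argmax(scores))
            if best_o != offsets[i]:
                offsets[i] = best_o
                changed = True
            win = seq[offsets[i] : offsets[i] + window]
            np.add.at(counts, (win, cols), 1)

        cur = _consensus_score(_window_matrix(encoded, offsets, window))
        lo = -min(offsets)
        hi = min(c - 1 - o for c, o in zip(choices, offsets))
        best_d = 0
        for d in range(lo, hi + 1):
            if d == 0:
                continue
            s = _consensus_score(
                _window_matrix(encoded, [o + d for o in offsets], window)
            )
            if s > cur:
                cur, best_d = s, d
        if best_d:
            offsets = [o + best_d for o in offsets]
            counts = np.zeros((4, window), dtype=np.int64)
            for s_, o in zip(encoded, offsets):
                np.add.at(counts, (s_[o : o + window], cols), 1)
            changed = True
        if not changed:
            break
    return offsets, _consensus_score(_window_matrix(encoded, offsets, window))


def build_pfm(
    sequences: Sequence[tuple[str, str]], alignment: UngappedAlignment
) -> PositionFrequencyMatrix:
    """Count bases per alignment column; errors on non-ACGT inside a window."""
    if len(alignment.offsets) != len(sequences):
        raise ValueError("alignment does not match sequence set")
    counts = np.zeros((4, alignment.window_length), dtype=np.int64)
    for (name, seq), offset in zip(sequences, alignment.offsets):
        if offset < 0 or offset + alignment.window_length > len(seq):
            raise ValueError(f"offset out of range for sequence {name!r}")
        win = encode(seq[offset : offset + alignment.window_length])
        if (win > 3).any():
            raise ValueError(f"non-ACGT base inside aligned window of {name!r}")
        np.add.at(counts, (win, np.arange(alignment.window_length)), 1)
    return PositionFrequencyMatrix(counts, len(sequences))


# ---------------------------------------------------------------------------
# classification and consensus


def classify_positions(
    pfm: PositionFrequencyMatrix, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> list[str]:
    """Assign each column exactly one conservation class (see module docs)."""
    frac = pfm.fractions()
    max_frac = frac.max(axis=0)
    a, c, g, t = pfm.counts
    gc_frac = frac[1] + frac[2]
    classes = []
    for j in range(pfm.width):
        if max_frac[j] >= thresholds.invariant_min:
            cls = "invariant"
        elif thresholds.high_min <= max_frac[j] <= thresholds.high_max:
            cls = "high"
        elif c[j] == 0 and g[j] == 0:
            cls = "at_only"
        elif gc_frac[j] >= thresholds.gc_rich_min:
            cls = "gc_rich"
        else:
            cls = "unclassified"
        classes.append(cls)
    return classes


def derive_degenerate_consensus(
    pfm: PositionFrequencyMatrix, include_min: float = 0.15
) -> str:
    """Per column, the IUPAC code of {bases with frequency >= include_min}.

    With ten sequences and the default 0.15 a base needs two occurrences to
    enter the code, which suppresses singleton noise while keeping genuine
    two-fold degeneracies.  An empty base set yields 'N'.
    """
    if not 0 < include_min < 1:
        raise ValueError("include_min must lie in (0, 1)")
    frac = pfm.fractions()
    out = []
    for j in range(pfm.width):
        bases = {BASES[b] for b in range(4) if frac[b, j] >= include_min}
        out.append(code_for_bases(bases))
    return "".join(out)


def _runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal [start, end] 0-based inclusive runs of True."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def annotate_consensus(
    pfm: PositionFrequencyMatrix,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    include_min: float = 0.15,
) -> ConsensusAnnotation:
    """Classify columns, emit the degenerate consensus, elements and core."""
    classes = classify_positions(pfm, thresholds)
    degenerate = derive_degenerate_consensus(pfm, include_min)

    conserved = [cls in ("invariant", "high") for cls in classes]
    elements = [
        ConsensusElement(s + 1, e + 1, degenerate[s : e + 1])
        for s, e in _runs(conserved)
        if e - s + 1 >= thresholds.element_min_len
    ]

    classified = [cls != "unclassified" for cls in classes]
    core_runs = [
        (s, e)
        for s, e in _runs(classified)
        if e - s + 1 >= thresholds.core_min_run
    ]
    if core_runs:
        core = (core_runs[0][0] + 1, core_runs[-1][1] + 1)
    else:
        core = None
        log.warning("no classified columns; consensus core undefined")
    return ConsensusAnnotation(classes, degenerate, elements, core)


def merge_consensus(
    pfm_a: PositionFrequencyMatrix, pfm_b: PositionFrequencyMatrix
) -> PositionFrequencyMatrix:
    """Element-wise count addition of two PFMs over the same columns."""
    if pfm_a.width != pfm_b.width:
        raise ValueError(
            f"column-count mismatch: {pfm_a.width} != {pfm_b.width}"
        )
    return PositionFrequencyMatrix(
        pfm_a.counts + pfm_b.counts, pfm_a.n_sequences + pfm_b.n_sequences
    )
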