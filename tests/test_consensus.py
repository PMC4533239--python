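"""Consensus building: alignment optimality, column classes, layout recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pointcen as pc
from pointcen.consensus import UngappedAlignment
from pointcen.iupac import encode


def exhaustive_align(sequences, window):
    """Oracle: enumerate every offset tuple, lex-smallest argmax."""
    encoded = [encode(s) for _, s in sequences]
    best = (-1, None)
    for offsets in itertools.product(
        *(range(len(s) - window + 1) for s in encoded)
    ):
        block = [s[o : o + window] for s, o in zip(encoded, offsets)]
        score = sum(
            max(sum(b[j] == base for b in block) for base in range(4))
            for j in range(window)
        )
        if score > best[0]:
            best = (score, offsets)
    return best


def trivial_alignment(n, window):
    return UngappedAlignment((0,) * n, window)


class TestAnchorAlign:
    def test_identical_sequences_align_at_zero(self):
        seqs = [(f"s{i}", "ACGTACGTAC") for i in range(10)]
        aln = pc.anchor_align(seqs, 10)
        assert aln.offsets == (0,) * 10
        pfm = pc.build_pfm(seqs, aln)
        assert np.all(pfm.counts.max(axis=0) == 10)

    def test_known_three_sequence_optimum(self):
        seqs = [("a", "AACGTA"), ("b", "ACGTAA"), ("c", "CACGTT")]
        aln = pc.anchor_align(seqs, 4)
        assert aln.offsets == (1, 0, 1)
        score, offsets = exhaustive_align(seqs, 4)
        assert score == 12 and offsets == (1, 0, 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=8, max_size=20),
            min_size=2,
            max_size=4,
        ),
        st.integers(min_value=4, max_value=8),
    )
    def test_exact_branch_equals_enumeration(self, raw, window):
        seqs = [(f"s{i}", s) for i, s in enumerate(raw)]
        if any(len(s) < window for _, s in seqs):
            with pytest.raises(ValueError):
                pc.anchor_align(seqs, window)
            return
        aln = pc.anchor_align(seqs, window)
        score, offsets = exhaustive_align(seqs, window)
        assert aln.offsets == offsets
        got = sum(
            int(pc.build_pfm(seqs, aln).counts.max(axis=0)[j])
            for j in range(window)
        )
        assert got == score

    def test_short_sequence_is_named_in_error(self):
        with pytest.raises(ValueError, match="shorty"):
            pc.anchor_align([("ok", "ACGTACGT"), ("shorty", "ACG")], 6)

    def test_recovers_planted_registration_in_contexts(self, default_model):
        """Windows embedded at random offsets in 500-bp AT-rich contexts align
        so that planted element columns share alignment columns."""
        rng = np.random.default_rng(99)
        bg_probs = [0.35, 0.15, 0.15, 0.35]
        seqs, planted = [], []
        for i in range(10):
            win = pc.sample_centromere(default_model, rng).sequence
            off = int(rng.integers(150, 250))
            left = "".join(rng.choice(list("ACGT"), p=bg_probs) for _ in range(off))
            right = "".join(
                rng.choice(list("ACGT"), p=bg_probs) for _ in range(500 - off - 110)
            )
            seqs.append((f"s{i}", left + win + right))
            planted.append(off)
        aln = pc.anchor_align(seqs, 110)
        rel_got = [o - aln.offsets[0] for o in aln.offsets]
        rel_true = [o - planted[0] for o in planted]
        assert rel_got == rel_true


class TestBuildPfm:
    def test_counts_and_conservation(self, sampled_windows):
        pfm = pc.build_pfm(sampled_windows, trivial_alignment(10, 110))
        assert pfm.counts.shape == (4, 110)
        assert np.all(pfm.counts.sum(axis=0) == 10)

    def test_direct_count_example(self):
        seqs = [(f"s{i}", "G") for i in range(6)] + [(f"t{i}", "C") for i in range(4)]
        pfm = pc.build_pfm(seqs, trivial_alignment(10, 1))
        assert pfm.counts[:, 0].tolist() == [0, 4, 6, 0]  # A,C,G,T

    def test_non_acgt_in_window_is_an_error(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            pc.build_pfm(
                [("a", "ACNT"), ("b", "ACGT")], trivial_alignment(2, 4)
            )


def pfm_from_columns(columns):
    """Build a PFM from per-column {base: count} dicts."""
    n = sum(next(iter(columns)).values()) if columns else 0
    counts = np.zeros((4, len(columns)), dtype=int)
    for j, col in enumerate(columns):
        for base, cnt in col.items():
            counts["ACGT".index(base), j] = cnt
    return pc.PositionFrequencyMatrix(counts, n)


class TestClassifyPositions:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ({"A": 10}, "invariant"),
            ({"A": 9, "C": 1}, "high"),
            ({"A": 8, "G": 2}, "high"),
            ({"A": 5, "T": 5}, "at_only"),
            ({"G": 5, "C": 4, "A": 1}, "gc_rich"),
            ({"A": 4, "C": 3, "G": 2, "T": 1}, "unclassified"),
            ({"G": 10}, "invariant"),  # precedence over gc_rich
            ({"A": 8, "T": 2}, "high"),  # precedence over at_only
        ],
    )
    def test_column_rules(self, column, expected):
        pfm = pfm_from_columns([column])
        assert pc.classify_positions(pfm) == [expected]

    def test_every_column_gets_exactly_one_class(self):
        rng = np.random.default_rng(0)
        cols = rng.multinomial(10, [0.25] * 4, size=200)
        pfm = pc.PositionFrequencyMatrix(cols.T, 10)
        classes = pc.classify_positions(pfm)
        assert len(classes) == 200
        assert all(
            c in ("invariant", "high", "at_only", "gc_rich", "unclassified")
            for c in classes
        )


class TestDegenerateConsensus:
    @pytest.mark.parametrize(
        "column,include_min,expected",
        [
            ({"C": 4, "G": 6}, 0.15, "S"),
            ({"A": 10}, 0.15, "A"),
            ({"A": 4, "G": 3, "T": 3}, 0.15, "D"),
            ({"A": 5, "T": 5}, 0.15, "W"),
            ({"A": 9, "C": 1}, 0.15, "A"),  # singleton suppressed
        ],
    )
    def test_column_codes(self, column, include_min, expected):
        pfm = pfm_from_columns([column])
        assert pc.derive_degenerate_consensus(pfm, include_min) == expected

    def test_raising_include_min_never_enlarges_base_sets(self):
        rng = np.random.default_rng(1)
        cols = rng.multinomial(10, [0.4, 0.3, 0.2, 0.1], size=50)
        pfm = pc.PositionFrequencyMatrix(cols.T, 10)
        frac = pfm.fractions()
        prev = None
        for inc in (0.05, 0.15, 0.25, 0.45, 0.65):
            sets = [
                frozenset("ACGT"[b] for b in range(4) if frac[b, j] >= inc)
                for j in range(pfm.width)
            ]
            if prev is not None:
                assert all(s <= p for s, p in zip(sets, prev))
            prev = sets

    def test_empty_base_set_falls_back_to_n(self):
        pfm = pfm_from_columns([{"A": 3, "C": 3, "G": 2, "T": 2}])
        assert pc.derive_degenerate_consensus(pfm, 0.5) == "N"


class TestAnnotateConsensus:
    def test_planted_layout_recovered(self, sampled_windows):
        pfm = pc.build_pfm(sampled_windows, trivial_alignment(10, 110))
        ann = pc.annotate_consensus(pfm)
        spans = [(e.start, e.end) for e in ann.elements]
        assert spans == [(20, 26), (45, 52)]
        assert ann.core == (20, 89)
        assert ann.core_length == 70

    def test_uniform_pfm_has_no_elements_or_core(self):
        counts = np.full((4, 20), 5)
        pfm = pc.PositionFrequencyMatrix(counts, 20)
        ann = pc.annotate_consensus(pfm)
        assert ann.elements == []
        assert ann.core is None

    def test_recovery_rate_across_independent_sets(self, default_model):
        """Element spans (20,26) and (45,52) recovered in >=99% of sets."""
        trials = 3000
        ok = 0
        for t in range(trials):
            rng = np.random.default_rng([202, t])
            seqs = [
                (f"s{i}", pc.sample_centromere(default_model, rng).sequence)
                for i in range(10)
            ]
            ann = pc.annotate_consensus(
                pc.build_pfm(seqs, trivial_alignment(10, 110))
            )
            spans = [(e.start, e.end) for e in ann.elements]
            ok += spans == [(20, 26), (45, 52)]
        assert ok >= 0.99 * trials


class TestMergeConsensus:
    def test_identity_with_empty_pfm(self, sampled_windows):
        pfm = pc.build_pfm(sampled_windows, trivial_alignment(10, 110))
        zero = pc.PositionFrequencyMatrix(np.zeros((4, 110), dtype=int), 0)
        merged = pc.merge_consensus(pfm, zero)
        assert np.array_equal(merged.counts, pfm.counts)
        assert merged.n_sequences == 10

    def test_counts_add_and_annotation_is_stable(self, default_model, sampled_windows):
        rng = np.random.default_rng(555)
        other = [
            (f"t{i}", pc.sample_centromere(default_model, rng).sequence)
            for i in range(10)
        ]
        pfm_a = pc.build_pfm(sampled_windows, trivial_alignment(10, 110))
        pfm_b = pc.build_pfm(other, trivial_alignment(10, 110))
        merged = pc.merge_consensus(pfm_a, pfm_b)
        assert merged.n_sequences == 20
        assert np.all(merged.counts.sum(axis=0) == 20)
        ann = pc.annotate_consensus(merged)
        assert [(e.start, e.end) for e in ann.elements] == [(20, 26), (45, 52)]

    def test_width_mismatch_is_an_error(self):
        a = pc.PositionFrequencyMatrix(np.zeros((4, 5), dtype=int), 0)
        b = pc.PositionFrequencyMatrix(np.zeros((4, 6), dtype=int), 0)
        with pytest.raises(ValueError, match="mismatch"):
            pc.merge_consensus(a, b)
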