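"""Alignment, frameshift flagging and the misalignment filter."""

from __future__ import annotations

import numpy as np
import pytest

from amplifid import (
    align_to_reference,
    filter_misaligned,
    frameshift_correct,
    default_reference,
)
from amplifid.align import make_aligner, write_sam
from amplifid.merge import MergedRead
from amplifid.reference import ReferenceAmplicon
from amplifid.simulate import _phase_shift


def mk_merged(seq, read_id="r", umi="AAAA"):
    return MergedRead(
        read_id=read_id,
        umi=umi,
        seq=seq,
        qual=np.full(len(seq), 30),
        overlap_span=(0, 0),
        offset=0,
    )


def gotoh_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Exhaustive affine-gap global alignment score (independent DP oracle).

    ``gap_open`` is the cost of the first gapped column, ``gap_extend`` of
    each further column, matching the production scoring scheme.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


@pytest.fixture(scope="module")
def short_ref():
    return ReferenceAmplicon(
        seq="ACGTACGTGGATCCATTGCA",
        primer_fwd_region=(0, 4),
        primer_rev_region=(16, 20),
        analysis_window=(4, 16),
    )


class TestAlignToReference:
    def test_identical_read_has_zero_misalignment(self, ref):
        aligned = align_to_reference(mk_merged(ref.seq), ref)
        assert aligned.mismatch_count == 0
        assert aligned.gap_column_count == 0
        assert aligned.misalignment_fraction == 0.0
        assert aligned.calls == {i: ref.seq[i] for i in range(len(ref.seq))}

    def test_25_substitutions_give_fraction_025(self, ref):
        seq = list(ref.seq)
        for i in range(0, 100, 4):  # 25 evenly spread substitutions
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        aligned = align_to_reference(mk_merged("".join(seq)), ref)
        assert aligned.mismatch_count == 25
        assert aligned.gap_column_count == 0
        assert aligned.misalignment_fraction == pytest.approx(0.25)

    def test_deleted_position_yields_no_call(self, ref):
        seq = ref.seq[:40] + ref.seq[41:]
        aligned = align_to_reference(mk_merged(seq), ref)
        missing = set(range(len(ref.seq))) - set(aligned.calls)
        assert len(missing) == 1  # exactly one reference position uncovered
        assert aligned.gap_column_count == 1

    def test_fractions_match_exhaustive_dp_oracle(self, short_ref):
        """Scores (and, for substitution-only reads, fractions) agree with
        an independent exhaustive affine-gap DP on short sequences."""
        rng = np.random.default_rng(12)
        bases = "ACGT"
        aligner = make_aligner()
        for _ in range(40):
            seq = list(short_ref.seq)
            n_sub = rng.integers(0, 4)
            sub_pos = rng.choice(len(seq), size=n_sub, replace=False)
            for p in sub_pos:
                seq[p] = bases[(bases.index(seq[p]) + int(rng.integers(1, 4))) % 4]
            has_indel = rng.random() < 0.4
            if has_indel:
                p = int(rng.integers(2, len(seq) - 2))
                if rng.random() < 0.5:
                    del seq[p]
                else:
                    seq.insert(p, bases[int(rng.integers(0, 4))])
            read = "".join(seq)
            aligned = align_to_reference(mk_merged(read), short_ref, aligner)
            oracle = gotoh_score(short_ref.seq, read)
            assert aligner.score(short_ref.seq, read) == oracle
            if not has_indel:
                assert aligned.misalignment_fraction == pytest.approx(
                    len(sub_pos) / len(short_ref.seq)
                )


class TestFrameshiftCorrect:
    def test_single_deletion_is_flagged_and_cheap(self, ref):
        seq = ref.seq[:40] + ref.seq[41:]  # clean 1-nt deletion
        aligned = frameshift_correct(align_to_reference(mk_merged(seq), ref), ref)
        assert aligned.frameshift_corrected
        assert aligned.misalignment_fraction == pytest.approx(0.01)

    def test_single_insertion_is_flagged(self, ref):
        seq = ref.seq[:40] + "A" + ref.seq[40:]
        if seq[40] == seq[41]:  # avoid ambiguous homopolymer placement
            seq = ref.seq[:40] + "C" + ref.seq[40:]
        aligned = frameshift_correct(align_to_reference(mk_merged(seq), ref), ref)
        assert aligned.frameshift_corrected
        assert aligned.misalignment_fraction == pytest.approx(0.01)

    def test_double_shift_is_not_corrected(self, ref):
        seq = ref.seq[:30] + ref.seq[31:60] + ref.seq[61:]  # two deletions
        aligned = frameshift_correct(align_to_reference(mk_merged(seq), ref), ref)
        assert not aligned.frameshift_corrected

    def test_correction_never_increases_misalignment(self, ref):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = list(ref.seq)
            p = int(rng.integers(5, 95))
            del seq[p]
            before = align_to_reference(mk_merged("".join(seq)), ref)
            frac_before = before.misalignment_fraction
            after = frameshift_correct(before, ref)
            assert after.misalignment_fraction <= frac_before

    def test_simulated_phasing_reads_are_flagged(self, ref):
        """Reads carrying a synthetic phasing shift are recognised at >=95%."""
        rng = np.random.default_rng(8)
        flagged = 0
        n = 200
        for _ in range(n):
            shifted = _phase_shift(ref.seq, rng)
            aligned = frameshift_correct(
                align_to_reference(mk_merged(shifted), ref), ref
            )
            flagged += aligned.frameshift_corrected
        assert flagged / n >= 0.95


class TestFilterMisaligned:
    def test_strict_inequality_at_threshold(self, ref):
        """A read at exactly 24% misalignment is kept; just above is removed."""
        def read_with_subs(k, read_id):
            seq = list(ref.seq)
            for i in range(k):
                pos = 4 * i
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            return align_to_reference(mk_merged("".join(seq), read_id=read_id), ref)

        at = read_with_subs(24, "at")   # fraction 0.24
        above = read_with_subs(25, "above")  # fraction 0.25
        result = filter_misaligned([at, above], threshold=0.24)
        assert [r.read_id for r in result.kept] == ["at"]
        assert [r.read_id for r in result.removed] == ["above"]

    def test_perfect_batch_removes_nothing(self, ref):
        reads = [align_to_reference(mk_merged(ref.seq, read_id=f"r{i}"), ref)
                 for i in range(5)]
        result = filter_misaligned(reads)
        assert result.removal_fraction == 0.0

    def test_empty_input(self):
        result = filter_misaligned([])
        assert result.kept == [] and result.removal_fraction == 0.0

    def test_filter_is_idempotent(self, ref):
        rng = np.random.default_rng(5)
        reads = []
        for i in range(30):
            seq = list(ref.seq)
            for p in rng.choice(100, size=int(rng.integers(0, 40)), replace=False):
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(align_to_reference(mk_merged("".join(seq), read_id=f"r{i}"), ref))
        once = filter_misaligned(reads)
        twice = filter_misaligned(once.kept)
        assert [r.read_id for r in twice.kept] == [r.read_id for r in once.kept]
        assert twice.removed == []

    def test_invalid_threshold_rejected(self, ref):
        with pytest.raises(ValueError):
            filter_misaligned([], threshold=1.5)


def test_sam_export_is_valid(tmp_path, ref):
    import pysam

    reads = [
        align_to_reference(mk_merged(ref.seq, read_id="perfect"), ref),
        align_to_reference(mk_merged(ref.seq[:40] + ref.seq[41:], read_id="del"), ref),
    ]
    path = tmp_path / "out.sam"
    write_sam(reads, ref, path)
    with pysam.AlignmentFile(str(path)) as fh:
        records = list(fh)
    assert [r.query_name for r in records] == ["perfect", "del"]
    assert records[0].cigarstring == "100M"
    assert "D" in records[1].cigarstring
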