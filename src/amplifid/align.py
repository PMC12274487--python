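"""Global alignment to the reference, frameshift handling and the 24% filter.

Merged reads are aligned end-to-end against the reference amplicon (match
+1, mismatch -1, gap open -2, gap extend -1).  The misalignment fraction of
a read is (mismatch columns + gap columns) / reference length; reads above
the removal threshold (default 24%, strict inequality) are discarded — in
practice these are adapter dimers and other junk inserts.

Sequencer phasing/pre-phasing produces an apparent single-base frameshift:
one isolated 1-nt indel with the downstream segment intact at the shifted
register.  The affine-gap aligner already re-anchors the downstream calls
across such an indel; :func:`frameshift_correct` recognises the pattern
(single isolated 1-nt indel, downstream identity >= 90%) and flags the read,
so shifted reads survive with only the single gap column charged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .merge import MergedRead
from .reference import ReferenceAmplicon


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class AlignedRead:
    """Per-reference-position base calls plus alignment quality metrics.

    ``calls`` maps reference positions to the read base aligned there;
    positions deleted in the read are absent (no substitution call is
    possible there).  Inserted read bases contribute gap columns but no
    calls.
    """

    read_id: str
    umi: str | None
    calls: dict[int, str]
    mismatch_count: int
    gap_column_count: int
    ref_length: int
    frameshift_corrected: bool = False
    # (ref_blocks, read_blocks) from the pairwise alignment, for frameshift
    # pattern inspection and SAM export.
    blocks: tuple = field(default=(), repr=False)
    read_seq: str = field(default="", repr=False)

    @property
    def misalignment_fraction(self) -> float:
        return (self.mismatch_count + self.gap_column_count) / self.ref_length


def align_to_reference(
    merged: MergedRead,
    ref: ReferenceAmplicon,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignedRead:
    """Globally align a merged read and record per-position base calls."""
    if not merged.seq:
        raise ValueError("merged read is empty")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(ref.seq, merged.seq)[0]
    ref_blocks, read_blocks = alignment.aligned

    calls: dict[int, str] = {}
    mismatch = 0
    aligned_ref = 0
    aligned_read = 0
    for (r0, r1), (s0, s1) in zip(ref_blocks, read_blocks):
        aligned_ref += r1 - r0
        aligned_read += s1 - s0
        for i in range(r1 - r0):
            base = merged.seq[s0 + i]
            calls[r0 + i] = base
            if base != ref.seq[r0 + i]:
                mismatch += 1
    gap_columns = (len(ref.seq) - aligned_ref) + (len(merged.seq) - aligned_read)
    return AlignedRead(
        read_id=merged.read_id,
        umi=merged.umi,
        calls=calls,
        mismatch_count=mismatch,
        gap_column_count=gap_columns,
        ref_length=len(ref.seq),
        blocks=(tuple(map(tuple, ref_blocks)), tuple(map(tuple, read_blocks))),
        read_seq=merged.seq,
    )


def _indel_events(aligned: AlignedRead) -> list[tuple[str, int, int]]:
    """Internal indel events as (kind, length, ref_pos); 'del' = gap in read."""
    ref_blocks, read_blocks = aligned.blocks
    events: list[tuple[str, int, int]] = []
    for i in range(1, len(ref_blocks)):
        dref = ref_blocks[i][0] - ref_blocks[i - 1][1]
        dread = read_blocks[i][0] - read_blocks[i - 1][1]
        if dref > 0:
            events.append(("del", int(dref), int(ref_blocks[i - 1][1])))
        if dread > 0:
            events.append(("ins", int(dread), int(ref_blocks[i][0])))
    return events


def frameshift_correct(
    aligned: AlignedRead,
    ref: ReferenceAmplicon,
    min_downstream_identity: float = 0.9,
) -> AlignedRead:
    """Flag reads whose alignment shows a phasing-style single frameshift.

    A read qualifies when its alignment contains exactly one isolated
    internal 1-nt indel and the re-anchored downstream segment matches the
    reference at >= ``min_downstream_identity``.  A further 1-nt indel
    within a few columns of either sequence end is tolerated as a terminal
    artifact (the register slip leaves one junk base at the read's end)
    rather than counted as an independent shift.  The downstream calls are
    already re-anchored by the gap-aware alignment; the indel is charged as
    a single gap column and never as mismatches.  Non-qualifying reads pass
    through unchanged.
    """
    edge_margin = 3
    if not aligned.blocks or len(aligned.blocks[0]) < 2:
        return aligned
    events = _indel_events(aligned)
    interior = [
        e
        for e in events
        if edge_margin <= e[2] <= aligned.ref_length - edge_margin
    ]
    terminal = [e for e in events if e not in interior]
    if len(interior) != 1 or interior[0][1] != 1:
        return aligned
    if any(length != 1 for _k, length, _p in terminal):
        return aligned
    break_pos = interior[0][2]
    down = [
        (pos, base)
        for pos, base in aligned.calls.items()
        if pos >= break_pos
    ]
    if not down:
        return aligned
    matches = sum(1 for pos, base in down if base == ref.seq[pos])
    if matches / len(down) < min_downstream_identity:
        return aligned
    aligned.frameshift_corrected = True
    return aligned


@dataclass
class FilterResult:
    kept: list[AlignedRead]
    removed: list[AlignedRead]

    @property
    def removal_fraction(self) -> float:
        n = len(self.kept) + len(self.removed)
        return len(self.removed) / n if n else 0.0

    def to_tsv(self, path: str | Path, threshold: float) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"threshold\t{threshold}\n")
            fh.write(f"kept\t{len(self.kept)}\n")
            fh.write(f"removed\t{len(self.removed)}\n")
            fh.write(f"removal_fraction\t{self.removal_fraction:.6g}\n")


def filter_misaligned(
    reads: Iterable[AlignedRead], threshold: float = 0.24
) -> FilterResult:
    """Remove reads with misalignment fraction strictly greater than threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    kept, removed = [], []
    for read in reads:
        (removed if read.misalignment_fraction > threshold else kept).append(read)
    return FilterResult(kept=kept, removed=removed)


def _cigar_from_blocks(aligned: AlignedRead) -> str:
    ref_blocks, read_blocks = aligned.blocks
    if not ref_blocks:
        return f"{len(aligned.read_seq)}I" if aligned.read_seq else "*"
    ops: list[tuple[int, str]] = []
    # Leading soft-clip-free global alignment: leading/trailing ref gaps are
    # deletions, read gaps insertions.
    if read_blocks[0][0] > 0:
        ops.append((read_blocks[0][0], "I"))
    if ref_blocks[0][0] > 0:
        ops.append((ref_blocks[0][0], "D"))
    for i, ((r0, r1), (s0, s1)) in enumerate(zip(ref_blocks, read_blocks)):
        if i > 0:
            dref = r0 - ref_blocks[i - 1][1]
            dread = s0 - read_blocks[i - 1][1]
            if dread > 0:
                ops.append((dread, "I"))
            if dref > 0:
                ops.append((dref, "D"))
        ops.append((r1 - r0, "M"))
    ref_len = aligned.ref_length
    read_len = len(aligned.read_seq)
    if ref_blocks[-1][1] < ref_len:
        ops.append((ref_len - ref_blocks[-1][1], "D"))
    if read_blocks[-1][1] < read_len:
        ops.append((read_len - read_blocks[-1][1], "I"))
    return "".join(f"{n}{op}" for n, op in ops if n > 0)


def write_sam(
    reads: Sequence[AlignedRead], ref: ReferenceAmplicon, path: str | Path
) -> None:
    """Export aligned reads as SAM with a single-reference header."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref.seq)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.read_seq
            seg.flag = 0
            seg.reference_id = 0
            ref_blocks = read.blocks[0] if read.blocks else ()
            seg.reference_start = ref_blocks[0][0] if ref_blocks else 0
            seg.mapping_quality = 255
            cigar = _cigar_from_blocks(read)
            # SAM cannot represent a deletion before the first aligned base;
            # reference offset handles it via reference_start instead.
            if ref_blocks and ref_blocks[0][0] > 0:
                cigar = cigar.replace(f"{ref_blocks[0][0]}D", "", 1)
            seg.cigarstring = cigar
            out.write(seg)
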