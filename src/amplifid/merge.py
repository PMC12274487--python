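"""Paired-read merging: Phred transform and highest-quality-base consensus.

Mates of a short amplicon read through each other, so Read 2 (reverse
complemented) is placed against Read 1 at the offset implied by the expected
amplicon size, refined by a small local search.  Inside the overlap the base
with the higher Phred score wins (ties go to Read 1); outside it the covering
mate supplies the base.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .reference import reverse_complement


def phred_to_prob(q):
    """Base-calling error probability P = 10^(-Q/10).

    Accepts a scalar or array of Phred scores; negative scores are invalid.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Phred scores must be >= 0")
    p = 10.0 ** (-q / 10.0)
    return float(p) if p.ndim == 0 else p


@dataclass
class ReadPair:
    read_id: str
    umi: str | None
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray

    def __post_init__(self) -> None:
        self.r1_qual = np.asarray(self.r1_qual, dtype=int)
        self.r2_qual = np.asarray(self.r2_qual, dtype=int)
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(
            self.r2_qual
        ):
            raise ValueError("sequence and quality lengths differ")
        if np.any(self.r1_qual < 0) or np.any(self.r2_qual < 0):
            raise ValueError("Phred scores must be >= 0")


@dataclass
class MergedRead:
    read_id: str
    umi: str | None
    seq: str
    qual: np.ndarray
    overlap_span: tuple[int, int]
    offset: int

    @property
    def error_prob(self) -> np.ndarray:
        return phred_to_prob(self.qual)


@dataclass
class MergeStats:
    """Per-batch accounting of merge outcomes."""

    total: int = 0
    merged: int = 0
    unmergeable: int = 0
    reasons: dict = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.unmergeable += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            fh.write(f"total\t{self.total}\n")
            fh.write(f"merged\t{self.merged}\n")
            fh.write(f"unmergeable\t{self.unmergeable}\n")
            for reason, n in sorted(self.reasons.items()):
                fh.write(f"unmergeable.{reason}\t{n}\n")


def merge_pair(
    pair: ReadPair,
    expected_length: int,
    max_offset_shift: int = 3,
    min_overlap_identity: float = 0.6,
) -> MergedRead | None:
    """Merge a read pair into one quality-resolved sequence.

    Read 2 is reverse complemented and placed at offset
    ``expected_length - len(r2)``; offsets within ``max_offset_shift`` of
    that are scored by overlap matches and the best wins (ties to the offset
    closest to expected).  Returns None when the best overlap identity falls
    below ``min_overlap_identity`` (the pair is not from the amplicon, e.g.
    an inconsistent junk pair).
    """
    if not pair.r1_seq or not pair.r2_seq:
        raise ValueError("both mates must be non-empty")
    n1, n2 = len(pair.r1_seq), len(pair.r2_seq)
    if expected_length > n1 + n2:
        raise ValueError("expected_length exceeds combined mate length")

    a1 = np.frombuffer(pair.r1_seq.encode(), dtype=np.uint8)
    rc2 = reverse_complement(pair.r2_seq)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    q2 = pair.r2_qual[::-1]

    expected_offset = expected_length - n2
    best: tuple[int, int, int] | None = None  # (matches, -|off-exp|, off)
    for off in range(
        max(0, expected_offset - max_offset_shift),
        min(n1, expected_offset + max_offset_shift) + 1,
    ):
        ov = min(n1 - off, n2)
        if ov <= 0:
            matches = 0
        else:
            matches = int(np.count_nonzero(a1[off : off + ov] == a2[:ov]))
        key = (matches, -abs(off - expected_offset), off)
        if best is None or key > best:
            best = key
    assert best is not None
    matches, _, off = best
    overlap_len = min(n1 - off, n2)
    if overlap_len > 0 and matches / overlap_len < min_overlap_identity:
        return None

    # Assemble: R1 prefix, quality-resolved overlap, R2 suffix.
    ov0, ov1 = off, off + overlap_len
    take_r1 = pair.r1_qual[ov0:ov1] >= q2[:overlap_len]
    overlap_bases = np.where(take_r1, a1[ov0:ov1], a2[:overlap_len])
    overlap_qual = np.maximum(pair.r1_qual[ov0:ov1], q2[:overlap_len])
    seq = (
        pair.r1_seq[:ov0]
        + overlap_bases.tobytes().decode()
        + rc2[overlap_len:]
    )
    qual = np.concatenate(
        [pair.r1_qual[:ov0], overlap_qual, q2[overlap_len:]]
    )
    return MergedRead(
        read_id=pair.read_id,
        umi=pair.umi,
        seq=seq,
        qual=qual,
        overlap_span=(ov0, ov1),
        offset=off,
    )


def merge_pairs(
    pairs: Iterable[ReadPair],
    expected_length: int,
    max_offset_shift: int = 3,
    min_overlap_identity: float = 0.6,
) -> tuple[list[MergedRead], MergeStats]:
    """Merge a batch of pairs, dropping unmergeable ones with counted reasons."""
    stats = MergeStats()
    merged: list[MergedRead] = []
    for pair in pairs:
        stats.total += 1
        m = merge_pair(pair, expected_length, max_offset_shift, min_overlap_identity)
        if m is None:
            stats.count("low_overlap_identity")
        else:
            merged.append(m)
            stats.merged += 1
    return merged, stats


_UMI_NAME_RE = re.compile(r"UMI_([ACGTN]+)")


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    umi_in_read: bool = False,
    umi_length: int | None = None,
) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (Phred+33, optionally gzip).

    The UMI is taken from the read name (``...UMI_<tag>``); with
    ``umi_in_read`` it is instead stripped from the first ``umi_length``
    bases of Read 1.
    """
    if umi_in_read and not umi_length:
        raise ValueError("umi_length required when umi_in_read is set")
    with _open_maybe_gzip(r1_path) as fh1, _open_maybe_gzip(r2_path) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            if rec1.id != rec2.id:
                raise ValueError(
                    f"mate ids out of sync: {rec1.id!r} vs {rec2.id!r}"
                )
            seq1 = str(rec1.seq)
            q1 = np.asarray(rec1.letter_annotations["phred_quality"], dtype=int)
            seq2 = str(rec2.seq)
            q2 = np.asarray(rec2.letter_annotations["phred_quality"], dtype=int)
            if umi_in_read:
                umi = seq1[:umi_length]
                seq1 = seq1[umi_length:]
                q1 = q1[umi_length:]
            else:
                m = _UMI_NAME_RE.search(rec1.id)
                umi = m.group(1) if m else None
            yield ReadPair(rec1.id, umi, seq1, seq2, q1, q2)


def write_merged_fastq(reads: Iterable[MergedRead], path: str | Path) -> None:
    """Write merged reads as single-end Phred+33 FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            qstr = "".join(chr(int(q) + 33) for q in r.qual)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qstr}\n")
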