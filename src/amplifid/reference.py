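"""Reference amplicon description: sequence, primer regions and analysis window.

The fidelity statistic is averaged only over the primer-free interior of the
amplicon, because bases under the primers are dictated by the synthetic
oligonucleotides rather than by the polymerase being assayed.  One further
position — by default the 3'-most reference T inside the window — is excluded,
since consensus-family error counts at that position behave as a clear outlier
relative to the rest of the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# 5' 100 nt of the SARS-CoV-2 nucleocapsid (N) gene, covering the CDC N1
# primer/probe region.  Reconstructed from the N protein coding sequence;
# used as the default template for the ~100 bp N1 amplicon.
NCOV_N1_AMPLICON = (
    "ATGTCTGATAATGGACCCCAAAATCAGCGAAAT"
    "GCACCCCGCATTACGTTTGGTGGACCCT"
    "CAGATTCAACTGGCAGTAACCAGA"
    "ATGGAGAACGCAGTG"
)


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A reference amplicon with primer annotations and analysis window.

    Parameters
    ----------
    seq
        Reference sequence, DNA alphabet (ACGT), uppercase.
    primer_fwd_region, primer_rev_region
        0-based half-open intervals covered by the forward and reverse
        primers (the reverse primer's binding site on this strand).
    analysis_window
        0-based half-open interval over which per-position error rates are
        aggregated; must lie strictly between the primer regions.
    excluded_positions
        Window positions dropped from the average (default: the 3'-most
        reference T inside the window).
    """

    seq: str
    primer_fwd_region: tuple[int, int]
    primer_rev_region: tuple[int, int]
    analysis_window: tuple[int, int]
    excluded_positions: frozenset[int] = field(default_factory=frozenset)
    name: str = "amplicon"

    def __post_init__(self) -> None:
        if not self.seq or set(self.seq) - DNA_ALPHABET:
            raise ValueError("reference sequence must be non-empty ACGT")
        f0, f1 = self.primer_fwd_region
        r0, r1 = self.primer_rev_region
        w0, w1 = self.analysis_window
        if not (0 <= f0 < f1 <= r0 < r1 <= len(self.seq)):
            raise ValueError("primer regions must be ordered and in range")
        if not (f1 <= w0 < w1 <= r0):
            raise ValueError("analysis window must lie between primer regions")
        if not set(self.excluded_positions) <= set(range(w0, w1)):
            raise ValueError("excluded_positions must lie inside the window")

    @property
    def rna_display_seq(self) -> str:
        """The template rendered in the RNA alphabet (T -> U)."""
        return self.seq.replace("T", "U")

    def __len__(self) -> int:
        return len(self.seq)

    def window_positions(self, apply_exclusions: bool = True) -> list[int]:
        w0, w1 = self.analysis_window
        pos = range(w0, w1)
        if apply_exclusions:
            return [p for p in pos if p not in self.excluded_positions]
        return list(pos)

    @classmethod
    def with_default_window(
        cls,
        seq: str,
        primer_fwd_len: int,
        primer_rev_len: int,
        exclude_last_t: bool = True,
        name: str = "amplicon",
    ) -> "ReferenceAmplicon":
        """Build a reference whose window is everything between the primers.

        With ``exclude_last_t`` the 3'-most reference T inside the window is
        put on the exclusion list.
        """
        n = len(seq)
        window = (primer_fwd_len, n - primer_rev_len)
        excluded: frozenset[int] = frozenset()
        if exclude_last_t:
            t_pos = last_t_position(seq, window)
            if t_pos is not None:
                excluded = frozenset({t_pos})
        return cls(
            seq=seq,
            primer_fwd_region=(0, primer_fwd_len),
            primer_rev_region=(n - primer_rev_len, n),
            analysis_window=window,
            excluded_positions=excluded,
            name=name,
        )


def last_t_position(seq: str, window: tuple[int, int]) -> int | None:
    """0-based position of the 3'-most T within ``window``, or None."""
    w0, w1 = window
    idx = seq.rfind("T", w0, w1)
    return idx if idx >= 0 else None


def default_reference() -> ReferenceAmplicon:
    """The packaged 100-nt N1-region amplicon with 20-nt terminal primers."""
    return ReferenceAmplicon.with_default_window(
        NCOV_N1_AMPLICON, primer_fwd_len=20, primer_rev_len=20, name="nCov_N1"
    )
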