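"""Fidelity estimation as a model/results pair.

:class:`AmpliconFidelityModel` bundles the read data, the reference amplicon
and every pipeline threshold; ``fit()`` runs merge -> align -> frameshift ->
misalignment filter -> UMI grouping -> consensus calling -> doubling-number
normalization and returns an :class:`AmpliconFidelityResults` carrying the
per-position profile, the windowed average error with a standard error, the
per-base breakdown and all stage diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import align as _align
from . import merge as _merge
from . import normalize as _normalize
from . import umi as _umi
from .merge import MergedRead, MergeStats, ReadPair
from .normalize import FidelityReport, amplification_number, doubling_number
from .reference import ReferenceAmplicon, default_reference


@dataclass
class PipelineParams:
    """All tunable thresholds of the consensus pipeline."""

    max_misalignment: float = 0.24
    min_family_size: int = 4
    consensus_fraction: float = 0.90
    min_overlap_identity: float = 0.6
    max_offset_shift: int = 3
    min_downstream_identity: float = 0.9

    def validate(self) -> None:
        if not 0.0 < self.max_misalignment < 1.0:
            raise ValueError("max_misalignment must be in (0, 1)")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")
        if not 0.0 <= self.min_overlap_identity <= 1.0:
            raise ValueError("min_overlap_identity must be in [0, 1]")


class AmpliconFidelityModel:
    """UMI-consensus substitution-fidelity model for one sequencing library.

    Parameters
    ----------
    pairs
        Read pairs (in memory); use :meth:`from_fastq` to stream from files.
    reference
        The amplicon with primer regions and analysis window (defaults to
        the packaged N1-region amplicon).
    doubling_number
        The enzyme's doubling number D; alternatively give
        ``amplification=(n_after, n_input)`` and D is derived.
    params
        Pipeline thresholds; defaults follow the published workflow
        (24% misalignment, family size > 3, 90% consensus).
    """

    def __init__(
        self,
        pairs: Iterable[ReadPair],
        reference: ReferenceAmplicon | None = None,
        doubling_number: float | None = None,
        amplification: tuple[float, float] | None = None,
        params: PipelineParams | None = None,
    ):
        if (doubling_number is None) == (amplification is None):
            raise ValueError(
                "specify exactly one of doubling_number or amplification"
            )
        self.pairs = pairs
        self.reference = reference if reference is not None else default_reference()
        self.params = params or PipelineParams()
        self.params.validate()
        if amplification is not None:
            n_after, n_input = amplification
            self._A = amplification_number(n_after, n_input)
        else:
            self._A = 2.0**doubling_number
        self._D = doubling_number if doubling_number is not None else (
            _normalize.doubling_number(self._A)
        )
        if self._D <= 0:
            raise ValueError("doubling number must be positive")

    @classmethod
    def from_fastq(
        cls,
        r1_path: str | Path,
        r2_path: str | Path,
        reference: ReferenceAmplicon | None = None,
        umi_in_read: bool = False,
        umi_length: int | None = None,
        **kwargs,
    ) -> "AmpliconFidelityModel":
        pairs = _merge.read_fastq_pairs(
            r1_path, r2_path, umi_in_read=umi_in_read, umi_length=umi_length
        )
        return cls(pairs, reference=reference, **kwargs)

    def fit(self) -> "AmpliconFidelityResults":
        p = self.params
        ref = self.reference
        merged, merge_stats = _merge.merge_pairs(
            self.pairs,
            expected_length=len(ref.seq),
            max_offset_shift=p.max_offset_shift,
            min_overlap_identity=p.min_overlap_identity,
        )
        aligner = _align.make_aligner()
        aligned = [
            _align.frameshift_correct(
                _align.align_to_reference(m, ref, aligner),
                ref,
                p.min_downstream_identity,
            )
            for m in merged
        ]
        filt = _align.filter_misaligned(aligned, threshold=p.max_misalignment)
        families, grouping = _umi.group_by_umi(filt.kept)
        profile = _umi.position_error_rates(
            families,
            ref,
            consensus_fraction=p.consensus_fraction,
            min_family_size=p.min_family_size,
        )
        report = _normalize.build_report(
            profile,
            ref,
            D=self._D,
            A=self._A,
            n_families=len(families),
            metadata={
                "max_misalignment": p.max_misalignment,
                "min_family_size": p.min_family_size,
                "consensus_fraction": p.consensus_fraction,
                "min_overlap_identity": p.min_overlap_identity,
            },
        )
        return AmpliconFidelityResults(
            model=self,
            report=report,
            merge_stats=merge_stats,
            filter_result=filt,
            grouping_stats=grouping,
            families=families,
        )


@dataclass
class AmpliconFidelityResults:
    """Estimates and diagnostics from a fitted fidelity model."""

    model: AmpliconFidelityModel
    report: FidelityReport
    merge_stats: MergeStats
    filter_result: _align.FilterResult
    grouping_stats: _umi.GroupingStats
    families: list[_umi.UmiFamily] = field(repr=False, default_factory=list)

    @property
    def average_error(self) -> float:
        """Average substitution error, % per doubling."""
        return self.report.average_error

    @property
    def average_error_se(self) -> float:
        return self.report.average_error_se

    @property
    def per_base_rates(self) -> dict[str, float | None]:
        return self.report.per_base_rates

    @property
    def doubling_number(self) -> float:
        return self.report.doubling_number

    def profile_frame(self):
        return self.report.profile.to_frame()

    def n_qualifying_families(self) -> int:
        return self.report.n_qualifying_families

    def summary(self) -> str:
        r = self.report
        fs = self.filter_result
        lines = [
            "Amplicon substitution-fidelity results (UMI-family consensus)",
            "=" * 62,
            f"reference                      {self.model.reference.name}"
            f" ({len(self.model.reference.seq)} nt)",
            f"read pairs                     {self.merge_stats.total:>10d}",
            f"  merged                       {self.merge_stats.merged:>10d}",
            f"  unmergeable                  {self.merge_stats.unmergeable:>10d}",
            f"misalignment filter (> {self.model.params.max_misalignment:.0%})"
            f"{'':<6}removed {len(fs.removed)}"
            f" ({fs.removal_fraction:.2%})",
            f"UMI families                   {r.n_families:>10d}"
            f"  (qualifying at best position: {r.n_qualifying_families})",
            f"amplification number A         {r.amplification_number:>10.4g}",
            f"doubling number D              {r.doubling_number:>10.4f}",
            "-" * 62,
            f"average substitution error     {r.average_error:>10.4f} % per doubling"
            f"  (SE {r.average_error_se:.4f})",
            "per-base rates (% per doubling):",
        ]
        for base in "ACGU":
            rate = r.per_base_rates.get(base)
            shown = f"{rate:.4f}" if rate is not None else "absent"
            lines.append(f"  {base}                            {shown:>10}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Per-position normalized error profile (matplotlib bar plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        df = self.profile_frame()
        ax.bar(df["position"], df["normalized_rate_pct_per_doubling"], width=0.8)
        ax.set_xlabel("reference position")
        ax.set_ylabel("% error per doubling")
        ax.set_title("Per-position substitution error (normalized)")
        return ax

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_json(out / "fidelity_report.json")
        self.report.to_tsv(out / "position_rates.tsv")
        self.merge_stats.to_tsv(out / "merge_stats.tsv")
        self.filter_result.to_tsv(
            out / "filter_report.tsv", self.model.params.max_misalignment
        )
        _umi.write_family_histogram(self.families, out / "family_sizes.tsv")
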