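"""Doubling-number normalization and the final fidelity report.

A polymerase that amplified more has had more chances to err, so raw
per-position rates are divided by the doubling number

    A = n(after PCR) / n(input RNA),    D = ln(A) / ln(2),

giving substitution rates per base per doubling (reported in percent).  The
average is taken over the primer-free analysis window, skipping excluded and
no-data positions, and a per-base breakdown groups window positions by their
template identity in the RNA alphabet (A, C, G, U).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import ReferenceAmplicon
from .umi import PositionErrorProfile


@dataclass(frozen=True)
class AmplificationStats:
    """Input/output quantities and the derived amplification and doubling
    numbers.  Only the ratio matters, so n may be copies or moles as long as
    both are in the same units."""

    n_input: float
    n_after: float

    def __post_init__(self) -> None:
        if self.n_input <= 0 or self.n_after <= 0:
            raise ValueError("quantities must be positive")

    @property
    def A(self) -> float:
        return amplification_number(self.n_after, self.n_input)

    @property
    def D(self) -> float:
        return doubling_number(self.A)


def amplification_number(n_after: float, n_input: float) -> float:
    """A = n(after PCR) / n(input RNA); both in the same units."""
    if n_after <= 0 or n_input <= 0:
        raise ValueError("quantities must be positive")
    return n_after / n_input


def doubling_number(A: float) -> float:
    """D = ln(A)/ln(2).  A < 1 yields a negative D (net loss of material)."""
    if A <= 0:
        raise ValueError("amplification number must be positive")
    return math.log(A) / math.log(2)


def normalize_errors(
    profile: PositionErrorProfile, D: float
) -> PositionErrorProfile:
    """Fill ``normalized_rate`` = 100 * raw_rate / D (percent per doubling)."""
    if D <= 0:
        raise ValueError("doubling number must be positive")
    profile.normalized_rate = 100.0 * profile.raw_rate / D
    profile.doubling_number = D
    return profile


def _included_mask(
    profile: PositionErrorProfile, ref: ReferenceAmplicon
) -> np.ndarray:
    excluded = ref.excluded_positions
    mask = ~profile.no_data
    if excluded:
        mask &= ~np.isin(profile.positions, list(excluded))
    return mask


def average_error(
    profile: PositionErrorProfile, ref: ReferenceAmplicon
) -> float:
    """Mean normalized rate (% per doubling) over the effective window.

    Excluded positions (by default the 3'-most reference T in the window)
    and positions without qualifying families are left out of the mean.
    """
    if profile.normalized_rate is None:
        raise ValueError("profile must be normalized first")
    mask = _included_mask(profile, ref)
    if not mask.any():
        raise ValueError("no evaluable positions in the analysis window")
    return float(np.mean(profile.normalized_rate[mask]))


def average_error_se(
    profile: PositionErrorProfile, ref: ReferenceAmplicon
) -> float:
    """Binomial standard error of the windowed average (% per doubling).

    Treats per-position family tallies as independent binomials; family
    sharing across positions makes this an approximation.
    """
    if profile.normalized_rate is None or profile.doubling_number is None:
        raise ValueError("profile must be normalized first")
    mask = _included_mask(profile, ref)
    p = profile.raw_rate[mask]
    n = profile.n_qualifying[mask]
    var = p * (1.0 - p) / n
    m = mask.sum()
    return float(100.0 * np.sqrt(var.sum()) / (m * profile.doubling_number))


def per_base_breakdown(
    profile: PositionErrorProfile, ref: ReferenceAmplicon
) -> dict[str, float | None]:
    """Mean normalized rate per template base identity (RNA alphabet).

    Bases absent from the effective window map to None.
    """
    if profile.normalized_rate is None:
        raise ValueError("profile must be normalized first")
    rna = ref.rna_display_seq
    mask = _included_mask(profile, ref)
    rates: dict[str, float | None] = {}
    for base in "ACGU":
        sel = mask & np.array([rna[p] == base for p in profile.positions])
        rates[base] = float(np.mean(profile.normalized_rate[sel])) if sel.any() else None
    return rates


@dataclass
class FidelityReport:
    """Final per-run substitution-fidelity summary."""

    profile: PositionErrorProfile
    average_error: float  # % per doubling
    average_error_se: float
    per_base_rates: dict[str, float | None]
    doubling_number: float
    amplification_number: float
    n_families: int
    n_qualifying_families: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        df = self.profile.to_frame()
        return {
            "average_error_pct_per_doubling": self.average_error,
            "average_error_se": self.average_error_se,
            "per_base_rates_pct_per_doubling": self.per_base_rates,
            "doubling_number": self.doubling_number,
            "amplification_number": self.amplification_number,
            "n_families": self.n_families,
            "n_qualifying_families": self.n_qualifying_families,
            "excluded_positions": sorted(self.profile.ref.excluded_positions),
            "analysis_window": list(self.profile.ref.analysis_window),
            "positions": df.replace({np.nan: None}).to_dict(orient="records"),
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_tsv(self, path: str | Path) -> None:
        self.profile.to_tsv(path)


def build_report(
    profile: PositionErrorProfile,
    ref: ReferenceAmplicon,
    D: float,
    A: float,
    n_families: int,
    metadata: dict | None = None,
) -> FidelityReport:
    """Normalize a raw profile and assemble the fidelity report."""
    normalize_errors(profile, D)
    qualifying = int(profile.n_qualifying.max()) if len(profile.n_qualifying) else 0
    return FidelityReport(
        profile=profile,
        average_error=average_error(profile, ref),
        average_error_se=average_error_se(profile, ref),
        per_base_rates=per_base_breakdown(profile, ref),
        doubling_number=D,
        amplification_number=A,
        n_families=n_families,
        n_qualifying_families=qualifying,
        metadata=metadata or {},
    )
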