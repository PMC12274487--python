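"""Combinatorial polymerase-library enumeration, coverage and enrichment.

The engineered library combines 8 RT-enhancing point mutations of Taq
polymerase in all on/off combinations: 2^8 = 256 variants, from wild type to
the 8-fold mutant.  Colonies are picked at random from an equimolar plasmid
pool, so variant coverage follows the classic occupancy (coupon-collector)
model: with V equiprobable variants and N picks the expected covered
fraction is 1 - (1 - 1/V)^N.  Screening labels variants active/inactive;
per-site mutation frequencies and mutation-load histograms contrast the two
groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 8 recombined RT-enhancing mutations of the Taq polymerase library.
MUTATION_SITES: tuple[str, ...] = (
    "L459M",
    "N483K",
    "E507K",
    "S515R",
    "V586G",
    "I614K",
    "I638F",
    "M747K",
)


@dataclass(frozen=True)
class VariantGenotype:
    """One library member: per-site mutation flags plus an activity label."""

    variant_id: str
    flags: tuple[bool, ...]
    activity: str | None = None  # "active" | "inactive" | None
    sites: tuple[str, ...] = MUTATION_SITES

    def __post_init__(self) -> None:
        if len(self.flags) != len(self.sites):
            raise ValueError("flags length must equal number of sites")
        if self.activity not in (None, "active", "inactive"):
            raise ValueError("activity must be 'active', 'inactive' or None")

    @property
    def mutation_load(self) -> int:
        return sum(self.flags)

    @property
    def mutations(self) -> tuple[str, ...]:
        return tuple(s for s, f in zip(self.sites, self.flags) if f)


@dataclass(frozen=True)
class LibrarySpec:
    """Size/coverage bookkeeping for a combinatorial site-toggle library."""

    n_sites: int
    n_picks: int

    @property
    def variant_count(self) -> int:
        return 2**self.n_sites

    @property
    def oversampling_factor(self) -> float:
        return self.n_picks / self.variant_count

    @property
    def expected_coverage_fraction(self) -> float:
        return expected_coverage(self.variant_count, self.n_picks).expected_fraction


def enumerate_variants(
    n_sites: int = 8, sites: Sequence[str] | None = None
) -> list[VariantGenotype]:
    """All 2^n_sites genotypes, wild type (no flags) included."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if sites is None:
        sites = MUTATION_SITES[:n_sites] if n_sites <= len(MUTATION_SITES) else [
            f"site{i}" for i in range(n_sites)
        ]
    sites = tuple(sites)
    width = len(str(max(2**n_sites - 1, 0)))
    variants = []
    for i, flags in enumerate(itertools.product((False, True), repeat=n_sites)):
        variants.append(
            VariantGenotype(variant_id=f"v{i:0{width}d}", flags=flags, sites=sites)
        )
    return variants


@dataclass(frozen=True)
class CoverageResult:
    expected_fraction: float
    p_full_coverage: float
    method: str  # "inclusion-exclusion" | "monte-carlo"


def _p_full_inclusion_exclusion(V: int, N: int, tol: float = 1e-15) -> float:
    """P(all V variants seen in N equiprobable picks) by inclusion-exclusion.

    Terms are computed in log space and accumulation stops once they fall
    below ``tol``; the alternating series decays fast for N >> V ln V.
    """
    if N < V:
        return 0.0
    total = 1.0
    for j in range(1, V):  # j variants missed
        log_term = (
            math.lgamma(V + 1)
            - math.lgamma(j + 1)
            - math.lgamma(V - j + 1)
            + N * math.log1p(-j / V)
        )
        term = math.exp(log_term)
        total += term if j % 2 == 0 else -term
        if term < tol:
            break
    return min(max(total, 0.0), 1.0)


def expected_coverage(
    V: int,
    N: int,
    weights: np.ndarray | None = None,
    mc_threshold: int = 10_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> CoverageResult:
    """Expected covered fraction and full-coverage probability.

    Under equiprobable sampling the expected fraction is
    ``1 - (1 - 1/V)^N``; the probability that every variant is picked at
    least once uses inclusion-exclusion for modest V and a seeded
    Monte-Carlo estimate for large V.  A ``weights`` vector (length V,
    normalised internally) models non-equimolar pools; full-coverage
    probability is then estimated by Monte Carlo.
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    if N < 0:
        raise ValueError("N must be >= 0")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != V or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be V nonnegative values, not all zero")
        w = w / w.sum()
        expected = float(np.mean(1.0 - (1.0 - w) ** N))
        rng = np.random.default_rng(seed)
        n_rep = min(n_mc, 20_000)
        hits = sum(
            np.unique(rng.choice(V, size=N, p=w)).size == V
            for _ in range(n_rep)
        )
        return CoverageResult(expected, hits / n_rep, "monte-carlo")
    if N == 0:
        return CoverageResult(0.0, 1.0 if V == 0 else 0.0, "inclusion-exclusion")
    expected = 1.0 - (1.0 - 1.0 / V) ** N if V > 1 else 1.0
    if V <= mc_threshold:
        p_full = _p_full_inclusion_exclusion(V, N)
        method = "inclusion-exclusion"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            seen = np.unique(rng.integers(0, V, size=N)).size
            hits += seen == V
        p_full = hits / n_mc
        method = "monte-carlo"
    return CoverageResult(expected, p_full, method)


@dataclass
class EnrichmentResult:
    """Per-site mutation frequencies and load histograms, active vs inactive."""

    site_frequencies: pd.DataFrame  # index: site, columns: active, inactive
    load_histograms: dict[str, dict[int, int]]
    group_sizes: dict[str, int]
    empty_groups: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        self.site_frequencies.to_csv(path, sep="\t", float_format="%.6g")


def mutation_enrichment(
    genotypes: Iterable[VariantGenotype],
) -> EnrichmentResult:
    """Per-site mutation frequency and mutation-load histogram per group.

    Every genotype must carry an activity label; a group with no members
    gets NaN frequencies and is flagged empty.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no genotypes supplied")
    sites = genotypes[0].sites
    groups: dict[str, list[VariantGenotype]] = {"active": [], "inactive": []}
    for g in genotypes:
        if g.activity is None:
            raise ValueError(f"genotype {g.variant_id} has no activity label")
        if g.sites != sites:
            raise ValueError("all genotypes must share the same site list")
        groups[g.activity].append(g)

    freq = {}
    load_histograms: dict[str, dict[int, int]] = {}
    empty = []
    for name, members in groups.items():
        if not members:
            freq[name] = [float("nan")] * len(sites)
            load_histograms[name] = {}
            empty.append(name)
            continue
        flags = np.array([g.flags for g in members], dtype=bool)
        freq[name] = flags.mean(axis=0).tolist()
        loads, counts = np.unique(flags.sum(axis=1), return_counts=True)
        load_histograms[name] = {int(l): int(c) for l, c in zip(loads, counts)}
    df = pd.DataFrame(freq, index=list(sites))
    df.index.name = "site"
    return EnrichmentResult(
        site_frequencies=df,
        load_histograms=load_histograms,
        group_sizes={k: len(v) for k, v in groups.items()},
        empty_groups=empty,
    )


def read_genotype_table(path: str | Path, sep: str = "\t") -> list[VariantGenotype]:
    """Load genotypes from a table: variant id, one 0/1 column per site, label.

    Columns: ``variant``, the site names (e.g. L459M ... M747K), ``activity``.
    """
    df = pd.read_csv(path, sep=sep)
    site_cols = [c for c in df.columns if c not in ("variant", "activity")]
    genotypes = []
    for _, row in df.iterrows():
        genotypes.append(
            VariantGenotype(
                variant_id=str(row["variant"]),
                flags=tuple(bool(int(row[c])) for c in site_cols),
                activity=row["activity"] if pd.notna(row["activity"]) else None,
                sites=tuple(site_cols),
            )
        )
    return genotypes
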