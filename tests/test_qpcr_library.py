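"""Standard curves, efficiency math, LOD ratios, library combinatorics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from sympy import Rational, factorial
from sympy.functions.combinatorial.numbers import stirling

from amplifid import (
    LibrarySpec,
    MUTATION_SITES,
    VariantGenotype,
    enumerate_variants,
    expected_coverage,
    fit_standard_curve,
    lod_fold_change,
    mutation_enrichment,
    pcr_efficiency,
)
from amplifid.library import read_genotype_table
from amplifid.qpcr import StandardCurveModel

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # ~ -3.3219


class TestStandardCurve:
    def test_exact_fit_on_linear_points(self):
        points = [(10.0**k, -3.32 * k + 40.0) for k in range(1, 6)]
        curve = fit_standard_curve(points)
        assert curve.slope == pytest.approx(-3.32)
        assert curve.intercept == pytest.approx(40.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_replicates_averaged_before_regression(self):
        """Unbalanced replicates would skew a pooled fit; the curve must
        equal the fit on per-concentration averages."""
        rows = [
            (100.0, 30.0), (100.0, 31.0), (100.0, 35.0),  # avg 32
            (1000.0, 28.5),
            (10000.0, 25.0), (10000.0, 25.4),  # avg 25.2
        ]
        curve = fit_standard_curve(rows)
        from scipy.stats import linregress

        fit = linregress([2.0, 3.0, 4.0], [32.0, 28.5, 25.2])
        assert curve.slope == pytest.approx(fit.slope)
        assert curve.intercept == pytest.approx(fit.intercept)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(100.0, 30.0), (100.0, 31.0)])

    def test_noisy_curve_recovers_slope_within_3se(self):
        rng = np.random.default_rng(6)
        true_slope, true_b = PERFECT_SLOPE, 38.0
        concs = [10.0**k for k in range(1, 7)]
        points = [
            (c, true_slope * math.log10(c) + true_b + rng.normal(0, 0.2))
            for c in concs
            for _ in range(3)
        ]
        curve = fit_standard_curve(points)
        assert abs(curve.slope - true_slope) < 3 * max(curve.slope_stderr, 1e-6)

    def test_model_from_table(self, tmp_path):
        df = pd.DataFrame(
            {
                "target": ["N1"] * 4,
                "concentration": [10.0, 100.0, 1000.0, 10000.0],
                "replicate": [1, 1, 1, 1],
                "cq": [36.7, 33.4, 30.1, 26.8],
            }
        )
        path = tmp_path / "cq.tsv"
        df.to_csv(path, sep="\t", index=False)
        curve = StandardCurveModel.from_table(path).fit()
        assert curve.slope == pytest.approx(-3.3)
        assert "efficiency" in curve.summary()


class TestEfficiency:
    def test_perfect_doubling_slope_gives_exactly_100_percent(self):
        assert pcr_efficiency(PERFECT_SLOPE) == pytest.approx(1.0, abs=1e-12)

    def test_slope_minus_three_closed_form(self):
        assert pcr_efficiency(-3.0) == pytest.approx(10.0 ** (1.0 / 3.0) - 1.0)
        assert pcr_efficiency(-3.0) == pytest.approx(1.1544, abs=1e-4)

    def test_steep_slope_limit_is_zero(self):
        assert pcr_efficiency(-1e9) == pytest.approx(0.0, abs=1e-8)

    def test_nonnegative_slope_rejected(self):
        for m in (0.0, 3.3):
            with pytest.raises(ValueError):
                pcr_efficiency(m)


class TestLodFoldChange:
    @pytest.mark.parametrize(
        "ref,test,expected", [(2000, 20, 100.0), (50, 50, 1.0), (100, 20, 5.0)]
    )
    def test_ratios(self, ref, test, expected):
        assert lod_fold_change(ref, test) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lod_fold_change(0, 20)
        with pytest.raises(ValueError):
            lod_fold_change(100, -5)


class TestEnumerateVariants:
    @pytest.mark.parametrize("n,count", [(0, 1), (3, 8), (8, 256)])
    def test_counts(self, n, count):
        variants = enumerate_variants(n)
        assert len(variants) == count
        assert len({v.flags for v in variants}) == count  # all distinct

    def test_wild_type_and_full_mutant_present(self):
        variants = enumerate_variants(8)
        flags = {v.flags for v in variants}
        assert (False,) * 8 in flags
        assert (True,) * 8 in flags
        assert variants[0].sites == MUTATION_SITES

    def test_mutation_load(self):
        v = VariantGenotype("x", (True, False, True, False, False, False, False, True))
        assert v.mutation_load == 3
        assert v.mutations == ("L459M", "E507K", "M747K")


class TestExpectedCoverage:
    def test_library_scale_coverage_exceeds_99_percent(self):
        spec = LibrarySpec(n_sites=8, n_picks=2660)
        assert spec.variant_count == 256
        assert spec.oversampling_factor > 10
        cov = expected_coverage(256, 2660)
        assert cov.expected_fraction == pytest.approx(
            1.0 - (255.0 / 256.0) ** 2660
        )
        assert cov.expected_fraction > 0.99

    def test_zero_picks(self):
        assert expected_coverage(256, 0).expected_fraction == 0.0

    def test_monotone_in_picks_and_converges(self):
        fracs = [expected_coverage(256, n).expected_fraction
                 for n in (0, 100, 500, 2660, 20_000)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0, abs=1e-15)

    def test_expected_fraction_matches_monte_carlo(self):
        """Closed form within 3 SE of a direct sampling experiment."""
        rng = np.random.default_rng(31)
        V, N, reps = 256, 2660, 30_000
        fractions = np.empty(reps)
        chunk = 2_000
        done = 0
        while done < reps:
            k = min(chunk, reps - done)
            draws = rng.integers(0, V, size=(k, N))
            for i in range(k):
                fractions[done + i] = np.unique(draws[i]).size / V
            done += k
        se = fractions.std(ddof=1) / math.sqrt(reps)
        closed = expected_coverage(V, N).expected_fraction
        assert abs(closed - fractions.mean()) < 3 * se + 1e-9

    def test_full_coverage_probability_matches_stirling_exact(self):
        """Inclusion-exclusion equals the exact occupancy probability
        S(N,V) V! / V^N for a small case."""
        V, N = 4, 12
        exact = float(
            Rational(stirling(N, V, kind=2) * factorial(V), V**N)
        )
        cov = expected_coverage(V, N)
        assert cov.method == "inclusion-exclusion"
        assert cov.p_full_coverage == pytest.approx(exact, rel=1e-9)

    def test_full_coverage_at_library_scale_is_high(self):
        cov = expected_coverage(256, 2660)
        assert 0.98 < cov.p_full_coverage < 1.0

    def test_insufficient_picks_cannot_cover(self):
        assert expected_coverage(10, 5).p_full_coverage == 0.0

    def test_skewed_pool_covers_less_than_equimolar(self):
        """A non-equimolar pool wastes picks on common variants."""
        w = np.ones(16)
        w[0] = 50.0
        skewed = expected_coverage(16, 60, weights=w)
        uniform = expected_coverage(16, 60)
        assert skewed.expected_fraction < uniform.expected_fraction
        assert skewed.method == "monte-carlo"
        # uniform weights reproduce the closed form
        flat = expected_coverage(16, 60, weights=np.ones(16))
        assert flat.expected_fraction == pytest.approx(uniform.expected_fraction)


def random_genotypes(rng, n=40):
    out = []
    for i in range(n):
        flags = tuple(bool(b) for b in rng.integers(0, 2, size=8))
        label = "active" if rng.random() < 0.5 else "inactive"
        out.append(VariantGenotype(f"v{i}", flags, label))
    return out


class TestMutationEnrichment:
    def test_universal_mutation_has_frequency_one(self):
        genos = [
            VariantGenotype(f"v{i}", tuple(j == 5 for j in range(8)), "active")
            for i in range(4)
        ]
        result = mutation_enrichment(genos)
        assert result.site_frequencies.loc["I614K", "active"] == 1.0
        assert result.site_frequencies.loc["L459M", "active"] == 0.0

    def test_load_histogram(self):
        def with_load(i, k):
            return VariantGenotype(
                f"v{i}", tuple(j < k for j in range(8)), "inactive"
            )

        result = mutation_enrichment(
            [with_load(0, 3), with_load(1, 3), with_load(2, 2), with_load(3, 4)]
        )
        assert result.load_histograms["inactive"] == {2: 1, 3: 2, 4: 1}
        assert result.empty_groups == ["active"]
        assert math.isnan(result.site_frequencies.loc["L459M", "active"])

    def test_matches_recount_oracle_and_order_invariance(self):
        rng = np.random.default_rng(13)
        genos = random_genotypes(rng)
        result = mutation_enrichment(genos)
        for group in ("active", "inactive"):
            members = [g for g in genos if g.activity == group]
            assert result.group_sizes[group] == len(members)
            assert sum(result.load_histograms[group].values()) == len(members)
            for j, site in enumerate(MUTATION_SITES):
                manual = sum(g.flags[j] for g in members) / len(members)
                assert result.site_frequencies.loc[site, group] == pytest.approx(manual)
        shuffled = mutation_enrichment(list(rng.permutation(genos)))
        pd.testing.assert_frame_equal(
            result.site_frequencies, shuffled.site_frequencies
        )

    def test_unlabelled_genotype_rejected(self):
        with pytest.raises(ValueError):
            mutation_enrichment([VariantGenotype("v", (False,) * 8)])

    def test_genotype_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        genos = random_genotypes(rng, n=10)
        rows = []
        for g in genos:
            row = {"variant": g.variant_id, "activity": g.activity}
            row.update({s: int(f) for s, f in zip(g.sites, g.flags)})
            rows.append(row)
        path = tmp_path / "genos.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        loaded = read_genotype_table(path)
        assert [g.flags for g in loaded] == [g.flags for g in genos]
        assert [g.activity for g in loaded] == [g.activity for g in genos]
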