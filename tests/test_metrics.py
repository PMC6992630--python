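"""Density, clonality and richness contracts against independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrrep import metrics
from tcrrep.repertoire import Clone, RepertoireSample


def brute_force_expected_unique(counts, t):
    """Enumerate every without-replacement subsample of size t."""
    pop = [i for i, c in enumerate(counts) for _ in range(c)]
    vals = [len({pop[j] for j in comb}) for comb in itertools.combinations(range(len(pop)), t)]
    return sum(vals) / len(vals)


def partitions(n, maxpart=None):
    if maxpart is None:
        maxpart = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, maxpart), 0, -1):
        for rest in partitions(n - first, first):
            yield (first,) + rest


class TestClonality:
    def test_hand_derived_entropy_example(self):
        # two clones at 80/20 templates: H' = -(0.8 ln 0.8 + 0.2 ln 0.2)
        h = -(0.8 * math.log(0.8) + 0.2 * math.log(0.2))
        expected = 1 - h / math.log(2)
        assert metrics.clonality([80, 20]) == pytest.approx(expected, abs=1e-12)
        assert metrics.clonality([80, 20]) == pytest.approx(0.2781, abs=1e-4)

    def test_even_repertoire_has_zero_clonality(self):
        assert metrics.clonality([50, 50]) == 0.0
        assert metrics.clonality([7] * 23) == 0.0

    def test_monoclonal_convention_and_empty(self):
        assert metrics.clonality([42]) == 1.0
        assert math.isnan(metrics.clonality([]))

    def test_dominance_drives_clonality_toward_one(self):
        values = [metrics.clonality([int(10**k), 1, 1, 1]) for k in range(1, 7)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[-1] > 0.95

    @settings(deadline=None, max_examples=150)
    @given(
        st.lists(st.integers(1, 10_000), min_size=2, max_size=30),
        st.integers(2, 1000),
    )
    def test_scale_invariance_and_range(self, counts, factor):
        base = metrics.clonality(counts)
        scaled = metrics.clonality([c * factor for c in counts])
        assert 0.0 <= base <= 1.0
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_matches_frequency_form(self):
        counts = np.array([5, 9, 1, 30])
        assert metrics.clonality(counts) == pytest.approx(
            metrics.clonality_from_frequencies(counts / counts.sum()), abs=1e-12
        )


class TestDensity:
    def test_direct_ratio(self):
        s = RepertoireSample.from_counts("s", {"CASSF": 500}, usable_input=2000.0)
        assert metrics.density(s) == 0.25

    def test_zero_templates(self):
        s = RepertoireSample("s", cdr3_aa=[], v_gene=[], j_gene=[], templates=[],
                             usable_input=100.0)
        assert metrics.density(s) == 0.0

    def test_missing_denominator_is_absent_not_zero(self):
        s = RepertoireSample.from_counts("s", {"CASSF": 500})
        assert math.isnan(metrics.density(s))

    def test_above_one_clipped_with_warning(self):
        s = RepertoireSample.from_counts("s", {"CASSF": 500}, usable_input=100.0)
        assert metrics.density(s) == 1.0
        assert any("clipped" in w for w in s.warnings)


class TestRichnessInterpolation:
    @pytest.mark.parametrize("n", range(2, 10))
    def test_matches_exhaustive_enumeration(self, n):
        for counts in partitions(n):
            if len(counts) < 2:
                continue
            for t in range(1, n):
                exact = metrics.expected_unique_subsample(np.array(counts), t)
                brute = brute_force_expected_unique(counts, t)
                assert exact == pytest.approx(brute, abs=1e-9), (counts, t)

    def test_spec_toy_example(self):
        # counts (5,3,2), t=2: enumeration over all C(10,2) subsamples
        assert metrics.expected_unique_subsample(np.array([5, 3, 2]), 2) == pytest.approx(
            brute_force_expected_unique((5, 3, 2), 2), abs=1e-12
        )

    def test_large_sample_loggamma_branch_agrees_with_exact(self):
        rng = np.random.default_rng(0)
        counts = rng.geometric(0.05, size=40)
        counts = np.append(counts, 1200)  # push total over the exact-path cutoff
        assert counts.sum() > 1000 and (counts > 0).all()
        t = 500
        log_branch = metrics.expected_unique_subsample(counts, t)
        # exact integer path, forced
        from fractions import Fraction

        n = int(counts.sum())
        denom = math.comb(n, t)
        exact = sum(
            1.0 if n - int(c) < t else 1.0 - float(Fraction(math.comb(n - int(c), t), denom))
            for c in counts
        )
        assert log_branch == pytest.approx(exact, rel=1e-9)


class TestRichnessExtrapolation:
    def test_identity_at_observed_depth(self):
        counts = np.array([40, 25, 20, 10, 5])
        est = metrics.richness_extrapolated(counts, int(counts.sum()))
        assert est.value == pytest.approx(5, abs=1e-9)
        assert est.method == "interpolation"

    def test_monotone_in_target_and_continuous_at_depth(self):
        rng = np.random.default_rng(5)
        counts = rng.multinomial(2000, np.ones(400) / 400)
        counts = counts[counts > 0]
        n = int(counts.sum())
        targets = [n // 2, n - 1, n, n + 1, 2 * n, 5 * n, 10 * n]
        values = [metrics.richness_extrapolated(counts, t).value for t in targets]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        at_n = values[targets.index(n)]
        just_above = values[targets.index(n + 1)]
        assert abs(just_above - at_n) < 1.0

    def test_tenfold_extrapolation_tracks_monte_carlo_truth(self):
        rng = np.random.default_rng(11)
        f = np.ones(300) / 300
        counts = rng.multinomial(1200, f)
        est = metrics.richness_extrapolated(counts[counts > 0], 12_000)
        mc = np.mean([(rng.multinomial(12_000, f) > 0).sum() for _ in range(100)])
        assert est.value == pytest.approx(mc, rel=0.10)

    def test_shallow_sample_flagged_absent(self):
        est = metrics.richness_extrapolated(np.array([3, 2, 1]), 1000, min_templates=100)
        assert math.isnan(est.value)
        assert est.flagged

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            metrics.richness_extrapolated(np.array([5, 5]), 0)


class TestRepertoireMetricsSummary:
    def test_clonality_identity_links_entropy_and_richness(self, random_sample_factory):
        sample = random_sample_factory(seed=9, n=60, compartment="TUMOR")
        m = metrics.repertoire_metrics(sample, extrapolation_target=200, min_templates=10)
        assert m.clonality == pytest.approx(
            1 - m.shannon_entropy / math.log(m.richness_observed), abs=1e-12
        )

    def test_pbmc_uses_pbmc_default_target(self):
        s = RepertoireSample.from_counts(
            "s", {f"C{i}F": 5 for i in range(40)}, compartment="PBMC", usable_input=1000.0
        )
        m = metrics.repertoire_metrics(s)
        assert m.extrapolation_target == 400_000
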