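import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taupattern.simulate import SimConfig, generate_expression
from taupattern.templates import (
    TEMPLATE_NAMES,
    assign_pattern,
    assign_patterns,
    canonical_templates,
    enrichment_null_rate,
    group_means,
    template_correlation,
    test_enrichment as run_enrichment_test,
)

from conftest import make_matrix

LYZ1_MEANS = (5.64, 6.65, 7.29, 6.03)


def pearson_oracle(x, y):
    """Hand-rolled Pearson: covariance over the product of standard deviations."""
    x, y = list(x), list(y)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


class TestCanonicalTemplates:
    def test_fixed_order_and_values(self):
        templates = canonical_templates()
        assert [t.name for t in templates] == list(TEMPLATE_NAMES)
        assert templates[0].values == (0, 0, 1, 0)
        assert [t.values for t in templates[1:]] == [
            (0, 0, 1, 1), (0, 1, 0, 1), (0, 1, 1, 2), (0, 1, 0, 0), (0, 0, 0, 1)
        ]

    def test_templates_pairwise_distinct_under_correlation(self):
        templates = canonical_templates()
        for i, a in enumerate(templates):
            for b in templates[i + 1:]:
                assert abs(template_correlation(a.values, b)) < 1


class TestTemplateCorrelation:
    def test_identity_and_mirror(self):
        t0 = canonical_templates()[0]
        assert template_correlation((0, 0, 1, 0), t0) == pytest.approx(1.0)
        assert template_correlation((1, 1, 0, 1), t0) == pytest.approx(-1.0)

    def test_lyz1_worked_example_matches_hand_oracle(self):
        """Printed group means vs the (0,0,1,0) template: plain Pearson r ~ 0.8181."""
        t0 = canonical_templates()[0]
        r = template_correlation(LYZ1_MEANS, t0)
        assert r == pytest.approx(pearson_oracle(LYZ1_MEANS, t0.values), abs=1e-12)
        assert r == pytest.approx(0.8181178, abs=1e-6)

    def test_constant_means_undefined(self):
        assert math.isnan(template_correlation((5, 5, 5, 5), canonical_templates()[0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        means=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        scale=st.floats(0.01, 100),
        shift=st.floats(-100, 100),
    )
    def test_invariant_to_positive_affine_maps_and_antisymmetric_under_negation(
        self, means, scale, shift
    ):
        t0 = canonical_templates()[0]
        r = template_correlation(means, t0)
        transformed = [scale * m + shift for m in means]
        r2 = template_correlation(transformed, t0)
        r_neg = template_correlation([-m for m in means], t0)
        if math.isnan(r):
            assert math.isnan(r2)
        else:
            assert r2 == pytest.approx(r, abs=1e-6)
            assert r_neg == pytest.approx(-r, abs=1e-9)


class TestAssignPattern:
    def test_affine_image_of_template_assigned_with_r_one(self):
        means = [0.7 * v + 6.0 for v in (0, 0, 1, 1)]
        a = assign_pattern(means)
        assert a.template == "resistant_to_tau_suppression"
        assert a.r == pytest.approx(1.0)
        assert a.direction == 1

    def test_mirror_match_gets_negative_direction(self):
        means = [-1.0 * v + 9.0 for v in (0, 0, 1, 0)]
        a = assign_pattern(means)
        assert a.template == "rescued_by_tau_reduction"
        assert a.direction == -1

    def test_constant_means_unassigned(self):
        a = assign_pattern((5, 5, 5, 5))
        assert not a.assigned and math.isnan(a.r)

    def test_lyz1_below_default_threshold_but_assigned_at_080(self):
        unassigned = assign_pattern(LYZ1_MEANS, r_min=0.85)
        assert not unassigned.assigned
        assert abs(unassigned.r) == pytest.approx(0.8181178, abs=1e-6)
        relaxed = assign_pattern(LYZ1_MEANS, r_min=0.80)
        assert relaxed.template == "rescued_by_tau_reduction"
        assert relaxed.direction == 1

    def test_tie_on_absolute_r_broken_by_canonical_order(self):
        templates = canonical_templates()
        # (0,1,1,0) correlates equally (|r|) with several templates; ensure the
        # winner is the earliest such template in canonical order
        a = assign_pattern((0, 1, 1, 0), templates)
        r_all = [template_correlation((0, 1, 1, 0), t) for t in templates]
        best = max(abs(r) for r in r_all)
        first = next(i for i, r in enumerate(r_all) if abs(r) == pytest.approx(best))
        if a.assigned:
            assert a.template == templates[first].name

    def test_vectorized_assignment_matches_scalar(self, rng):
        means = pd.DataFrame(rng.normal(7, 1, size=(50, 4)),
                             columns=["Non_Veh", "Non_Dox", "Tg_Veh", "Tg_Dox"])
        table = assign_patterns(means, r_min=0.85)
        for gene in means.index:
            single = assign_pattern(means.loc[gene], r_min=0.85)
            row = table.loc[gene]
            assert row["assigned"] == single.assigned
            if single.assigned:
                assert row["template"] == single.template
                assert row["direction"] == single.direction
                assert row["r"] == pytest.approx(single.r)

    def test_assigned_count_non_increasing_in_r_min(self, rng):
        means = pd.DataFrame(rng.normal(7, 1, size=(200, 4)))
        counts = [
            assign_patterns(means, r_min=r)["assigned"].sum()
            for r in (0.5, 0.7, 0.85, 0.95, 0.999)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGroupMeans:
    def test_single_sample_cells_return_raw_values(self, rng):
        values = rng.normal(7, 1, size=(3, 4))
        matrix = make_matrix(values, n_per_group=(1, 1, 1, 1))
        np.testing.assert_allclose(group_means(matrix).to_numpy(), values)

    def test_duplicate_sample_cell_averages(self):
        matrix = make_matrix([[4, 6, 5, 5, 5, 5, 5, 5]], n_per_group=(2, 2, 2, 2))
        assert group_means(matrix).iloc[0, 0] == pytest.approx(5.0)


def brute_force_binomial_tail(k, n, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestEnrichment:
    @pytest.mark.parametrize("n", range(1, 21))
    def test_binomial_pvalue_matches_brute_force_for_all_small_n(self, n):
        from taupattern.templates import binomial_upper_tail

        for k in range(0, n + 1):
            for p in (0.01, 1 / 6, 0.5, 0.9):
                assert binomial_upper_tail(k, n, p) == pytest.approx(
                    brute_force_binomial_tail(k, n, p), rel=1e-9, abs=1e-12
                )

    def test_exact_small_case_two_of_two(self):
        assignments = pd.DataFrame(
            {"template": ["dox_altered", "dox_altered"], "r": [1.0, 1.0],
             "direction": [1, 1], "assigned": [True, True]},
            index=["g1", "g2"],
        )
        p0 = pd.Series(0.5, index=list(TEMPLATE_NAMES))
        result = run_enrichment_test(assignments, p0)
        assert result.loc["dox_altered", "p_binomial"] == pytest.approx(0.25)

    def test_zero_assigned_gives_p_one(self):
        assignments = pd.DataFrame(
            {"template": [""], "r": [0.1], "direction": [0], "assigned": [False]},
            index=["g1"],
        )
        p0 = pd.Series(0.3, index=list(TEMPLATE_NAMES))
        result = run_enrichment_test(assignments, p0)
        assert (result["p_binomial"] == 1.0).all()
        assert (result["k"] == 0).all()


@pytest.fixture(scope="module")
def null_matrix():
    config = SimConfig(
        n_genes=400, planted_fraction=0.0, low_signal_fraction=0.0,
        ambiguous_fraction=0.0, unannotated_fraction=0.0, seed=3,
    )
    matrix, _ = generate_expression(config)
    return matrix


class TestEnrichmentNullRate:
    def test_extreme_threshold_drives_p0_to_floor(self, null_matrix):
        degs = list(null_matrix.genes[:100])
        null = enrichment_null_rate(
            null_matrix, degs, r_min=0.999, n_perm=20, seed=0, mode="fixed_degs"
        )
        # chance of |r| >= 0.999 against any template is ~0.1% per template
        assert (null.p0 <= 0.01).all()

    def test_identity_permutation_reproduces_observed_fractions(self, null_matrix):
        degs = list(null_matrix.genes[:150])
        means = group_means(null_matrix, degs)
        observed = assign_patterns(means, r_min=0.85)
        frac = observed.loc[observed["assigned"], "template"].value_counts() / len(degs)
        null = enrichment_null_rate(
            null_matrix, degs, r_min=0.85, mode="fixed_degs",
            permutations=[np.arange(len(null_matrix.samples))],
        )
        for name in TEMPLATE_NAMES:
            assert null.p0[name] == pytest.approx(
                max(frac.get(name, 0.0), 1 / 150), abs=1e-12
            )

    def test_null_rates_reproducible_and_sum_below_one(self, null_matrix):
        degs = list(null_matrix.genes[:100])
        a = enrichment_null_rate(null_matrix, degs, n_perm=10, seed=5, mode="fixed_degs")
        b = enrichment_null_rate(null_matrix, degs, n_perm=10, seed=5, mode="fixed_degs")
        pd.testing.assert_series_equal(a.p0, b.p0)
        assert a.p0.sum() <= 1.0
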