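"""Pairwise and multiple-site dissimilarity partitioning.

The brute-force oracles here (explicit double-loop membership counts,
Fraction arithmetic) are deliberately independent of the implementation
they check.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxbeta.community import IncidenceMatrix
from taxbeta.dissimilarity import (
    BetaPartition,
    PairComponents,
    contribution_percentages,
    multi_site,
    pair_components,
    pairwise_table,
    partition,
    square_matrix,
    taxonomic_partition,
)
from taxbeta.errors import UndefinedValueWarning, ValidationError
from taxbeta.synthetic import two_site_contrast


def brute_components(A, B):
    """Oracle: explicit double-loop membership counting."""
    a = sum(1 for x in A if x in B)
    b = sum(1 for x in A if x not in B)
    c = sum(1 for x in B if x not in A)
    return (a, b, c)


def brute_partition(a, b, c):
    """Oracle: exact rational arithmetic from the defining formulas."""
    n = Fraction(a + b + c)
    return (
        Fraction(b + c) / n,
        Fraction(2 * min(b, c)) / n,
        Fraction(abs(b - c)) / n,
    )


class TestPairComponents:
    @pytest.mark.parametrize(
        "A,B,expected",
        [
            ({"s1", "s2", "s3", "s4"}, {"s1", "s2", "s5"}, (2, 2, 1)),
            ({"x", "y"}, {"x", "y"}, (2, 0, 0)),
            (set(), {"x"}, (0, 0, 1)),
        ],
    )
    def test_set_algebra(self, A, B, expected):
        assert pair_components(A, B) == expected

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        universe = [f"e{i}" for i in range(40)]
        for _ in range(50):
            A = set(rng.choice(universe, size=20, replace=False))
            B = set(rng.choice(universe, size=20, replace=False))
            assert tuple(pair_components(A, B)) == brute_components(A, B)


class TestPartition:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ((2, 2, 1), (0.6, 0.4, 0.2)),
            ((0, 2, 3), (1.0, 0.8, 0.2)),
            ((5, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_worked_examples(self, comp, expected):
        result = partition(PairComponents(*comp))
        assert result == pytest.approx(expected, abs=1e-12)

    def test_empty_pair_is_nan_with_warning(self):
        with pytest.warns(UndefinedValueWarning):
            result = partition(PairComponents(0, 0, 0))
        assert all(math.isnan(v) for v in result)

    def test_negative_components_rejected(self):
        with pytest.raises(ValidationError):
            partition(PairComponents(1, -1, 0))

    @settings(derandomize=True, max_examples=500)
    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_additivity_range_symmetry(self, comp):
        bcc, b3, brich = partition(PairComponents(*comp))
        assert b3 + brich == pytest.approx(bcc, abs=1e-12)
        assert 0.0 <= b3 <= bcc <= 1.0 and 0.0 <= brich <= bcc
        a, b, c = comp
        assert partition(PairComponents(a, c, b)) == partition(PairComponents(a, b, c))
        # total dissimilarity is 1 iff nothing is shared
        assert (bcc == 1.0) == (a == 0)
        # exact-rational oracle
        oracle = brute_partition(a, b, c)
        assert (bcc, b3, brich) == pytest.approx(
            tuple(float(x) for x in oracle), abs=1e-15
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_sharing_one_more_element_never_raises_dissimilarity(self, comp):
        a, b, c = comp
        before = partition(PairComponents(a, b, c)).beta_cc
        after = partition(PairComponents(a + 1, b, c)).beta_cc
        assert after <= before + 1e-15


class TestTaxonomicPartition:
    def test_contrasting_structures_same_species_dissimilarity(self):
        """15 species with a 4/6/5 shared/exclusive split give identical
        species-level dissimilarity, but the taxonomic value drops to
        11/26 when every genus and family spans both sites and rises to
        20/26 when only one genus and one family are shared."""
        results = {}
        for case in ("shared-higher", "unshared-higher"):
            A, B, tax = two_site_contrast(case)
            assert partition(pair_components(A, B)).beta_cc == pytest.approx(11 / 15)
            results[case] = taxonomic_partition(A, B, tax)
        assert results["shared-higher"].beta_cc == pytest.approx(11 / 26, abs=5e-4)
        assert results["unshared-higher"].beta_cc == pytest.approx(20 / 26, abs=5e-4)
        assert round(results["shared-higher"].beta_cc, 3) == 0.423
        assert round(results["unshared-higher"].beta_cc, 3) == 0.769

    def test_identical_species_lists_are_identical_at_every_rank(self):
        A, _, tax = two_site_contrast("shared-higher")
        assert taxonomic_partition(A, A, tax) == (0.0, 0.0, 0.0)

    def test_species_dissimilarity_does_not_bound_taxonomic(self):
        """A ragged classification can push taxonomic dissimilarity above
        species dissimilarity: the code must not enforce the study's
        empirical pattern (species >= taxonomic) as an invariant."""
        from taxbeta.community import TaxonomyTable

        df = pd.DataFrame(
            [
                ("", "", "s1"),  # shared species with no higher taxa applicable
                ("famB", "genB", "s2"),
                ("famC", "genC", "s3"),
            ],
            columns=["family", "genus", "species"],
        )
        tax = TaxonomyTable(group="g", ranks=("family", "genus", "species"), assignments=df)
        A, B = {"s1", "s2"}, {"s1", "s3"}
        species_beta = partition(pair_components(A, B)).beta_cc
        taxo_beta = taxonomic_partition(A, B, tax).beta_cc
        assert species_beta == pytest.approx(2 / 3)
        assert taxo_beta == pytest.approx(6 / 7)
        assert taxo_beta > species_beta


class TestPairwiseTable:
    @pytest.mark.parametrize("n_sites,n_pairs", [(3, 3), (6, 15)])
    def test_pair_count(self, n_sites, n_pairs):
        rng = np.random.default_rng(7)
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n_sites, 10)),
            index=[f"S{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(10)],
        )
        presence.iloc[:, 0] = 1  # no empty sites
        inc = IncidenceMatrix(group="g", presence=presence)
        assert len(pairwise_table(inc)) == n_pairs

    def test_matches_composition_pair_by_pair(self, three_site_incidence):
        table = pairwise_table(three_site_incidence)
        for row in table.itertuples(index=False):
            A = three_site_incidence.site_species(row.site_i)
            B = three_site_incidence.site_species(row.site_j)
            expected = partition(pair_components(A, B))
            assert (row.beta_cc, row.beta_3, row.beta_rich) == pytest.approx(expected)

    def test_pairs_with_empty_site_are_missing(self):
        presence = pd.DataFrame(
            [[1, 1], [0, 0], [0, 1]], index=["A", "B", "C"], columns=["s1", "s2"]
        )
        inc = IncidenceMatrix(group="g", presence=presence)
        with pytest.warns(UndefinedValueWarning):
            table = pairwise_table(inc)
        missing = table[table["beta_cc"].isna()]
        assert set(map(tuple, missing[["site_i", "site_j"]].values)) == {
            ("A", "B"),
            ("B", "C"),
        }

    def test_fewer_than_two_sites_rejected(self):
        presence = pd.DataFrame([[1]], index=["A"], columns=["s1"])
        inc = IncidenceMatrix(group="g", presence=presence)
        with pytest.raises(ValidationError):
            pairwise_table(inc)

    def test_square_matrix_is_symmetric_with_zero_diagonal(self, three_site_incidence):
        mat = square_matrix(pairwise_table(three_site_incidence))
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)


class TestMultiSite:
    def test_three_site_worked_example(self, three_site_incidence):
        """A={1,2}, B={2,3}, C={3,4}: summed components give a pure-turnover
        total of 0.8 (sum a = 2, sum b+c = 8, sum 2min = 8, sum |b-c| = 0)."""
        msb = multi_site(three_site_incidence, level="species")
        assert (msb.beta_cc, msb.beta_3, msb.beta_rich) == pytest.approx((0.8, 0.8, 0.0))
        assert msb.T == 3
        assert msb.contribution_turnover == pytest.approx(100.0)

    @pytest.mark.parametrize("variant", ["component-sum", "pair-mean"])
    def test_two_sites_reduce_to_pairwise(self, variant):
        presence = pd.DataFrame(
            [[1, 1, 1, 1, 0], [1, 1, 0, 0, 1]], index=["A", "B"],
            columns=list("pqrst"),
        )
        inc = IncidenceMatrix(group="g", presence=presence)
        msb = multi_site(inc, level="species", variant=variant)
        pw = partition(pair_components(inc.site_species("A"), inc.site_species("B")))
        assert msb.partition == pytest.approx(pw)

    def test_identical_sites_zero_total_nan_contributions(self):
        presence = pd.DataFrame(
            [[1, 1], [1, 1], [1, 1]], index=["A", "B", "C"], columns=["s1", "s2"]
        )
        inc = IncidenceMatrix(group="g", presence=presence)
        with pytest.warns(UndefinedValueWarning):
            msb = multi_site(inc, level="species")
        assert msb.beta_cc == 0.0
        assert math.isnan(msb.contribution_turnover)

    def test_component_sum_additivity(self, three_site_incidence):
        msb = multi_site(three_site_incidence, level="species")
        assert msb.beta_3 + msb.beta_rich == pytest.approx(msb.beta_cc, abs=1e-12)

    def test_unknown_variant_rejected(self, three_site_incidence):
        with pytest.raises(ValueError):
            multi_site(three_site_incidence, variant="geometric")


class TestContributions:
    @pytest.mark.parametrize(
        "bcc,b3,expected",
        [(0.8, 0.8, (100.0, 0.0)), (0.5, 0.25, (50.0, 50.0))],
    )
    def test_splits(self, bcc, b3, expected):
        part = BetaPartition(bcc, b3, bcc - b3)
        pct = contribution_percentages(part)
        assert pct == pytest.approx(expected)
        assert sum(pct) == pytest.approx(100.0, abs=0.01)

    def test_zero_total_is_undefined(self):
        with pytest.warns(UndefinedValueWarning):
            pct = contribution_percentages(BetaPartition(0.0, 0.0, 0.0))
        assert all(math.isnan(v) for v in pct)


def test_pairwise_equals_brute_force_on_many_random_communities():
    """End-to-end oracle sweep: random small communities, explicit set
    enumeration vs the vectorized pairwise table."""
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n_sites = int(rng.integers(2, 6))
        n_species = int(rng.integers(3, 15))
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n_sites, n_species)),
            index=[f"S{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(n_species)],
        )
        presence.iloc[:, 0] = 1
        inc = IncidenceMatrix(group="g", presence=presence)
        table = pairwise_table(inc)
        for row in table.itertuples(index=False):
            A = {c for c in presence.columns if presence.at[row.site_i, c]}
            B = {c for c in presence.columns if presence.at[row.site_j, c]}
            a, b, c = brute_components(A, B)
            assert (row.a, row.b, row.c) == (a, b, c)
            expected = tuple(float(x) for x in brute_partition(a, b, c))
            assert (row.beta_cc, row.beta_3, row.beta_rich) == pytest.approx(expected)
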