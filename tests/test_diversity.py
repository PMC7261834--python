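import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrdem.diversity import (
    _rarefied_richness,
    allelic_richness,
    group_summary,
    locus_summary,
    null_allele_rate,
)
from ssrdem.io_formats import MISSING, GenotypeMatrix, Partition

from conftest import random_matrix


def matrix_from_calls(calls_per_locus):
    """Build a matrix from {locus: [(a, b), ...]} with equal lengths."""
    loci = list(calls_per_locus)
    n = len(calls_per_locus[loci[0]])
    arr = np.array([[calls_per_locus[l][i] for l in loci] for i in range(n)])
    return GenotypeMatrix(tuple(f"i{i}" for i in range(n)), tuple(loci), arr)


class TestLocusSummary:
    def test_hand_computed_example(self):
        g = matrix_from_calls({"L1": [(1, 1), (1, 2)]})
        df, _ = locus_summary(g, rarefaction_g=None)
        row = df.iloc[0]
        assert row["N_A"] == 2
        assert row["N_E"] == pytest.approx(1.6)
        assert row["H_O"] == pytest.approx(0.5)
        assert row["H_E"] == pytest.approx(0.5)          # (4/3) * 0.375
        assert row["I"] == pytest.approx(0.5623, abs=1e-4)
        assert row["major_allele_freq"] == pytest.approx(0.75)

    def test_monomorphic_locus(self):
        g = matrix_from_calls({"L1": [(3, 3), (3, 3)]})
        df, _ = locus_summary(g, rarefaction_g=None)
        row = df.iloc[0]
        assert row["N_A"] == 1 and row["N_E"] == 1
        assert row["I"] == 0 and row["H_O"] == 0 and row["H_E"] == 0
        assert np.isnan(row["F_IS"])

    def test_entirely_missing_locus_skipped(self):
        g = matrix_from_calls({
            "L1": [(1, 2), (1, 1)],
            "L2": [(MISSING, MISSING), (MISSING, MISSING)],
        })
        with pytest.warns(UserWarning, match="entirely missing"):
            df, avg = locus_summary(g, rarefaction_g=None)
        assert list(df.index) == ["L1"]
        assert avg["n_loci"] == 1

    def test_ne_at_most_na_with_equality_iff_equifrequent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_matrix(rng, n=30, L=4, n_alleles=5)
            df, _ = locus_summary(g, rarefaction_g=None)
            assert (df["N_E"] <= df["N_A"] + 1e-12).all()
        g_eq = matrix_from_calls({"L1": [(1, 2), (1, 2)]})
        df_eq, _ = locus_summary(g_eq, rarefaction_g=None)
        assert df_eq["N_E"].iloc[0] == pytest.approx(df_eq["N_A"].iloc[0])

    def test_unbiased_he_is_unbiased(self):
        # sampling n=10 individuals from p=(0.7,0.3): E[H_E] = 1 - sum p^2
        rng = np.random.default_rng(42)
        target = 1 - (0.7**2 + 0.3**2)
        vals = []
        for _ in range(1000):
            copies = rng.choice([1, 2], size=20, p=[0.7, 0.3])
            calls = copies.reshape(10, 2)[:, None, :]
            g = GenotypeMatrix(tuple(f"i{i}" for i in range(10)), ("L",), calls)
            df, _ = locus_summary(g, rarefaction_g=None)
            if not np.isnan(df["H_E"].iloc[0]):
                vals.append(df["H_E"].iloc[0])
        assert np.mean(vals) == pytest.approx(target, abs=0.01)


class TestAllelicRichness:
    def test_full_sample_equals_na(self):
        g = matrix_from_calls({"L1": [(1, 2), (3, 4), (5, 5)]})
        df, _ = locus_summary(g, rarefaction_g=6)
        assert df["A_R"].iloc[0] == pytest.approx(df["N_A"].iloc[0])

    def test_exhaustive_subsample_oracle(self):
        # counts (5, 3, 2), g = 5: mean distinct alleles over all C(10, 5)
        counts = np.array([5, 3, 2])
        copies = [0] * 5 + [1] * 3 + [2] * 2
        brute = np.mean([
            len({copies[i] for i in sub})
            for sub in itertools.combinations(range(10), 5)
        ])
        assert _rarefied_richness(counts, 5) == pytest.approx(brute)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(1, 5), min_size=1, max_size=4),
        g_copies=st.integers(2, 12),
    )
    def test_oracle_property_small_instances(self, counts, g_copies):
        total = sum(counts)
        if g_copies > total:
            g_copies = total
        if g_copies < 2:
            return
        copies = [a for a, c in enumerate(counts) for _ in range(c)]
        brute = np.mean([
            len({copies[i] for i in sub})
            for sub in itertools.combinations(range(total), g_copies)
        ])
        assert _rarefied_richness(np.array(counts), g_copies) == pytest.approx(brute)

    def test_monotone_in_g(self):
        counts = np.array([8, 4, 2, 1])
        vals = [_rarefied_richness(counts, g) for g in range(2, 16)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bad_rarefaction_size(self):
        g = matrix_from_calls({"L1": [(1, 2), (1, 1)]})
        with pytest.raises(ValueError):
            allelic_richness(g, rarefaction_g=1)

    def test_auto_uses_smallest_group_locus_cell(self):
        g = matrix_from_calls({
            "L1": [(1, 2), (1, 1), (2, 2), (1, 2)],
            "L2": [(1, 2), (MISSING, MISSING), (2, 2), (1, 2)],
        })
        p = Partition({"i0": "a", "i1": "a", "i2": "b", "i3": "b"})
        df = allelic_richness(g, p, "auto")
        assert df.attrs["rarefaction_g"] == 2  # group a at L2: one individual


class TestGroupSummary:
    def test_identical_groups_share_everything(self):
        g = matrix_from_calls({"L1": [(1, 2), (1, 2), (1, 2), (1, 2)]})
        p = Partition({"i0": "a", "i1": "a", "i2": "b", "i3": "b"})
        gs = group_summary(g, p)
        assert (gs["private"] == 0).all()

    def test_singleton_allele_is_private_and_unique(self):
        g = matrix_from_calls({
            "L1": [(1, 2), (1, 2), (1, 1), (1, 9)],  # allele 9 once, in i3
        })
        p = Partition({"i0": "a", "i1": "a", "i2": "b", "i3": "b"})
        gs = group_summary(g, p)
        assert gs.loc["b", "private"] >= 1   # allele 9 confined to group b
        assert gs.loc["b", "unique"] == 1    # carried by one accession only
        assert gs.loc["a", "unique"] == 0    # allele 2 occurs in two accessions

    def test_small_group_excluded_with_warning(self):
        g = matrix_from_calls({"L1": [(1, 2), (1, 2), (2, 2)]})
        p = Partition({"i0": "a", "i1": "a", "i2": "solo"})
        with pytest.warns(UserWarning, match="excluded"):
            gs = group_summary(g, p)
        assert list(gs.index) == ["a"]


class TestNullAlleleRate:
    def test_no_deficit_and_floor(self):
        assert null_allele_rate(0.5, 0.5) == 0.0
        assert null_allele_rate(0.8, 0.5) == 0.0

    def test_printed_table_values(self):
        assert null_allele_rate(0.132, 0.299) == pytest.approx(0.1286, abs=1e-4)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            null_allele_rate(-0.1, 0.5)


class TestFisPermutation:
    def test_pvalue_small_under_strong_deficit(self):
        # all homozygotes but polymorphic: extreme heterozygote deficit
        g = matrix_from_calls({"L1": [(1, 1)] * 10 + [(2, 2)] * 10})
        df, _ = locus_summary(g, rarefaction_g=None, n_perm=199, seed=0)
        assert df["F_IS_p"].iloc[0] < 0.02

    def test_type_one_error_control(self):
        # panmictic HWE data: rejection rate at alpha=0.05 over 200 loci
        rng = np.random.default_rng(8)
        rejections = 0
        n_loci = 200
        for i in range(n_loci):
            copies = rng.integers(1, 5, size=100)
            calls = copies.reshape(50, 2)[:, None, :]
            g = GenotypeMatrix(tuple(f"i{j}" for j in range(50)), ("L",), calls)
            df, _ = locus_summary(g, rarefaction_g=None, n_perm=99,
                                  seed=int(rng.integers(2**31 - 1)))
            p = df["F_IS_p"].iloc[0]
            if np.isfinite(p) and p <= 0.05:
                rejections += 1
        assert rejections / n_loci == pytest.approx(0.05, abs=0.04)
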