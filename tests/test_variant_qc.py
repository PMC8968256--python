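from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from genocurate import variant_qc
from genocurate.geno_io import MISSING, subset
from genocurate.simdata import SimConfig, simulate_collection

from conftest import make_matrix


def exact_fisher_left_tail(n_het, n_hom_ref, n_hom_alt, n_missing):
    """Exhaustive hypergeometric enumeration with exact integer arithmetic.

    Left-tail P(X <= n_het) for the 2x2 allele-presence table with fixed
    margins (ref carriers = het + hom_ref, alt carriers = het + hom_alt,
    population = all accessions).
    """
    N = n_het + n_hom_ref + n_hom_alt + n_missing
    K = n_het + n_hom_ref
    n = n_het + n_hom_alt
    denom = comb(N, n)
    num = sum(comb(K, x) * comb(N - K, n - x)
              for x in range(max(0, n - (N - K)), n_het + 1))
    return float(Fraction(num, denom))


class TestSiteStats:
    def test_direct_counts(self):
        G = make_matrix([[0], [2], [2]])
        s = variant_qc.site_stats(G)
        assert s.alt_freq[0] == pytest.approx(4 / 6)
        assert s.maf[0] == pytest.approx(1 / 3)
        assert s.het_rate[0] == 0

    def test_missing_excluded_from_frequencies(self):
        G = make_matrix([[1], [MISSING], [2]])
        s = variant_qc.site_stats(G)
        assert s.alt_freq[0] == pytest.approx(3 / 4)
        assert s.maf[0] == pytest.approx(0.25)
        assert s.missing_rate[0] == pytest.approx(1 / 3)
        assert s.het_rate[0] == pytest.approx(1 / 2)

    def test_all_missing_flagged_undefined(self):
        G = make_matrix([[MISSING], [MISSING]])
        s = variant_qc.site_stats(G)
        assert bool(s.undefined[0]) and np.isnan(s.maf[0])


class TestFisherFilter:
    def test_complete_cooccurrence_never_significant(self):
        # 10 hets, nothing else: alleles perfectly co-occur, P = 1
        p = variant_qc.fisher_disassociation_pvalues(
            np.array([10]), np.array([0]), np.array([0]), np.array([0]))
        assert p[0] == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        p = variant_qc.fisher_disassociation_pvalues(
            np.array([0]), np.array([5]), np.array([5]), np.array([5]))
        assert p[0] == pytest.approx(
            exact_fisher_left_tail(0, 5, 5, 5), abs=1e-12)

    def test_large_disassociated_site_kept(self):
        p = variant_qc.fisher_disassociation_pvalues(
            np.array([0]), np.array([200]), np.array([200]), np.array([0]))
        assert p[0] < 1e-3

    def test_matches_scipy_fisher_exact(self, rng):
        """Independent route: scipy's Fisher exact with alternative='less'."""
        for _ in range(50):
            het, hr, ha, ms = rng.integers(0, 15, size=4)
            ours = variant_qc.fisher_disassociation_pvalues(
                np.array([het]), np.array([hr]), np.array([ha]), np.array([ms]))[0]
            ref = stats.fisher_exact([[het, hr], [ha, ms]],
                                     alternative="less")[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_alpha_validated(self, toy_matrix):
        with pytest.raises(ValueError, match="alpha"):
            variant_qc.fisher_disassociation_filter(toy_matrix, alpha=1.5)

    def test_separates_true_sites_from_paralog_artifacts(self, rng):
        """Inbred biallelic sites pass; sites with independent allele
        presence (collapsed-paralog signature) are removed."""
        N, L = 200, 300
        p = rng.uniform(0.1, 0.9, L)
        true_calls = np.where(rng.random((N, L)) < p, 2, 0).astype(np.int8)
        err = rng.random((N, L)) < 0.01
        true_calls[err] = 1
        # artifact sites: ref and alt presence drawn independently
        ref_present = rng.random((N, L)) < 0.5
        alt_present = rng.random((N, L)) < 0.5
        art_calls = np.full((N, L), MISSING, dtype=np.int8)
        art_calls[ref_present & ~alt_present] = 0
        art_calls[~ref_present & alt_present] = 2
        art_calls[ref_present & alt_present] = 1
        G = make_matrix(np.hstack([true_calls, art_calls]))
        kept, _ = variant_qc.fisher_disassociation_filter(G, alpha=0.001)
        kept = set(kept)
        true_kept = sum(j in kept for j in range(L)) / L
        art_removed = sum(j + L not in kept for j in range(L)) / L
        assert true_kept >= 0.99
        assert art_removed >= 0.95


class TestSiteFilters:
    def test_thresholds_are_strict(self):
        # maf exactly at the bound fails "maf > maf_min"
        G = make_matrix(np.array([[0] * 99 + [2]]).T.reshape(100, 1))
        s = variant_qc.site_stats(G)
        assert s.maf[0] == pytest.approx(0.01)
        kept, _ = variant_qc.filter_sites(G, maf_min=0.01)
        assert len(kept) == 0

    def test_kept_set_matches_bruteforce(self, rng):
        G = make_matrix(rng.choice([0, 1, 2, MISSING], size=(40, 10),
                                   p=[0.45, 0.05, 0.3, 0.2]))
        kept, _ = variant_qc.filter_sites(G)
        s = variant_qc.site_stats(G)
        expected = [j for j in range(10)
                    if not s.undefined[j] and s.maf[j] > 0.01
                    and s.missing_rate[j] < 0.30 and s.het_rate[j] < 0.10]
        assert list(kept) == expected

    def test_rerun_is_noop(self, rng):
        G = make_matrix(rng.choice([0, 1, 2, MISSING], size=(40, 30),
                                   p=[0.45, 0.05, 0.3, 0.2]))
        kept, _ = variant_qc.filter_sites(G)
        G1 = subset(G, site_indices=kept)
        kept2, _ = variant_qc.filter_sites(G1)
        assert len(kept2) == G1.n_sites


class TestAccessionFilter:
    def test_boundary_is_inclusive(self):
        # exactly 55% missing is kept (removal rule is strict ">")
        calls = np.zeros((2, 20), dtype=np.int8)
        calls[0, :11] = MISSING  # 55%
        calls[1, :12] = MISSING  # 60%
        G = make_matrix(calls)
        kept, rep = variant_qc.filter_accessions(G, missing_max=0.55)
        assert kept == [G.accession_ids[0]]
        assert rep.accessions_out == 1


class TestSingleHetFixedRule:
    @pytest.mark.parametrize("n,extra_hets,expect_removed", [
        (150, 0, True),   # one het, otherwise fixed, large group
        (150, 1, False),  # two hets: kept
        (50, 0, False),   # small group: rule not applied
    ])
    def test_rule_gating(self, n, extra_hets, expect_removed):
        calls = np.zeros((n, 1), dtype=np.int8)
        calls[0, 0] = 1
        if extra_hets:
            calls[1, 0] = 1
        G = make_matrix(calls)
        kept, _ = variant_qc.drop_single_het_fixed(G, min_population=100)
        assert (len(kept) == 0) == expect_removed


class TestModeImpute:
    def test_mode_and_tie_rule(self):
        G = make_matrix([[0], [0], [2], [MISSING]])
        assert variant_qc.mode_impute(G).calls[3, 0] == 0
        G = make_matrix([[0], [2], [MISSING]])
        assert variant_qc.mode_impute(G).calls[2, 0] == 0  # tie -> lower code

    def test_complete_matrix_unchanged(self, rng):
        G = make_matrix(rng.choice([0, 1, 2], size=(5, 8)))
        assert np.array_equal(variant_qc.mode_impute(G).calls, G.calls)

    def test_all_missing_site_rejected(self):
        G = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="entirely missing"):
            variant_qc.mode_impute(G)
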