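import numpy as np
import pytest

from genocurate import geno_io, popstats, simdata
from genocurate.geno_io import MISSING
from genocurate.simdata import (DuplicateSpec, SimConfig, SimTruth, SweepSpec,
                                draw_subpop_freqs, sample_genotypes,
                                apply_artifacts, simulate_collection,
                                write_collection)


class TestSubpopFreqs:
    def test_moments_match_balding_nichols(self, rng):
        L, F = 20000, 0.2
        p0, P = draw_subpop_freqs(L, 1, [F], rng)
        err = P[0] - p0
        assert abs(err.mean()) < 0.005  # E[p_k] = p0
        v = err ** 2 / (p0 * (1 - p0))
        assert v.mean() == pytest.approx(F, abs=0.01)  # Var = F p0 (1-p0)

    def test_small_f_concentrates_at_ancestral(self, rng):
        p0, P = draw_subpop_freqs(5000, 1, [0.001], rng)
        assert np.abs(P[0] - p0).max() < 0.1

    def test_seed_reproducibility(self):
        a = draw_subpop_freqs(100, 2, [0.2, 0.3], np.random.default_rng(5))
        b = draw_subpop_freqs(100, 2, [0.2, 0.3], np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_f_rejected(self, rng):
        with pytest.raises(ValueError, match="F_pop"):
            draw_subpop_freqs(10, 1, [1.0], rng)


class TestGenotypes:
    def test_full_inbreeding_no_hets(self, rng):
        freqs = np.full((1, 2000), 0.5)
        calls = sample_genotypes(freqs, [50], 1.0, rng)
        assert (calls == 1).sum() == 0

    def test_het_rate_under_selfing(self, rng):
        # p = 0.5, f_is = 0.97: P(het) = 2 * 0.25 * 0.03 = 0.015
        freqs = np.full((1, 10000), 0.5)
        calls = sample_genotypes(freqs, [100], 0.97, rng)
        rate = (calls == 1).mean()
        sd = np.sqrt(0.015 * 0.985 / calls.size)
        assert abs(rate - 0.015) < 3 * sd

    def test_allele_frequency_unbiased(self, rng):
        p = 0.3
        freqs = np.full((1, 5000), p)
        calls = sample_genotypes(freqs, [200], 0.97, rng)
        emp = calls.mean() / 2
        assert emp == pytest.approx(p, abs=0.005)


class TestArtifacts:
    def test_zero_rates_identity(self, rng):
        calls = rng.choice([0, 2], size=(10, 50)).astype(np.int8)
        assert np.array_equal(apply_artifacts(calls, 0.0, 0.0, rng), calls)

    def test_missing_rate_within_binomial_band(self, rng):
        calls = np.zeros((100, 1000), dtype=np.int8)
        out = apply_artifacts(calls, 0.1, 0.0, rng)
        rate = (out == MISSING).mean()
        sd = np.sqrt(0.1 * 0.9 / calls.size)
        assert abs(rate - 0.1) < 3 * sd

    def test_het_error_raises_het_rate(self, rng):
        calls = np.zeros((100, 1000), dtype=np.int8)
        out = apply_artifacts(calls, 0.0, 0.005, rng)
        rate = (out == 1).mean()
        sd = np.sqrt(0.005 * 0.995 / calls.size)
        assert abs(rate - 0.005) < 3 * sd


class TestPlantedFeatures:
    def test_zero_epsilon_duplicate_is_identical(self, rng):
        cfg = SimConfig(seed=2, L=800, pop_labels=("a",), n_per_pop=(30,),
                        F_pop=(0.3,), missing_rate=0.0, het_error_rate=0.0,
                        duplicates=(DuplicateSpec("a", 3, 0.0),),
                        mislabel_fraction=0.0, sweep=None)
        G, _, truth = simulate_collection(cfg)
        for src, clone, _ in truth.duplicate_pairs:
            i, j = G.accession_index(src), G.accession_index(clone)
            assert np.array_equal(G.calls[i], G.calls[j])

    def test_epsilon_discordance_within_binomial_band(self, rng):
        eps = 0.01
        cfg = SimConfig(seed=2, L=5000, pop_labels=("a",), n_per_pop=(30,),
                        F_pop=(0.3,), missing_rate=0.0, het_error_rate=0.0,
                        duplicates=(DuplicateSpec("a", 5, eps),),
                        mislabel_fraction=0.0, sweep=None)
        G, _, truth = simulate_collection(cfg)
        for src, clone, _ in truth.duplicate_pairs:
            i, j = G.accession_index(src), G.accession_index(clone)
            hom = ((G.calls[i] == 0) | (G.calls[i] == 2)) \
                & ((G.calls[j] == 0) | (G.calls[j] == 2))
            disc = (G.calls[i] != G.calls[j]) & hom
            rate = disc.sum() / hom.sum()
            assert abs(rate - eps) < 3 * np.sqrt(eps * (1 - eps) / hom.sum())

    def test_sweep_window_elevates_theta(self):
        cfg = SimConfig(seed=4, L=2100, pop_labels=("dom", "wild"),
                        n_per_pop=(60, 60), F_pop=(0.1, 0.1), duplicates=(),
                        mislabel_fraction=0.0,
                        sweep=SweepSpec(chrom="3A", window_sites=20,
                                        pair=("dom", "wild")))
        G, _, truth = simulate_collection(cfg)
        theta = popstats.wc_fst_per_site(G, truth.pop_of, ("dom", "wild"))
        chrom, start, end = truth.sweep_window
        w = ((G.sites.chrom == chrom) & (G.sites.pos >= start)
             & (G.sites.pos <= end)).to_numpy()
        assert np.nanmean(theta[w]) > 0.6
        assert np.nanmean(theta[~w]) < 0.2

    def test_mislabels_recorded_and_wrong(self):
        cfg = SimConfig(seed=6, L=300, pop_labels=("a", "b"), n_per_pop=(40, 40),
                        F_pop=(0.3, 0.3), duplicates=(), mislabel_fraction=0.1,
                        sweep=None)
        _, passports, truth = simulate_collection(cfg)
        recorded = {p.accession_id: p.taxon for p in passports}
        assert len(truth.mislabeled) == 8
        for acc, true_label in truth.mislabeled.items():
            assert recorded[acc] != true_label


class TestCollectionOutput:
    def test_round_trip_through_files(self, tmp_path):
        cfg = SimConfig(seed=3, L=600, n_per_pop=(20, 20, 30, 10))
        G, passports, truth = simulate_collection(cfg)
        paths = write_collection(G, passports, truth, tmp_path)
        G2 = geno_io.read_vcf(paths["vcf"])
        assert np.array_equal(G.calls, G2.calls)
        assert G2.accession_ids == G.accession_ids
        recs = geno_io.read_passport(paths["passport"])
        assert [r.accession_id for r in recs] == G.accession_ids
        truth2 = SimTruth.from_json(paths["truth"])
        assert truth2.pop_of == truth.pop_of
        assert truth2.duplicate_pairs == truth.duplicate_pairs

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, L=400, n_per_pop=(15, 15, 20, 10))
        a = tmp_path / "a"
        b = tmp_path / "b"
        for d in (a, b):
            G, p, t = simulate_collection(cfg)
            write_collection(G, p, t, d)
        for name in ("synthetic.vcf", "synthetic_passport.csv",
                     "synthetic_truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_realized_fst_near_target(self):
        cfg = SimConfig(seed=10, L=6000, pop_labels=("a", "b"),
                        n_per_pop=(80, 80), F_pop=(0.25, 0.25), duplicates=(),
                        mislabel_fraction=0.0, sweep=None, missing_rate=0.0)
        G, _, truth = simulate_collection(cfg)
        est = popstats.wc_fst_multilocus(G, truth.pop_of, ("a", "b"))
        assert est == pytest.approx(0.25, abs=0.02)
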