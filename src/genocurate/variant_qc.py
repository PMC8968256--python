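"""SNP and accession quality-control filters for inbred genotype matrices.

The filter cascade, in the order it is meant to run:

1. :func:`fisher_disassociation_filter` — removes artifact sites (e.g.
   collapsed paralogs) where the two alleles co-occur within accessions
   more than expected for a truly biallelic locus in an inbred line.
2. :func:`filter_sites` — minor-allele frequency, per-site missingness
   and per-site heterozygosity thresholds.
3. :func:`filter_accessions` — drops accessions with excessive missing data.
4. :func:`drop_single_het_fixed` — within an analysis group, removes loci
   whose only variation is a single heterozygous call (likely sequencing
   error) when the group is large enough to make that suspicious.

All thresholds are strict inequalities; boundary values fall on the side
the operator implies (e.g. a site with MAF exactly 0.01 fails ``maf > 0.01``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import MISSING, GenotypeMatrix, subset


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage (counts in/out plus parameters)."""

    stage: str
    sites_in: int
    sites_out: int
    accessions_in: int
    accessions_out: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sites_out > self.sites_in or self.accessions_out > self.accessions_in:
            raise ValueError(f"{self.stage}: filter output larger than input")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def append_to_log(self, path: str | Path) -> None:
        with Path(path).open("a") as fh:
            fh.write(self.to_json() + "\n")


def site_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-site genotype-class counts, MAF, missing rate and het rate.

    MAF is computed over non-missing alleles only; sites with no
    non-missing call get NaN frequencies and are flagged ``undefined``.
    """
    if G.n_accessions < 1:
        raise ValueError("empty matrix")
    c = G.calls
    n_hom_ref = (c == 0).sum(axis=0)
    n_het = (c == 1).sum(axis=0)
    n_hom_alt = (c == 2).sum(axis=0)
    n_missing = (c == MISSING).sum(axis=0)
    n_called = G.n_accessions - n_missing
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (2.0 * n_hom_alt + n_het) / (2.0 * n_called)
        maf = np.minimum(q, 1.0 - q)
        het_rate = n_het / n_called
    missing_rate = n_missing / G.n_accessions
    return pd.DataFrame({
        "n_hom_ref": n_hom_ref, "n_het": n_het, "n_hom_alt": n_hom_alt,
        "n_missing": n_missing, "alt_freq": q, "maf": maf,
        "missing_rate": missing_rate, "het_rate": het_rate,
        "undefined": n_called == 0,
    })


def fisher_disassociation_pvalues(n_het: np.ndarray, n_hom_ref: np.ndarray,
                                  n_hom_alt: np.ndarray, n_missing: np.ndarray) -> np.ndarray:
    """One-sided Fisher exact P for *under*-representation of allele co-occurrence.

    Per site, accessions are cross-classified by presence of the ref and
    alt allele: het = both present, hom-ref = ref only, hom-alt = alt only,
    missing = neither observed.  A true biallelic locus in a selfing
    population shows mutually exclusive homozygotes (few hets), so small P
    (odds ratio < 1) supports a genuine variant.  P = hypergeometric
    left tail P(X <= n_het) with population N, n_het+n_hom_ref ref-carriers
    and n_het+n_hom_alt alt-carriers.
    """
    n_het = np.asarray(n_het, dtype=np.int64)
    n_hom_ref = np.asarray(n_hom_ref, dtype=np.int64)
    n_hom_alt = np.asarray(n_hom_alt, dtype=np.int64)
    n_missing = np.asarray(n_missing, dtype=np.int64)
    N = n_het + n_hom_ref + n_hom_alt + n_missing
    return stats.hypergeom.cdf(n_het, N, n_het + n_hom_ref, n_het + n_hom_alt)


def fisher_disassociation_filter(G: GenotypeMatrix, alpha: float = 0.001
                                 ) -> tuple[np.ndarray, FilterReport]:
    """Keep sites whose alleles are significantly disassociated (P < alpha)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    s = site_stats(G)
    p = fisher_disassociation_pvalues(s.n_het.to_numpy(), s.n_hom_ref.to_numpy(),
                                      s.n_hom_alt.to_numpy(), s.n_missing.to_numpy())
    kept = np.flatnonzero(p < alpha)
    report = FilterReport("fisher_disassociation", G.n_sites, len(kept),
                          G.n_accessions, G.n_accessions, {"alpha": alpha})
    return kept, report


def filter_sites(G: GenotypeMatrix, maf_min: float = 0.01, missing_max: float = 0.30,
                 het_max: float = 0.10) -> tuple[np.ndarray, FilterReport]:
    """Keep sites with maf > maf_min, missing_rate < missing_max, het_rate < het_max."""
    s = site_stats(G)
    keep = ((s.maf.to_numpy() > maf_min)
            & (s.missing_rate.to_numpy() < missing_max)
            & (s.het_rate.to_numpy() < het_max)
            & ~s.undefined.to_numpy())
    kept = np.flatnonzero(keep)
    report = FilterReport("site_filters", G.n_sites, len(kept),
                          G.n_accessions, G.n_accessions,
                          {"maf_min": maf_min, "missing_max": missing_max, "het_max": het_max})
    return kept, report


def filter_accessions(G: GenotypeMatrix, missing_max: float = 0.55
                      ) -> tuple[list[str], FilterReport]:
    """Keep accessions whose missing-call fraction is <= missing_max."""
    if G.n_sites < 1:
        raise ValueError("matrix has no sites")
    frac = (G.calls == MISSING).mean(axis=1)
    kept = [a for a, f in zip(G.accession_ids, frac) if f <= missing_max]
    if not kept:
        raise ValueError("accession filter removed every accession")
    report = FilterReport("accession_missingness", G.n_sites, G.n_sites,
                          G.n_accessions, len(kept), {"missing_max": missing_max})
    return kept, report


def single_het_fixed_mask(G: GenotypeMatrix) -> np.ndarray:
    """Boolean mask of sites with exactly one het call and no other segregation."""
    s = site_stats(G)
    return ((s.n_het.to_numpy() == 1)
            & (np.minimum(s.n_hom_ref.to_numpy(), s.n_hom_alt.to_numpy()) == 0))


def drop_single_het_fixed(G: GenotypeMatrix, min_population: int = 100
                          ) -> tuple[np.ndarray, FilterReport]:
    """Remove single-het otherwise-fixed loci in groups larger than ``min_population``.

    In a large inbred group, a locus whose only non-reference signal is a
    single heterozygous call is more plausibly a sequencing error than a
    real variant; in small groups the rule is not applied.
    """
    if G.n_accessions > min_population:
        kept = np.flatnonzero(~single_het_fixed_mask(G))
    else:
        kept = np.arange(G.n_sites)
    report = FilterReport("single_het_fixed", G.n_sites, len(kept),
                          G.n_accessions, G.n_accessions,
                          {"min_population": min_population,
                           "applied": G.n_accessions > min_population})
    return kept, report


def mode_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each MISSING call with the most frequent code at its site.

    Ties break toward the lower code, so the result is deterministic.
    This simple single-site imputation is used only where downstream
    steps need a complete matrix (the selection scan); it ignores linkage
    and will shrink rare-allele frequencies slightly.
    """
    counts = np.stack([(G.calls == code).sum(axis=0) for code in (0, 1, 2)])
    if (counts.sum(axis=0) == 0).any():
        j = int(np.flatnonzero(counts.sum(axis=0) == 0)[0])
        raise ValueError(f"site {j} ({G.sites.chrom[j]}:{G.sites.pos[j]}) is entirely missing")
    modes = counts.argmax(axis=0).astype(np.int8)  # argmax tie-break picks the lower code
    calls = G.calls.copy()
    miss = calls == MISSING
    calls[miss] = np.broadcast_to(modes, calls.shape)[miss]
    return GenotypeMatrix(G.accession_ids, G.sites.copy(), calls)


def apply_site_filter(G: GenotypeMatrix, kept: np.ndarray) -> GenotypeMatrix:
    return subset(G, site_indices=kept)
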