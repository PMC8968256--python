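"""Diversity and differentiation statistics for accession groups.

Implements Nei's gene diversity (mean per-site expected heterozygosity),
segregating-locus accounting with the single-heterozygote error rule, a
G_ST-style pairwise F_ST by ratio of sums over loci, and the Weir &
Cockerham (1984) per-site theta used by the selection scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, subset
from .variant_qc import drop_single_het_fixed, site_stats


@dataclass
class DiversityReport:
    group: str
    n: int
    nei: float
    segregating: int
    segregating_pct: float | None = None


def nei_diversity(G: GenotypeMatrix) -> float:
    """Nei's gene diversity: mean over sites of h = 1 - p^2 - q^2.

    Allele frequencies are taken over non-missing alleles only; sites with
    no defined frequency are excluded from the mean.  No small-sample
    correction is applied (negligible at gene-bank collection sizes; see
    the methods note).
    """
    if G.n_accessions < 2:
        raise ValueError("diversity needs at least 2 accessions")
    s = site_stats(G)
    p = s.alt_freq.to_numpy()
    defined = np.isfinite(p)
    if not defined.any():
        raise ValueError("no site with a defined allele frequency")
    h = 2.0 * p[defined] * (1.0 - p[defined])
    return float(h.mean())


def segregating_mask(G: GenotypeMatrix) -> np.ndarray:
    """Sites with at least two distinct non-missing genotype classes."""
    s = site_stats(G)
    n_classes = ((s.n_hom_ref.to_numpy() > 0).astype(int)
                 + (s.n_het.to_numpy() > 0).astype(int)
                 + (s.n_hom_alt.to_numpy() > 0).astype(int))
    return n_classes >= 2


def segregating_count(G: GenotypeMatrix, apply_single_het_rule: bool = True,
                      min_population: int = 100) -> int:
    """Count segregating sites in one group.

    With ``apply_single_het_rule`` and group size > ``min_population``,
    loci whose only variation is a single heterozygous call are first
    removed as likely sequencing errors.
    """
    if apply_single_het_rule:
        kept, _ = drop_single_het_fixed(G, min_population=min_population)
        G = subset(G, site_indices=kept)
    return int(segregating_mask(G).sum())


def _group_site_arrays(G: GenotypeMatrix, groups: Mapping[str, str],
                       label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called, alt freq, observed het fraction) for one group."""
    members = [a for a in G.accession_ids if groups.get(a) == label]
    if len(members) < 2:
        raise ValueError(f"group {label!r} has fewer than 2 members")
    sub = subset(G, accessions=members)
    c = sub.calls
    called = (c != MISSING).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ((c == 2).sum(axis=0) * 2.0 + (c == 1).sum(axis=0)) / (2.0 * called)
        h = (c == 1).sum(axis=0) / called
    return called, p, h


def pairwise_fst(G: GenotypeMatrix, groups: Mapping[str, str],
                 pair: tuple[str, str]) -> float:
    """G_ST-style pairwise F_ST by ratio of sums over loci.

    F = 1 - sum_j H_S,j / sum_j H_T,j, where H_S is the sample-size
    weighted mean within-group expected heterozygosity (2 p_i (1 - p_i))
    and H_T the expected heterozygosity at the pooled (weighted) allele
    frequency.  Sites with an undefined frequency in either group are
    skipped.  Ratio of sums, not mean of ratios, so low-diversity loci do
    not destabilise the estimate.
    """
    a, b = pair
    n1, p1, h1 = _group_site_arrays(G, groups, a)
    n2, p2, h2 = _group_site_arrays(G, groups, b)
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 0) & (n2 > 0)
    if not ok.any():
        raise ValueError(f"no site with defined frequencies in both {a!r} and {b!r}")
    n1, p1, n2, p2 = n1[ok], p1[ok], n2[ok], p2[ok]
    hs = (n1 * 2.0 * p1 * (1.0 - p1) + n2 * 2.0 * p2 * (1.0 - p2)) / (n1 + n2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    ht = 2.0 * pbar * (1.0 - pbar)
    sum_ht = ht.sum()
    if sum_ht == 0.0:
        raise ValueError("both groups identically fixed at every site; F_ST undefined")
    return float(1.0 - hs.sum() / sum_ht)


def wc_fst_components(G: GenotypeMatrix, groups: Mapping[str, str],
                      pair: tuple[str, str]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) variance components (a, b, c) per site, r = 2 groups.

    a is the between-group component, b between individuals within groups,
    c within individuals (heterozygosity).  Sites where either group has
    fewer than 2 called accessions, or where n_c <= 0, are NaN.
    """
    la, lb = pair
    n1, p1, h1 = _group_site_arrays(G, groups, la)
    n2, p2, h2 = _group_site_arrays(G, groups, lb)
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1.0 - pbar)
                                 - s2 * (r - 1.0) / r
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar)
                                     - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_fst_per_site(G: GenotypeMatrix, groups: Mapping[str, str],
                    pair: tuple[str, str]) -> np.ndarray:
    """Per-site Weir–Cockerham theta = a / (a + b + c); NaN where undefined."""
    a, b, c = wc_fst_components(G, groups, pair)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    theta[denom == 0.0] = np.nan
    return theta


def wc_fst_multilocus(G: GenotypeMatrix, groups: Mapping[str, str],
                      pair: tuple[str, str]) -> float:
    """Multi-locus Weir–Cockerham estimate sum(a) / sum(a + b + c)."""
    a, b, c = wc_fst_components(G, groups, pair)
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0.0:
        raise ValueError("sum of variance components is zero; F_ST undefined")
    return float(a[ok].sum() / denom)


def diversity_table(G: GenotypeMatrix, groups: Mapping[str, str],
                    apply_single_het_rule: bool = True) -> pd.DataFrame:
    """Per-group diversity report (n, Nei index, segregating count and %).

    Percentages are relative to the total site count of the supplied
    matrix; an "all" row covers the pooled collection.
    """
    rows = []
    total_sites = G.n_sites

    def _row(label: str, sub: GenotypeMatrix) -> dict:
        seg = segregating_count(sub, apply_single_het_rule=apply_single_het_rule)
        return {"group": label, "n": sub.n_accessions,
                "nei": round(nei_diversity(sub), 6),
                "segregating": seg,
                "segregating_pct": round(100.0 * seg / total_sites, 1)}

    rows.append(_row("all", G))
    for label in dict.fromkeys(groups.get(a) for a in G.accession_ids if a in groups):
        members = [a for a in G.accession_ids if groups.get(a) == label]
        if len(members) >= 2:
            rows.append(_row(str(label), subset(G, accessions=members)))
    return pd.DataFrame(rows)


def pairwise_fst_table(G: GenotypeMatrix, groups: Mapping[str, str],
                       labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric table of pairwise G_ST-style F_ST between all group pairs."""
    if labels is None:
        labels = list(dict.fromkeys(groups.get(a) for a in G.accession_ids
                                    if a in groups))
    labels = [str(l) for l in labels]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        out.loc[la, la] = 0.0
        for lb in labels[i + 1:]:
            f = pairwise_fst(G, groups, (la, lb))
            out.loc[la, lb] = out.loc[lb, la] = round(f, 4)
    return out
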