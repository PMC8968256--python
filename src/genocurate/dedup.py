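"""Duplicate-accession detection by pairwise identity by state (IBS).

Gene banks accumulate genetically identical accessions (re-donations,
renumbered material, seed splits).  For a selfing species almost all
informative sites are homozygous, so two accessions are compared only at
loci where *both* are homozygous and non-missing; the IBS fraction is the
share of those loci with equal genotype.  A near-1 identity mode in the
distribution of pairwise IBS separates true duplicates (differing only by
genotyping error) from the unrelated bulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, PassportRecord, passport_frame

logger = logging.getLogger(__name__)


@dataclass
class IdentityResult:
    """Pairwise IBS fractions and compared-locus counts.

    ``identity[i, j]`` is NaN (undefined) when fewer than ``min_compared``
    loci were jointly homozygous and non-missing — a guard against calling
    two accessions identical from a handful of overlapping loci.
    """

    ids: list[str]
    identity: np.ndarray
    compared: np.ndarray
    min_compared: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.identity, index=self.ids, columns=self.ids)


@dataclass
class DuplicateGroupSet:
    """Connected components of the >= threshold identity graph (size >= 2)."""

    threshold: float
    groups: list[set[str]]
    unique_count: int
    n_accessions: int

    @property
    def n_redundant(self) -> int:
        return self.n_accessions - self.unique_count

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold,
                "groups": [sorted(g) for g in self.groups],
                "unique_count": self.unique_count}


class ThresholdDetection(NamedTuple):
    threshold: float
    duplicate_mode_found: bool
    note: str


def ibs_matrix(G: GenotypeMatrix, min_compared: int = 500) -> IdentityResult:
    """Pairwise IBS over jointly homozygous, non-missing loci.

    Sites where either member is heterozygous or missing are excluded from
    both numerator and denominator.  Expects a matrix already filtered for
    duplicate analysis (typically MAF > 0.05, missing < 50%, het < 10%).
    """
    if G.n_accessions < 2:
        raise ValueError("need at least two accessions for pairwise identity")
    hom_ref = (G.calls == 0).astype(np.float64)
    hom_alt = (G.calls == 2).astype(np.float64)
    hom = hom_ref + hom_alt
    compared = hom @ hom.T
    matches = hom_ref @ hom_ref.T + hom_alt @ hom_alt.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = matches / compared
    identity[compared < min_compared] = np.nan
    np.fill_diagonal(identity, 1.0)
    return IdentityResult(list(G.accession_ids), identity,
                          compared.astype(np.int64), min_compared)


def offdiagonal_identities(res: IdentityResult) -> np.ndarray:
    """Defined upper-triangle identity values as a flat array."""
    iu = np.triu_indices(len(res.ids), k=1)
    vals = res.identity[iu]
    return vals[np.isfinite(vals)]


def _mode_scale(counts: np.ndarray, mode: int, bin_width: float) -> float:
    """Gaussian scale of a histogram mode from its full width at half maximum."""
    half = counts[mode] / 2.0
    left = mode
    while left > 0 and counts[left - 1] >= half:
        left -= 1
    right = mode
    while right + 1 < len(counts) and counts[right + 1] >= half:
        right += 1
    fwhm = (right - left + 1) * bin_width
    return max(fwhm / 2.355, bin_width / 2.0)


def detect_identity_threshold(values: Sequence[float], bin_width: float = 0.0025,
                              default: float = 0.99,
                              min_duplicate_mode: float = 0.95) -> ThresholdDetection:
    """Locate the identity threshold separating the duplicate mode from the bulk.

    Histograms the pairwise identities, finds the global (bulk) mode and
    the nearest-to-1.0 local maximum above it, and returns the density
    minimum between them.  Empirical bin counts in the gap are typically
    all zero, which leaves the minimum-density bin ill-defined, so the
    minimum is located by modeling each mode as a Gaussian (scale from
    its full width at half maximum) and taking their equal-z-score
    crossing point, clamped into the empty gap.  When no separated
    high-identity mode exists the ``default`` is returned with a note.
    """
    vals = np.asarray(list(values), dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 100:
        raise ValueError(f"need >= 100 pairwise identity values, got {len(vals)}")
    lo = min(vals.min(), 1.0 - bin_width)
    nbins = int(np.ceil((1.0 - lo) / bin_width)) + 1
    edges = 1.0 - bin_width * np.arange(nbins, -1, -1)
    counts, _ = np.histogram(vals, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0

    # contiguous nonzero runs; a mode run must carry non-trivial mass so
    # stray tail bins of a unimodal bulk are not mistaken for duplicates
    min_mass = max(5, int(np.ceil(5e-4 * len(vals))))
    runs: list[tuple[int, int, int]] = []  # (start, end, mass)
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(counts) and counts[j + 1] > 0:
            j += 1
        runs.append((i, j, int(counts[i:j + 1].sum())))
        i = j + 1
    qualifying = [r for r in runs if r[2] >= min_mass]
    if len(qualifying) < 2:
        return ThresholdDetection(default, False,
                                  "no duplicate mode separated from the bulk")
    hi_start, hi_end, _ = qualifying[-1]  # the mode nearest perfect identity
    high = hi_start + int(np.argmax(counts[hi_start:hi_end + 1]))
    if mids[high] < min_duplicate_mode:
        # duplicates differ only by genotyping error, so their mode must sit
        # near perfect identity; anything lower is population structure
        return ThresholdDetection(default, False,
                                  "no duplicate mode near perfect identity")
    bulk = int(np.argmax(counts[:hi_start]))
    between = counts[bulk + 1:high]
    if len(between) == 0 or between.min() >= min(counts[bulk], counts[high]):
        return ThresholdDetection(default, False,
                                  "no duplicate mode separated from the bulk")
    mu_b, mu_h = float(mids[bulk]), float(mids[high])
    s_b = _mode_scale(counts, bulk, bin_width)
    s_h = _mode_scale(counts, high, bin_width)
    if mu_h - mu_b < 5.0 * s_b:
        # fragments of the bulk's own tail, not a distinct duplicate mode
        return ThresholdDetection(default, False,
                                  "no duplicate mode separated from the bulk")
    thr = (s_h * mu_b + s_b * mu_h) / (s_b + s_h)
    # keep the threshold inside the low-density gap between the modes
    min_count = between.min()
    gap = np.flatnonzero(between == min_count) + bulk + 1
    thr = float(np.clip(thr, mids[gap[0]], mids[gap[-1]]))
    return ThresholdDetection(thr, True,
                              f"density minimum at {thr:.4f} between bulk mode "
                              f"{mu_b:.4f} and duplicate mode {mu_h:.4f}")


def duplicate_groups(res: IdentityResult, threshold: float = 0.99) -> DuplicateGroupSet:
    """Group accessions connected by identity >= threshold (transitive closure)."""
    n = len(res.ids)
    g = nx.Graph()
    g.add_nodes_from(res.ids)
    iu, ju = np.triu_indices(n, k=1)
    ok = np.isfinite(res.identity[iu, ju]) & (res.identity[iu, ju] >= threshold)
    for i, j in zip(iu[ok], ju[ok]):
        g.add_edge(res.ids[i], res.ids[j])
    groups = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    groups.sort(key=lambda c: (-len(c), sorted(c)[0]))
    unique = n - sum(len(c) - 1 for c in groups)
    return DuplicateGroupSet(threshold, groups, unique, n)


def duplicate_pairs(res: IdentityResult, threshold: float = 0.99) -> set[frozenset]:
    """All unordered pairs with defined identity >= threshold."""
    n = len(res.ids)
    iu, ju = np.triu_indices(n, k=1)
    ok = np.isfinite(res.identity[iu, ju]) & (res.identity[iu, ju] >= threshold)
    return {frozenset((res.ids[i], res.ids[j])) for i, j in zip(iu[ok], ju[ok])}


def representatives(groups: DuplicateGroupSet, all_ids: Sequence[str]) -> list[str]:
    """One representative per duplicate group (first in input order) plus all singletons."""
    grouped: set[str] = set().union(*groups.groups) if groups.groups else set()
    reps = []
    seen_groups: set[int] = set()
    for a in all_ids:
        if a not in grouped:
            reps.append(a)
            continue
        for gi, grp in enumerate(groups.groups):
            if a in grp:
                if gi not in seen_groups:
                    reps.append(a)
                    seen_groups.add(gi)
                break
    return reps


def phenotype_consistency(groups: DuplicateGroupSet,
                          passports: Sequence[PassportRecord]) -> pd.DataFrame:
    """Cross-validate duplicate groups against glume-color scores.

    Genetically identical accessions should share phenotype; a group with
    more than one distinct non-missing glume score is flagged for curator
    review.
    """
    pf = passport_frame(passports)
    rows = []
    for grp in groups.groups:
        members = sorted(grp)
        scores = [pf.loc[a, "glume_score"] for a in members if a in pf.index]
        distinct = sorted({int(s) for s in scores if s is not None and not pd.isna(s)})
        rows.append({
            "members": ",".join(members),
            "size": len(members),
            "glume_scores": ",".join(map(str, distinct)) if distinct else "no phenotype",
            "consistent": len(distinct) <= 1 if distinct else None,
            "flagged": len(distinct) > 1,
        })
    return pd.DataFrame(rows, columns=["members", "size", "glume_scores",
                                       "consistent", "flagged"])
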