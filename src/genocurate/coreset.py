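"""Greedy core-collection selection by homozygous-genotype coverage.

The coverage target set T is every (site, homozygous genotype class) pair
observed at least once in the full collection after masking heterozygous
calls to missing; the coverage of a subset is the fraction of T it
carries.  Coverage is monotone and submodular, so greedy selection of the
accession with maximal incremental coverage is the standard, near-optimal
strategy.  Selection stops at a coverage target (``cv``), when the
marginal gain drops below ``d``, or when accessions are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, subset
from .popstats import nei_diversity, segregating_count, segregating_mask


@dataclass
class CoreSelection:
    """Result of a greedy core selection (ordered ids + coverage trajectory)."""

    selected: list[str]
    coverage_after_each: list[float]
    final_coverage: float
    stop_reason: str  # coverage_target | marginal_gain | exhausted
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        inc = np.diff([0.0] + self.coverage_after_each)
        return pd.DataFrame({"rank": np.arange(1, len(self.selected) + 1),
                             "accession_id": self.selected,
                             "incremental_coverage": inc,
                             "cumulative_coverage": self.coverage_after_each})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mask_heterozygotes(G: GenotypeMatrix) -> GenotypeMatrix:
    """Set every heterozygous call to MISSING (hets carry no core signal here)."""
    calls = G.calls.copy()
    calls[calls == 1] = MISSING
    return GenotypeMatrix(G.accession_ids, G.sites.copy(), calls)


def _presence(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Boolean N x L presence of the two homozygous classes, hets masked."""
    return (G.calls == 0), (G.calls == 2)


def allele_coverage(G: GenotypeMatrix, subset_ids: Iterable[str]) -> float:
    """Fraction of the collection's (site, homozygote class) pairs present in a subset."""
    p0, p2 = _presence(G)
    t0, t2 = p0.any(axis=0), p2.any(axis=0)
    total = int(t0.sum() + t2.sum())
    if total == 0:
        raise ValueError("no polymorphism: the coverage target set is empty")
    idx = [G.accession_index(a) for a in subset_ids]
    if not idx:
        return 0.0
    got0 = (p0[idx].any(axis=0) & t0).sum()
    got2 = (p2[idx].any(axis=0) & t2).sum()
    return float((got0 + got2) / total)


def greedy_core(G: GenotypeMatrix, cv: float = 0.99, d: float = 0.0001) -> CoreSelection:
    """Greedy coverage-maximising core; ties break to the lowest accession index.

    ``cv`` is the coverage target and ``d`` the minimum marginal coverage
    gain (both fractions in (0, 1]); heterozygous calls are masked before
    anything is counted.
    """
    if not 0.0 < cv <= 1.0:
        raise ValueError(f"cv must be in (0, 1], got {cv}")
    if not 0.0 < d <= 1.0:
        raise ValueError(f"d must be in (0, 1], got {d}")
    p0, p2 = _presence(G)
    t0, t2 = p0.any(axis=0), p2.any(axis=0)
    total = int(t0.sum() + t2.sum())
    if total == 0:
        raise ValueError("no polymorphism: the coverage target set is empty")
    uncov0, uncov2 = t0.copy(), t2.copy()
    selected: list[str] = []
    trajectory: list[float] = []
    covered = 0
    remaining = set(range(G.n_accessions))
    stop_reason = "exhausted"
    while remaining:
        gains = np.array([(p0[i] & uncov0).sum() + (p2[i] & uncov2).sum()
                          if i in remaining else -1
                          for i in range(G.n_accessions)])
        best = int(np.argmax(gains))  # argmax tie-break = lowest index
        gain = int(gains[best])
        if gain / total < d and selected:
            stop_reason = "marginal_gain"
            break
        remaining.discard(best)
        selected.append(G.accession_ids[best])
        covered += gain
        uncov0 &= ~p0[best]
        uncov2 &= ~p2[best]
        trajectory.append(covered / total)
        if covered / total >= cv:
            stop_reason = "coverage_target"
            break
        if gain == 0:
            stop_reason = "marginal_gain"
            break
    return CoreSelection(selected, trajectory,
                         trajectory[-1] if trajectory else 0.0,
                         stop_reason, {"cv": cv, "d": d})


def coverage_curve(core: CoreSelection) -> pd.DataFrame:
    """Coverage-vs-core-size curve for plotting."""
    return pd.DataFrame({"n_selected": np.arange(1, len(core.selected) + 1),
                         "coverage": core.coverage_after_each})


def core_report(cores: Mapping[str, Sequence[str]], G: GenotypeMatrix,
                passports: pd.DataFrame | None,
                groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-group accounting of a selected core.

    Reports core size, Nei diversity of the core, the percentage of the
    group's segregating loci still segregating in the core, and the
    passport countries represented by core members.
    """
    rows = []
    for label, core_ids in cores.items():
        members = [a for a in G.accession_ids if groups.get(a) == label]
        G_grp = subset(G, accessions=members)
        seg_grp = segregating_mask(G_grp)
        G_core = subset(G, accessions=list(core_ids))
        seg_core = segregating_mask(G_core)
        n_seg_grp = int(seg_grp.sum())
        retained = int((seg_grp & seg_core).sum())
        countries = ""
        if passports is not None:
            cc = sorted({str(passports.loc[a, "country"]) for a in core_ids
                         if a in passports.index
                         and not pd.isna(passports.loc[a, "country"])})
            countries = ",".join(cc)
        rows.append({"group": label, "group_size": len(members),
                     "core_size": len(core_ids),
                     "core_nei": round(nei_diversity(G_core), 6),
                     "group_segregating": n_seg_grp,
                     "core_segregating_retained_pct":
                         round(100.0 * retained / n_seg_grp, 1) if n_seg_grp else np.nan,
                     "countries": countries})
    return pd.DataFrame(rows)
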