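"""Genome-wide F_ST selection scan between two accession groups.

Per-site Weir–Cockerham theta is computed between a domesticated and a
wild group (the larger group subsampled to balance sizes), smoothed per
chromosome with Lowess (tricube-weighted local linear regression), and
outlier regions are called where the smoothed profile exceeds a
genome-wide threshold of mean + k·sigma of the raw per-site values.
Negative per-site estimates are retained for the mean/sigma computation:
clamping them would bias the threshold upward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .geno_io import GenotypeMatrix, subset
from .popstats import wc_fst_per_site


@dataclass
class ScanConfig:
    """Tunable parameters of the selection scan.

    f: Lowess smoothing fraction (share of sites in each local window).
    iterations: bisquare robustifying passes of the Lowess fit.  The
      default is 0: robustifying passes down-weight residual outliers,
      and in a selection scan the contiguous high-F_ST block *is* the
      outlier — with 2-3 passes a planted sweep window is assigned zero
      robustness weight and vanishes from the smoothed profile.
    k_sigma: outlier threshold multiplier over the genome-wide mean.
    seed: for the group-balancing subsample.
    threshold_on: "raw" (default) computes mean/sigma from raw per-site
      values; "smoothed" computes them from the smoothed profile.
    """

    f: float = 0.1
    iterations: int = 0
    k_sigma: float = 3.0
    seed: int = 0
    threshold_on: str = "raw"

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"Lowess fraction must be in (0, 1], got {self.f}")
        if self.k_sigma <= 0:
            raise ValueError(f"k_sigma must be > 0, got {self.k_sigma}")
        if self.threshold_on not in ("raw", "smoothed"):
            raise ValueError(f"threshold_on must be 'raw' or 'smoothed'")


@dataclass(frozen=True)
class Region:
    """A called outlier region (1-based inclusive bp interval)."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_smoothed: float


@dataclass
class FstProfile:
    """Per-chromosome raw and smoothed F_ST with threshold and called regions."""

    chroms: dict[str, pd.DataFrame]  # columns: pos, raw_fst, smoothed_fst
    genome_mean: float
    genome_sd: float
    threshold: float
    regions: list[Region]
    config: ScanConfig
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, df in self.chroms.items():
            part = df.copy()
            part.insert(0, "chrom", chrom)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_bed(self, path: str | Path) -> None:
        """Called regions as BED (0-based half-open) with peak position and score."""
        with Path(path).open("w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                         f"peak_{r.peak_bp}\t{r.peak_smoothed:.4f}\n")

    def write_config(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump({"config": asdict(self.config), "metadata": self.metadata,
                       "genome_mean": self.genome_mean, "genome_sd": self.genome_sd,
                       "threshold": self.threshold}, fh, indent=2)


def balance_groups(group_a: Sequence[str], group_b: Sequence[str],
                   seed: int) -> tuple[list[str], list[str]]:
    """Subsample the larger group (without replacement) to the smaller's size.

    The subsample is drawn with a seeded generator so a scan is fully
    reproducible; the smaller group is returned unchanged, and input order
    is preserved within each group.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    if len(a) > len(b):
        keep = set(rng.choice(len(a), size=len(b), replace=False))
        a = [x for i, x in enumerate(a) if i in keep]
    elif len(b) > len(a):
        keep = set(rng.choice(len(b), size=len(a), replace=False))
        b = [x for i, x in enumerate(b) if i in keep]
    return a, b


def lowess_smooth(positions: np.ndarray, values: np.ndarray, f: float = 0.1,
                  iterations: int = 3) -> np.ndarray:
    """Lowess smoothing at the input positions (single chromosome).

    Locally weighted linear regression with tricube weights over the
    nearest ``ceil(f * n)`` points and ``iterations`` bisquare
    robustifying passes.  Positions must be strictly increasing — the
    smoother must never be run across a chromosome boundary.
    """
    positions = np.asarray(positions, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(positions) < 5:
        raise ValueError(f"need >= 5 points to smooth, got {len(positions)}")
    if not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    return _sm_lowess(values, positions, frac=f, it=iterations,
                      return_sorted=False)


def _call_regions_arrays(chrom: str, positions: np.ndarray, smoothed: np.ndarray,
                         threshold: float) -> list[Region]:
    above = smoothed > threshold
    regions: list[Region] = []
    i = 0
    n = len(positions)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        seg = smoothed[i:j + 1]
        peak_rel = int(np.argmax(seg))  # argmax ties -> lowest position
        regions.append(Region(chrom, int(positions[i]), int(positions[j]),
                              int(positions[i + peak_rel]), float(seg[peak_rel])))
        i = j + 1
    return regions


def call_selection_regions(profile: FstProfile, k_sigma: float | None = None
                           ) -> list[Region]:
    """(Re-)call outlier regions on a computed profile.

    The threshold is mean + k_sigma * sd of the defined raw per-site
    values (or of the smoothed values if the profile was configured with
    ``threshold_on="smoothed"``); a region is a maximal run of consecutive
    sites whose smoothed value exceeds it.
    """
    if k_sigma is None:
        k_sigma = profile.config.k_sigma
    key = "raw_fst" if profile.config.threshold_on == "raw" else "smoothed_fst"
    vals = np.concatenate([df[key].to_numpy() for df in profile.chroms.values()])
    vals = vals[np.isfinite(vals)]
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    threshold = mean + k_sigma * sd
    regions: list[Region] = []
    for chrom, df in profile.chroms.items():
        ok = np.isfinite(df.smoothed_fst.to_numpy())
        regions.extend(_call_regions_arrays(
            chrom, df.pos.to_numpy()[ok], df.smoothed_fst.to_numpy()[ok], threshold))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    profile.genome_mean, profile.genome_sd = mean, sd
    profile.threshold = threshold
    profile.regions = regions
    return regions


def run_scan(G: GenotypeMatrix, groups: Mapping[str, str], pair: tuple[str, str],
             config: ScanConfig | None = None) -> FstProfile:
    """Full scan: balance groups, per-site W-C theta, Lowess, region calling.

    ``G`` should be imputed or complete for the two groups; undefined
    per-site values (e.g. monomorphic in the balanced sample) are excluded
    from the threshold and carried as NaN in the profile.
    """
    config = config or ScanConfig()
    la, lb = pair
    ids_a = [a for a in G.accession_ids if groups.get(a) == la]
    ids_b = [a for a in G.accession_ids if groups.get(a) == lb]
    bal_a, bal_b = balance_groups(ids_a, ids_b, seed=config.seed)
    sub = subset(G, accessions=bal_a + bal_b)
    bal_groups = {a: la for a in bal_a} | {b: lb for b in bal_b}
    theta = wc_fst_per_site(sub, bal_groups, pair)

    chroms: dict[str, pd.DataFrame] = {}
    for chrom in pd.unique(sub.sites["chrom"]):
        idx = np.flatnonzero((sub.sites["chrom"] == chrom).to_numpy())
        pos = sub.sites["pos"].to_numpy()[idx].astype(np.int64)
        raw = theta[idx]
        order = np.argsort(pos, kind="stable")
        pos, raw = pos[order], raw[order]
        ok = np.isfinite(raw)
        smoothed = np.full(len(raw), np.nan)
        if ok.sum() >= 5:
            smoothed[ok] = lowess_smooth(pos[ok].astype(np.float64), raw[ok],
                                         f=config.f, iterations=config.iterations)
        chroms[str(chrom)] = pd.DataFrame(
            {"pos": pos, "raw_fst": raw, "smoothed_fst": smoothed})

    profile = FstProfile(chroms, 0.0, 0.0, 0.0, [], config,
                         metadata={"group_a": la, "group_b": lb,
                                   "n_a": len(bal_a), "n_b": len(bal_b),
                                   "n_sites": int(sub.n_sites),
                                   "seed": config.seed})
    call_selection_regions(profile)
    return profile
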