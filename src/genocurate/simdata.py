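"""Synthetic inbred gene-bank collections with planted, known truth.

The generator emulates the data a curation pipeline sees for a
predominantly selfing diploid collection genotyped by reduced-
representation sequencing: K differentiated subpopulations (Balding–
Nichols allele frequencies around a shared ancestral frequency), strong
within-accession inbreeding, random missingness and a low rate of
spurious heterozygous calls, near-clonal duplicate accessions, a
localized high-differentiation window between two labeled groups (a
domestication-sweep analogue), and a fraction of accessions carrying
wrong passport labels.  Every planted feature is recorded in a
:class:`SimTruth` so pipeline estimates can be scored against truth.

It does not model linkage, recombination, admixture, or demographic
history: sites are independent given the subpopulation frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import (MISSING, GenotypeMatrix, PassportRecord, SITE_COLUMNS,
                      write_passport, write_vcf)

#: Default chromosome names/lengths: seven chromosomes of 500 Mb,
#: the karyotype of a diploid A-genome wheat.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (f"{i}A", 500_000_000) for i in range(1, 8))


@dataclass
class SweepSpec:
    """A planted high-differentiation window between two labeled groups."""

    chrom: str = "3A"
    window_sites: int = 25
    pair: tuple[str, str] = ("domesticated", "alpha")
    p_high: float = 0.98
    p_low: float = 0.02


@dataclass
class DuplicateSpec:
    """Clones appended from one subpopulation with per-site discordance epsilon."""

    source_pop: str
    count: int
    epsilon: float = 0.002


@dataclass
class SimConfig:
    """Study-shaped defaults: 4 subpopulations (a wild outgroup species,
    a domesticated group and two wild races), N = 400, L = 5,000 SNPs on
    7 chromosomes, heavy selfing (f_is = 0.97), GBS-like missingness and
    heterozygous error, planted duplicates, one sweep window and a small
    mislabeled fraction."""

    seed: int = 0
    L: int = 5000
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    pop_labels: tuple[str, ...] = ("urartu", "domesticated", "alpha", "gamma")
    n_per_pop: tuple[int, ...] = (100, 100, 150, 50)
    F_pop: tuple[float, ...] = (0.7, 0.4, 0.5, 0.4)
    f_is: float = 0.97
    missing_rate: float = 0.05
    het_error_rate: float = 0.002
    duplicates: tuple[DuplicateSpec, ...] = (
        DuplicateSpec("alpha", 20, 0.002), DuplicateSpec("urartu", 10, 0.002))
    sweep: SweepSpec | None = field(default_factory=SweepSpec)
    mislabel_fraction: float = 0.025

    def __post_init__(self) -> None:
        if len(self.pop_labels) != len(self.n_per_pop) or \
           len(self.pop_labels) != len(self.F_pop):
            raise ValueError("pop_labels, n_per_pop and F_pop must have equal length")
        for r in (self.f_is, self.missing_rate, self.het_error_rate,
                  self.mislabel_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate out of [0, 1]: {r}")


@dataclass
class SimTruth:
    """Planted ground truth of a synthetic collection."""

    seed: int
    pop_of: dict[str, str]
    F_pop: dict[str, float]
    duplicate_pairs: list[tuple[str, str, float]]  # (source, clone, epsilon)
    sweep_window: tuple[str, int, int] | None  # chrom, start_bp, end_bp (1-based incl.)
    mislabeled: dict[str, str]  # accession -> true label

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with Path(path).open() as fh:
            d = json.load(fh)
        d["duplicate_pairs"] = [tuple(p) for p in d["duplicate_pairs"]]
        if d["sweep_window"] is not None:
            d["sweep_window"] = tuple(d["sweep_window"])
        return cls(**d)


def draw_subpop_freqs(L: int, K: int, F_pop: Sequence[float],
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols subpopulation frequencies.

    Ancestral p0 ~ Uniform(0.05, 0.95) per locus; for subpopulation k,
    p_k ~ Beta(p0 (1-F_k)/F_k, (1-p0)(1-F_k)/F_k), so E[p_k] = p0 and
    Var[p_k] = F_k p0 (1-p0).
    """
    F_pop = np.asarray(F_pop, dtype=np.float64)
    if np.any((F_pop <= 0.0) | (F_pop >= 1.0)):
        raise ValueError(f"all F_pop must be in (0, 1), got {F_pop}")
    p0 = rng.uniform(0.05, 0.95, size=L)
    P = np.empty((K, L))
    for k in range(K):
        scale = (1.0 - F_pop[k]) / F_pop[k]
        P[k] = rng.beta(p0 * scale, (1.0 - p0) * scale)
    return p0, P


def _genotypes_from_freqs(p: np.ndarray, n: int, f_is: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample n accessions at loci with alt frequencies p under inbreeding f_is.

    P(het) = 2 p (1-p)(1 - f_is); P(hom-alt) = p^2 + f_is p (1-p);
    the rest is hom-ref.
    """
    p = np.asarray(p, dtype=np.float64)
    p_hom_alt = p ** 2 + f_is * p * (1.0 - p)
    p_het = 2.0 * p * (1.0 - p) * (1.0 - f_is)
    u = rng.random((n, len(p)))
    calls = np.zeros((n, len(p)), dtype=np.int8)
    calls[u < p_hom_alt + p_het] = 1
    calls[u < p_hom_alt] = 2
    return calls


def sample_genotypes(freqs: np.ndarray, n_per_pop: Sequence[int], f_is: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Stack genotype draws for each subpopulation (freqs is K x L)."""
    blocks = [_genotypes_from_freqs(freqs[k], n, f_is, rng)
              for k, n in enumerate(n_per_pop)]
    return np.vstack(blocks)


def apply_artifacts(calls: np.ndarray, missing_rate: float, het_error_rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """GBS-like artifacts: random missingness, then spurious het calls.

    Each call independently becomes MISSING with ``missing_rate``; each
    remaining homozygote flips to heterozygous with ``het_error_rate``.
    """
    out = calls.copy()
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    if het_error_rate > 0:
        hom = (out == 0) | (out == 2)
        flip = hom & (rng.random(out.shape) < het_error_rate)
        out[flip] = 1
    return out


def _sites_frame(L: int, chromosomes: Sequence[tuple[str, int]],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Random distinct sorted positions, loci split evenly across chromosomes."""
    per = [L // len(chromosomes)] * len(chromosomes)
    for i in range(L - sum(per)):
        per[i] += 1
    bases = np.array(list("ACGT"))
    rows = []
    for (chrom, length), n in zip(chromosomes, per):
        # distinct uniform positions without materialising the whole range
        pos = np.unique(rng.integers(1, length + 1, size=n + max(10, n // 10)))
        while len(pos) < n:
            pos = np.unique(np.concatenate(
                [pos, rng.integers(1, length + 1, size=n)]))
        pos = np.sort(pos[rng.permutation(len(pos))[:n]])
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((chrom, int(p), bases[ref], bases[alt], None))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df["id"] = [f"S{i + 1}" for i in range(len(df))]
    return df


def plant_sweep(P: np.ndarray, sites: pd.DataFrame, pop_labels: Sequence[str],
                spec: SweepSpec, rng: np.random.Generator
                ) -> tuple[np.ndarray, tuple[str, int, int], np.ndarray]:
    """Overwrite a window's frequencies with near-fixed opposite alleles.

    Chooses ``window_sites`` consecutive loci in the middle of the named
    chromosome and sets the first group of ``spec.pair`` to ``p_high`` and
    the second to ``p_low``.  Returns the modified frequencies, the window
    as a 1-based inclusive bp interval, and the window site indices.
    """
    idx = np.flatnonzero((sites["chrom"] == spec.chrom).to_numpy())
    if len(idx) < spec.window_sites:
        raise ValueError(f"chromosome {spec.chrom} has {len(idx)} sites; "
                         f"window of {spec.window_sites} does not fit")
    start = (len(idx) - spec.window_sites) // 2
    window = idx[start:start + spec.window_sites]
    P = P.copy()
    labels = list(pop_labels)
    ka, kb = labels.index(spec.pair[0]), labels.index(spec.pair[1])
    P[ka, window] = spec.p_high
    P[kb, window] = spec.p_low
    pos = sites["pos"].to_numpy()
    return P, (spec.chrom, int(pos[window[0]]), int(pos[window[-1]])), window


def plant_duplicates(calls: np.ndarray, pop_of: list[str], ids: list[str],
                     specs: Sequence[DuplicateSpec], missing_rate: float,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, list[str], list[str],
                                list[tuple[str, str, float]]]:
    """Append near-clonal copies of randomly chosen source accessions.

    Each clone starts from its source's pre-missingness calls, swaps the
    homozygous state at a fraction ``epsilon`` of sites (genotyping-error
    analogue), and receives fresh missingness.
    """
    calls_out = [calls]
    ids_out = list(ids)
    pops_out = list(pop_of)
    pairs: list[tuple[str, str, float]] = []
    for spec in specs:
        members = [i for i, p in enumerate(pop_of) if p == spec.source_pop]
        if spec.count > len(members):
            raise ValueError(f"cannot plant {spec.count} duplicates from "
                             f"{spec.source_pop!r} ({len(members)} members)")
        chosen = rng.choice(members, size=spec.count, replace=False)
        for src in chosen:
            clone = calls[src].copy()
            hom = (clone == 0) | (clone == 2)
            flip = hom & (rng.random(clone.shape) < spec.epsilon)
            clone[flip] = 2 - clone[flip]
            if missing_rate > 0:
                clone[rng.random(clone.shape) < missing_rate] = MISSING
            clone_id = f"{ids[src]}_dup{len(pairs) + 1}"
            calls_out.append(clone[None, :])
            ids_out.append(clone_id)
            pops_out.append(spec.source_pop)
            pairs.append((ids[src], clone_id, spec.epsilon))
    return np.vstack(calls_out), ids_out, pops_out, pairs


def plant_mislabels(pop_of: dict[str, str], fraction: float, labels: Sequence[str],
                    rng: np.random.Generator,
                    eligible: Sequence[str] | None = None) -> dict[str, str]:
    """Swap the recorded label of a random fraction of accessions.

    Returns {accession: true label}; the input mapping is modified in
    place to carry the wrong labels.
    """
    pool = list(eligible) if eligible is not None else list(pop_of)
    n_wrong = int(round(fraction * len(pool)))
    truth: dict[str, str] = {}
    if n_wrong == 0:
        return truth
    chosen = rng.choice(len(pool), size=n_wrong, replace=False)
    others = {l: [x for x in labels if x != l] for l in labels}
    for i in chosen:
        acc = pool[i]
        true_label = pop_of[acc]
        wrong = others[true_label][rng.integers(len(others[true_label]))]
        truth[acc] = true_label
        pop_of[acc] = wrong
    return truth


def simulate_collection(config: SimConfig
                        ) -> tuple[GenotypeMatrix, list[PassportRecord], SimTruth]:
    """Generate a full synthetic collection with planted truth.

    Fully reproducible from ``config.seed``; named substreams keep each
    planted feature independent of the others.
    """
    rng = np.random.default_rng(config.seed)
    K = len(config.pop_labels)
    sites = _sites_frame(config.L, config.chromosomes, rng)
    p0, P = draw_subpop_freqs(config.L, K, config.F_pop, rng)

    sweep_window = None
    if config.sweep is not None:
        P, sweep_window, _ = plant_sweep(P, sites, config.pop_labels,
                                         config.sweep, rng)

    clean = sample_genotypes(P, config.n_per_pop, config.f_is, rng)
    ids = [f"ACC{i + 1:04d}" for i in range(clean.shape[0])]
    pop_list = [label for label, n in zip(config.pop_labels, config.n_per_pop)
                for _ in range(n)]

    clean, ids, pop_list, dup_pairs = plant_duplicates(
        clean, pop_list, ids, config.duplicates, config.missing_rate, rng)
    # duplicates already carry their own missingness; artifacts apply to originals
    n_orig = sum(config.n_per_pop)
    calls = clean.copy()
    calls[:n_orig] = apply_artifacts(clean[:n_orig], config.missing_rate,
                                     config.het_error_rate, rng)
    if config.het_error_rate > 0:  # duplicates get het errors but keep their missingness
        hom = (calls[n_orig:] == 0) | (calls[n_orig:] == 2)
        flip = hom & (rng.random(calls[n_orig:].shape) < config.het_error_rate)
        calls[n_orig:][flip] = 1

    pop_of = dict(zip(ids, pop_list))
    true_pop = dict(pop_of)
    dup_ids = {c for _, c, _ in dup_pairs} | {s for s, _, _ in dup_pairs}
    mislabeled = plant_mislabels(pop_of, config.mislabel_fraction,
                                 config.pop_labels, rng,
                                 eligible=[a for a in ids if a not in dup_ids])

    countries = {l: c for l, c in zip(
        config.pop_labels, ["Lebanon", "Turkey", "Iraq", "Armenia", "Iran",
                            "Syria", "Georgia"][:K])}
    glume_of_pop = {l: g for l, g in zip(config.pop_labels,
                                         [2, 7, 5, 3, 8, 1, 6][:K])}
    passports = [PassportRecord(
        accession_id=a, taxon=pop_of[a], race=None,
        country=countries.get(pop_of[a]),
        site_name=None, lat=None, lon=None,
        glume_score=glume_of_pop.get(true_pop[a])) for a in ids]

    G = GenotypeMatrix(ids, sites, calls)
    truth = SimTruth(seed=config.seed, pop_of=true_pop,
                     F_pop=dict(zip(config.pop_labels, config.F_pop)),
                     duplicate_pairs=dup_pairs, sweep_window=sweep_window,
                     mislabeled=mislabeled)
    return G, passports, truth


def write_collection(G: GenotypeMatrix, passports: list[PassportRecord],
                     truth: SimTruth, outdir: str | Path,
                     prefix: str = "synthetic") -> dict[str, Path]:
    """Write VCF + passport CSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / f"{prefix}.vcf",
             "passport": outdir / f"{prefix}_passport.csv",
             "truth": outdir / f"{prefix}_truth.json"}
    write_vcf(G, paths["vcf"])
    write_passport(passports, paths["passport"])
    truth.to_json(paths["truth"])
    return paths
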