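"""Genotype and passport I/O plus the shared data model.

Genotypes are held as an accessions x sites matrix of alternate-allele
dosages: 0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternate, and ``MISSING`` (-1) for no-calls.  Phase is ignored: the
collections this package targets are predominantly selfing diploids
genotyped with reduced-representation sequencing, where phased calls
carry no extra information.  Only biallelic SNPs are represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (distinct from the dosage codes 0/1/2).
MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})

_BASES = {"A", "C", "G", "T"}

# IUPAC ambiguity codes for heterozygous diploid genotypes.
IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the expected genotype format."""


class PassportValidationError(ValueError):
    """Raised when a passport table fails validation."""


@dataclass(frozen=True)
class SiteInfo:
    """A biallelic SNP site (1-based position, single ref and alt base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-SNP alleles {self.ref}/{self.alt} at {self.chrom}:{self.pos}")


SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]


@dataclass
class GenotypeMatrix:
    """Accessions x sites dosage matrix with site and accession metadata.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt, id``
    (one row per site, file order preserved); ``calls`` is an N x L
    integer array over {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = sorted({a for a in self.accession_ids if self.accession_ids.count(a) > 1})
            raise ValueError(f"duplicate accession ids: {dupes}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, l = self.calls.shape
        if n != len(self.accession_ids):
            raise ValueError(f"{len(self.accession_ids)} accession ids but {n} call rows")
        if l != len(self.sites):
            raise ValueError(f"{len(self.sites)} site rows but {l} call columns")
        bad = ~np.isin(self.calls, list(VALID_CODES))
        if bad.any():
            raise ValueError(f"invalid genotype codes present: {np.unique(self.calls[bad])}")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def accession_index(self, accession_id: str) -> int:
        try:
            return self.accession_ids.index(accession_id)
        except ValueError:
            raise KeyError(f"unknown accession id: {accession_id!r}") from None

    def site_info(self, j: int) -> SiteInfo:
        row = self.sites.iloc[j]
        return SiteInfo(str(row.chrom), int(row.pos), str(row.ref), str(row.alt),
                        None if pd.isna(row.id) else str(row.id))


@dataclass(frozen=True)
class PassportRecord:
    """Curator-recorded accession metadata (taxon, origin, glume-color score)."""

    accession_id: str
    taxon: str | None = None
    race: str | None = None
    country: str | None = None
    site_name: str | None = None
    lat: float | None = None
    lon: float | None = None
    glume_score: int | None = None

    def __post_init__(self) -> None:
        if self.glume_score is not None and not 0 <= self.glume_score <= 9:
            raise PassportValidationError(
                f"glume_score for {self.accession_id} out of [0, 9]: {self.glume_score}"
            )


PASSPORT_COLUMNS = [
    "accession_id", "taxon", "race", "country", "site_name", "lat", "lon", "glume_score",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT field required) into a :class:`GenotypeMatrix`.

    Diploid GT values are collapsed to dosage codes; any genotype
    containing an uncalled allele (``.``), including half-calls, maps to
    MISSING.  Multiallelic records and non-SNP records are dropped (the
    count is logged): all downstream statistics assume biallelic SNPs.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        # cyvcf2 refuses sample-less headers outright; report that precisely
        for line in Path(path).open():
            if line.startswith("#CHROM") and len(line.rstrip("\n").split("\t")) <= 9:
                raise GenotypeFormatError(f"{path}: VCF has zero samples") from None
        raise GenotypeFormatError(f"{path}: not a parseable VCF ({exc})") from exc
    if not vcf.samples:
        raise GenotypeFormatError(f"{path}: VCF has zero samples")
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise GenotypeFormatError(f"{path}: VCF lacks the GT FORMAT field") from None

    ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    site_rows: list[tuple] = []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_dropped += 1
            continue
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int64)
        calls = gts.sum(axis=1).astype(np.int8)
        calls[(gts < 0).any(axis=1)] = MISSING
        rows.append(calls)
        site_rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                          rec.ID if rec.ID not in (None, ".") else None))
    if n_dropped:
        logger.info("%s: dropped %d multiallelic/non-SNP records", path, n_dropped)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    calls = (np.column_stack(rows) if rows
             else np.empty((len(ids), 0), dtype=np.int8))
    return GenotypeMatrix(ids, sites, calls)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 that round-trips through :func:`read_vcf`."""
    path = Path(path)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accession_ids) + "\n")
        for j in range(G.n_sites):
            row = G.sites.iloc[j]
            sid = "." if pd.isna(row.id) or row.id is None else str(row.id)
            gts = "\t".join(gt_of[int(c)] for c in G.calls[:, j])
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{sid}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def _decode_hapmap_call(token: str, ref: str, alt: str) -> tuple[int, bool]:
    """Map one HapMap genotype token to a dosage code.

    Returns (code, inconsistent).  Accepts single IUPAC letters, two-letter
    pairs ("AG"), and slash pairs ("A/G"); N or NN is missing.
    """
    token = token.strip().upper().replace("/", "")
    if token in ("N", "NN", "", "."):
        return MISSING, False
    if len(token) == 1:
        if token in _BASES:
            pair = frozenset((token,))
        elif token in IUPAC_HET:
            pair = IUPAC_HET[token]
        else:
            return MISSING, True
    elif len(token) == 2 and set(token) <= _BASES:
        pair = frozenset(token)
    else:
        return MISSING, True
    if not pair <= {ref, alt}:
        return MISSING, True
    if pair == {ref, alt}:
        return 1, False
    return (0, False) if pair == {ref} else (2, False)


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """Read a TASSEL-dialect HapMap text file (11 metadata columns).

    Homozygous letters are oriented against the ``alleles`` column (first
    allele = reference); IUPAC ambiguity codes map to heterozygous; ``N``
    maps to MISSING.  Genotype letters inconsistent with the declared
    alleles are set MISSING and counted in a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise GenotypeFormatError(f"{path}: expected >= 12 HapMap columns, got {df.shape[1]}")
    sample_cols = list(df.columns[11:])
    n_inconsistent = 0
    site_rows: list[tuple] = []
    cols: list[np.ndarray] = []
    for _, row in df.iterrows():
        alleles = str(row.iloc[1]).upper().split("/")
        if len(alleles) != 2 or not set(alleles) <= _BASES:
            raise GenotypeFormatError(f"{path}: cannot parse alleles field {row.iloc[1]!r}")
        ref, alt = alleles
        col = np.empty(len(sample_cols), dtype=np.int8)
        for i, s in enumerate(sample_cols):
            code, bad = _decode_hapmap_call(str(row[s]), ref, alt)
            col[i] = code
            n_inconsistent += bad
        cols.append(col)
        rsid = str(row.iloc[0])
        site_rows.append((str(row.iloc[2]), int(row.iloc[3]), ref, alt,
                          rsid if rsid not in (".", "nan", "") else None))
    if n_inconsistent:
        logger.warning("%s: %d genotype calls inconsistent with declared alleles set MISSING",
                       path, n_inconsistent)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    calls = (np.column_stack(cols) if cols
             else np.empty((len(sample_cols), 0), dtype=np.int8))
    G = GenotypeMatrix(sample_cols, sites, calls)
    G.n_inconsistent_calls = n_inconsistent  # type: ignore[attr-defined]
    return G


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    return float(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    return str(v).strip()


def read_passport(path: str | Path) -> list[PassportRecord]:
    """Read a delimited passport table (header required, ``accession_id`` column required)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "accession_id" not in df.columns:
        raise PassportValidationError(f"{path}: no accession_id column")
    dup = df["accession_id"][df["accession_id"].duplicated()].tolist()
    if dup:
        raise PassportValidationError(f"{path}: duplicate accession ids: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        gs = _opt_float(row.get("glume_score"))
        records.append(PassportRecord(
            accession_id=str(row["accession_id"]).strip(),
            taxon=_opt_str(row.get("taxon")),
            race=_opt_str(row.get("race")),
            country=_opt_str(row.get("country")),
            site_name=_opt_str(row.get("site_name")),
            lat=_opt_float(row.get("lat")),
            lon=_opt_float(row.get("lon")),
            glume_score=None if gs is None else int(gs),
        ))
    return records


def write_passport(records: Sequence[PassportRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in PASSPORT_COLUMNS} for r in records])
    df.to_csv(path, index=False)


def passport_frame(records: Sequence[PassportRecord]) -> pd.DataFrame:
    """Passport records as a DataFrame indexed by accession_id."""
    df = pd.DataFrame([{c: getattr(r, c) for c in PASSPORT_COLUMNS} for r in records])
    return df.set_index("accession_id", drop=False)


def subset(G: GenotypeMatrix,
           accessions: Iterable[str] | None = None,
           site_indices: Iterable[int] | None = None) -> GenotypeMatrix:
    """Subset by accession ids and/or site indices, preserving input order.

    The retained rows/columns keep their order in ``G`` regardless of the
    order in which they are requested.
    """
    if accessions is None:
        row_idx = np.arange(G.n_accessions)
    else:
        wanted = set(accessions)
        unknown = wanted - set(G.accession_ids)
        if unknown:
            raise KeyError(f"unknown accession ids: {sorted(unknown)}")
        row_idx = np.array([i for i, a in enumerate(G.accession_ids) if a in wanted],
                           dtype=np.intp)
    if site_indices is None:
        col_idx = np.arange(G.n_sites)
    else:
        col_idx = np.unique(np.asarray(list(site_indices), dtype=np.intp))
        if len(col_idx) and (col_idx[0] < 0 or col_idx[-1] >= G.n_sites):
            raise IndexError(f"site index out of range [0, {G.n_sites})")
    return GenotypeMatrix(
        [G.accession_ids[i] for i in row_idx],
        G.sites.iloc[col_idx].reset_index(drop=True),
        G.calls[np.ix_(row_idx, col_idx)],
    )


def split_by_group(G: GenotypeMatrix, groups: dict[str, str]) -> dict[str, GenotypeMatrix]:
    """Partition accessions into per-group matrices by a label mapping."""
    out: dict[str, GenotypeMatrix] = {}
    for label in dict.fromkeys(groups.get(a) for a in G.accession_ids if a in groups):
        members = [a for a in G.accession_ids if groups.get(a) == label]
        out[str(label)] = subset(G, accessions=members)
    return out
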