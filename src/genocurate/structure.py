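"""Population structure: genetic distances, NJ tree, PCA, mislabel flagging.

Structure here serves curation: an unrooted neighbor-joining tree and a
relationship-matrix PCA reveal the species/race clusters, and a simple
k-nearest-neighbor vote on genetic distance proposes accessions whose
passport taxon disagrees with their genetic neighborhood.  Proposals are
advisory only — reclassification remains a curator decision.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .dedup import ibs_matrix
from .geno_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass
class NJTree:
    """Unrooted NJ tree (scikit-bio TreeNode) with negative lengths clamped to 0."""

    tree: TreeNode
    n_clamped: int = 0

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def tip_distances(self) -> pd.DataFrame:
        dm = self.tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


@dataclass
class PCAResult:
    ids: list[str]
    coordinates: np.ndarray
    variance_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(self.coordinates, index=self.ids,
                            columns=[f"PC{i + 1}" for i in range(k)])


def distance_matrix(G: GenotypeMatrix, metric: str = "one_minus_ibs",
                    min_compared: int = 1) -> DistanceMatrix:
    """Pairwise genetic distances.

    ``one_minus_ibs``: 1 minus the IBS fraction over jointly homozygous,
    non-missing loci (robust to missing data in selfing collections).
    ``euclidean``: root-sum-square of dosage differences over shared
    non-missing sites, rescaled by sqrt(L_total / L_shared) so sparser
    pairs are not biased toward smaller distances.
    """
    if metric == "one_minus_ibs":
        res = ibs_matrix(G, min_compared=min_compared)
        d = 1.0 - res.identity
        und = np.argwhere(~np.isfinite(d))
        if len(und):
            i, j = und[0]
            raise ValueError(
                f"identity undefined for pair ({res.ids[i]}, {res.ids[j]}): "
                f"only {res.compared[i, j]} compared loci")
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(G.accession_ids), d, metric)
    if metric == "euclidean":
        X = G.calls.astype(np.float64)
        M = (G.calls != MISSING).astype(np.float64)
        X = X * M
        sq = X ** 2
        shared = M @ M.T
        if (shared == 0).any():
            i, j = np.argwhere(shared == 0)[0]
            raise ValueError(f"no shared loci for pair "
                             f"({G.accession_ids[i]}, {G.accession_ids[j]})")
        ss = sq @ M.T + M @ sq.T - 2.0 * (X @ X.T)
        ss = np.maximum(ss, 0.0)
        d = np.sqrt(ss * (G.n_sites / shared))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        return DistanceMatrix(list(G.accession_ids), d, metric)
    raise ValueError(f"unknown metric {metric!r}")


def nj_tree(D: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining; negative branch estimates clamped to 0."""
    if len(D.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 accessions")
    tree = _skbio_nj(_SkbioDM(D.d, ids=D.ids))
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to zero", n_clamped)
    return NJTree(tree, n_clamped)


def to_newick(T: NJTree, path: str | Path) -> None:
    """Write the tree as Newick (labels with spaces are quoted by the writer)."""
    T.tree.write(str(path), format="newick")


def grm_pca(G: GenotypeMatrix, k: int = 10) -> PCAResult:
    """PCA of the additive genomic relationship matrix (VanRaden scaling).

    Each site is centered by twice its alternate-allele frequency (missing
    calls contribute the mean, i.e. 0 after centering); the relationship
    matrix is Z Z' / (2 * sum p(1-p)).  Coordinates are eigenvectors scaled
    by the square root of their eigenvalues; variance explained is
    eigenvalue / trace.
    """
    if G.n_accessions < 2:
        raise ValueError("PCA needs at least 2 accessions")
    calls = G.calls.astype(np.float64)
    miss = G.calls == MISSING
    called = ~miss
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0.0).sum(axis=0) / (2.0 * called.sum(axis=0))
    p = np.where(np.isfinite(p), p, 0.0)
    Z = np.where(miss, 0.0, calls - 2.0 * p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("no polymorphism: relationship matrix has zero scale")
    K = (Z @ Z.T) / denom
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, G.n_accessions)
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    trace = np.trace(K)
    var_exp = lam / trace if trace > 0 else np.zeros(k)
    return PCAResult(list(G.accession_ids), coords, var_exp)


def flag_misclassified(D: DistanceMatrix, labels: Mapping[str, str],
                       k_neighbors: int = 10, agreement: float = 0.8
                       ) -> list[tuple[str, str, str]]:
    """Propose passport-label corrections by k-nearest-neighbor vote.

    For each accession the majority taxon among its ``k_neighbors`` nearest
    non-self neighbors is compared with its own passport label; a proposal
    ``(accession, passport_label, genetic_label)`` is emitted when they
    disagree and the majority fraction reaches ``agreement``.  Duplicate
    accessions should be collapsed to one representative beforehand so
    clone clusters cannot out-vote the neighborhood.
    """
    n = len(D.ids)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of accessions ({n})")
    missing = [a for a in D.ids if a not in labels]
    if missing:
        raise KeyError(f"no label for accessions: {missing[:5]}")
    proposals = []
    for i, acc in enumerate(D.ids):
        order = np.argsort(D.d[i], kind="stable")
        neigh = [j for j in order if j != i][:k_neighbors]
        votes = pd.Series([labels[D.ids[j]] for j in neigh]).value_counts()
        top_label = votes.index[0]
        frac = votes.iloc[0] / k_neighbors
        if top_label != labels[acc] and frac >= agreement:
            proposals.append((acc, labels[acc], str(top_label)))
    return proposals


def proposals_frame(proposals: Sequence[tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(proposals, columns=["accession_id", "passport_label",
                                            "proposed_label"])
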