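"""Simple-matching dissimilarity, principal coordinates and NJ trees.

The simple-matching dissimilarity between two diploid multilocus profiles
is ``1 - (1/L) * sum_l s_l / 2`` where ``s_l`` is the number of allele
copies shared at locus ``l`` (multiset overlap over ploidy) and ``L`` runs
over loci scored in both profiles. PCoA is classical metric scaling
(double-centered -d^2/2, eigendecomposition); negative eigenvalues are
reported, not silently corrected. The neighbor-joining tree uses the
Saitou-Nei agglomeration and is exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from ssrpop.io import GenotypeTable


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` holds one column per retained axis (positive
    eigenvalues only), ordered by decreasing eigenvalue; ``eigenvalues``
    is the full spectrum including any negative values, which indicate a
    non-Euclidean input; ``proportion_explained`` is computed over the
    positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


@dataclass
class NJTree:
    """Unrooted NJ tree with raw branch lengths retained.

    Negative branch lengths (a known NJ artifact on non-additive input)
    are clamped to zero in ``newick``; ``raw_newick`` keeps them.
    """

    tree: TreeNode
    newick: str
    raw_newick: str


def simple_matching_dissimilarity(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise simple-matching dissimilarity between diploid profiles.

    Loci missing (or non-diploid) in either member of a pair are skipped
    and the denominator is the number of compared loci. A pair with zero
    comparable loci is an error: remove or impute those accessions first.
    """
    mat = table.diploid_matrix()
    n = mat.shape[0]
    x1, x2 = mat[:, :, 0], mat[:, :, 1]
    scored = x1 >= 0
    d = np.zeros((n, n))
    for i in range(n):
        both = scored[i][None, :] & scored
        eq11 = x1[i][None, :] == x1
        eq12 = x1[i][None, :] == x2
        eq21 = x2[i][None, :] == x1
        eq22 = x2[i][None, :] == x2
        full = (eq11 & eq22) | (eq12 & eq21)
        anyeq = eq11 | eq12 | eq21 | eq22
        shared = (2 * full + (anyeq & ~full)) * both   # copies shared per locus
        n_loci = both.sum(axis=1)
        if np.any(n_loci == 0) and n > 1:
            j = int(np.nonzero(n_loci == 0)[0][0])
            if j != i:
                raise ValueError(
                    f"accessions {table.accession_ids[i]} and "
                    f"{table.accession_ids[j]} share no comparable locus")
        with np.errstate(invalid="ignore"):
            d[i] = 1.0 - shared.sum(axis=1) / (2.0 * n_loci)
    d[np.arange(n), np.arange(n)] = 0.0
    d = (d + d.T) / 2.0  # symmetrize away float round-off
    return DistanceMatrix(d, ids=table.accession_ids)


def pcoa(dm: DistanceMatrix, cailliez: bool = False) -> PCoAResult:
    """Principal Coordinate Analysis by classical metric scaling.

    Computes the eigendecomposition of the double-centered matrix
    ``-0.5 * J d^2 J``. Axes with eigenvalues <= 0 carry no coordinates;
    with ``cailliez=True`` the Cailliez constant is added to off-diagonal
    distances first, making the input Euclidean.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NA entries; "
                         "impute or remove those accessions before PCoA")
    if cailliez:
        d = d + _cailliez_constant(d) * (1 - np.eye(len(d)))
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids),
            columns=[f"PCo{k + 1}" for k in range(coords.shape[1])]),
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -1e-10],
    )


def _cailliez_constant(d: np.ndarray) -> float:
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    w1 = -0.5 * j @ (d**2) @ j
    w2 = -0.5 * j @ d @ j
    top = np.hstack([np.zeros((n, n)), 2 * w1])
    bot = np.hstack([-np.eye(n), -4 * w2])
    evals = np.linalg.eigvals(np.vstack([top, bot]))
    return float(max(0.0, np.max(evals.real)))


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic label handling.

    Additive input matrices are reconstructed exactly (topology and branch
    lengths). For two taxa the result is the degenerate single-edge tree.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NA entries")
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("neighbor joining needs at least 2 labels")
    if len(ids) == 2:
        raw = f"({ids[0]}:{d[0, 1]:.10g},{ids[1]}:0.0);"
        tree = TreeNode.read([raw])
        return NJTree(tree=tree, newick=raw, raw_newick=raw)
    raw_tree = _skbio_nj(dm, neg_as_zero=False)
    raw = str(raw_tree).strip()
    clamped = raw_tree.copy()
    for node in clamped.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return NJTree(tree=clamped, newick=str(clamped).strip(), raw_newick=raw)


def tree_distance_matrix(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Patristic (path-length) distances between leaves, in ``ids`` order."""
    tdm = tree.tip_tip_distances(endpoints=ids)
    frame = pd.DataFrame(tdm.data, index=list(tdm.ids), columns=list(tdm.ids))
    return frame.loc[ids, ids].to_numpy()
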