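"""Duplicate-accession resolution and putative-triploid flagging.

Clonally propagated accessions frequently appear several times in and
across germplasm collections. Two accessions are treated as duplicates
(the same clone) if their multilocus SSR fingerprints are identical, or if
they show a single-allele difference at no more than two loci -- slack that
absorbs occasional scoring errors and somatic SSR mutations. Duplicate
groups are the connected components of this pairwise relation, mirroring
the unique-group codes (FBUNQ analogue) used in germplasm curation.

An accession is flagged as a putative triploid when at least three loci
show three distinct alleles; triploids are excluded from grouping (and
from all diploid statistics downstream) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ssrpop.io import Call, GenotypeTable

logger = logging.getLogger(__name__)

TRIPLOID_MIN_LOCI = 3        # loci with 3 distinct alleles to call a triploid
DEFAULT_MAX_MISMATCH_LOCI = 2  # loci allowed a single-allele difference
DEFAULT_MIN_SHARED_LOCI = 12   # scored-in-both loci required to compare a pair


@dataclass(frozen=True)
class DuplicateGroup:
    group_id: str
    members: tuple[str, ...]      # sorted accession ids, len >= 2
    representative: str           # lexicographically smallest member


@dataclass(frozen=True)
class PloidyFlag:
    accession_id: str
    n_triallelic_loci: int
    is_putative_triploid: bool


def locus_difference(call_a: Call, call_b: Call) -> int:
    """Number of allele copies of a diploid call not shared with another.

    Returns ``2 - |multiset intersection|``: 0 = identical genotype,
    1 = exactly one shared copy, 2 = fully disjoint genotypes.
    """
    if len(call_a) != 2 or len(call_b) != 2:
        raise ValueError("locus_difference requires two diploid calls")
    a1, a2 = call_a
    b1, b2 = call_b
    if (a1 == b1 and a2 == b2) or (a1 == b2 and a2 == b1):
        return 0
    if a1 in (b1, b2) or a2 in (b1, b2):
        return 1
    return 2


def are_duplicates(
    profile_a: list[Call],
    profile_b: list[Call],
    max_mismatch_loci: int = DEFAULT_MAX_MISMATCH_LOCI,
    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
) -> bool:
    """Apply the duplicate criterion to two multilocus profiles.

    True iff, over loci diploid-scored in both profiles (at least
    ``min_shared_loci`` of them), no locus is fully disjoint and at most
    ``max_mismatch_loci`` loci differ by a single allele copy. Pairs with
    too few comparable loci are incomparable and reported non-duplicate.
    """
    shared = 0
    n_single = 0
    for ca, cb in zip(profile_a, profile_b):
        if len(ca) != 2 or len(cb) != 2:
            continue
        shared += 1
        d = locus_difference(ca, cb)
        if d == 2:
            return False
        n_single += d
        if n_single > max_mismatch_loci:
            return False
    if shared < min_shared_loci:
        logger.debug("pair incomparable: only %d shared loci", shared)
        return False
    return True


def _pairwise_difference_profile(mat: np.ndarray):
    """Vectorized pairwise comparison of diploid calls.

    ``mat`` is the (n, L, 2) sorted diploid matrix with -1 for unscored
    cells. Returns boolean helper arrays used by the grouping routine:
    per pair, the number of comparable loci, whether any locus is fully
    disjoint, and the count of single-copy differences.
    """
    n = mat.shape[0]
    x1, x2 = mat[:, :, 0], mat[:, :, 1]
    scored = x1 >= 0
    n_shared = np.zeros((n, n), dtype=np.int32)
    any_disjoint = np.zeros((n, n), dtype=bool)
    n_single = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        both = scored[i][None, :] & scored          # (n, L)
        eq11 = x1[i][None, :] == x1
        eq12 = x1[i][None, :] == x2
        eq21 = x2[i][None, :] == x1
        eq22 = x2[i][None, :] == x2
        full = (eq11 & eq22) | (eq12 & eq21)        # both copies shared
        anyeq = eq11 | eq12 | eq21 | eq22
        single = anyeq & ~full
        disjoint = ~anyeq
        n_shared[i] = both.sum(axis=1)
        any_disjoint[i] = (disjoint & both).any(axis=1)
        n_single[i] = (single & both).sum(axis=1)
    return n_shared, any_disjoint, n_single


def flag_triploids(table: GenotypeTable) -> list[PloidyFlag]:
    """Flag accessions with >= 3 loci showing three distinct alleles."""
    counts = table.triploid_locus_counts()
    return [
        PloidyFlag(acc.accession_id, int(c), bool(c >= TRIPLOID_MIN_LOCI))
        for acc, c in zip(table.accessions, counts)
    ]


def find_duplicate_groups(
    table: GenotypeTable,
    max_mismatch_loci: int = DEFAULT_MAX_MISMATCH_LOCI,
    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
    exclude_triploids: bool = True,
) -> tuple[list[DuplicateGroup], GenotypeTable]:
    """Build duplicate groups and the reduced table of unique genotypes.

    Groups are connected components of the pairwise duplicate relation
    (transitive closure), so chained near-matches collapse into one group
    even when distant members exceed the pairwise tolerance. One
    representative (lexicographically smallest accession id) is retained
    per group; the reduced table holds representatives plus singletons, in
    the original row order.

    Putative triploids are excluded from grouping by default (they pass
    through to the reduced table untouched); with
    ``exclude_triploids=False`` they are compared on their diploid loci
    only.
    """
    ids = table.accession_ids
    if exclude_triploids:
        triploid = {f.accession_id for f in flag_triploids(table)
                    if f.is_putative_triploid}
    else:
        triploid = set()
    comparable_idx = [i for i, a in enumerate(ids) if a not in triploid]

    mat = table.diploid_matrix()[comparable_idx]
    n_shared, any_disjoint, n_single = _pairwise_difference_profile(mat)
    dup = ((~any_disjoint) & (n_single <= max_mismatch_loci)
           & (n_shared >= min_shared_loci))
    np.fill_diagonal(dup, False)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(comparable_idx)))
    graph.add_edges_from(zip(*np.nonzero(np.triu(dup))))

    groups: list[DuplicateGroup] = []
    drop: set[str] = set()
    comps = [sorted(ids[comparable_idx[j]] for j in comp)
             for comp in nx.connected_components(graph) if len(comp) > 1]
    for members in sorted(comps):
        rep = members[0]
        groups.append(DuplicateGroup(
            group_id=f"DUP{len(groups) + 1:03d}",
            members=tuple(members), representative=rep))
        drop.update(m for m in members if m != rep)

    reduced = table.subset([a for a in ids if a not in drop])
    logger.info("duplicate grouping: %d groups, %d redundant accessions removed",
                len(groups), len(drop))
    return groups, reduced


def cumulative_pid_report(freqs) -> float:
    """Cumulative probability of identity over loci (match-confidence report).

    Thin wrapper over :func:`ssrpop.diversity.probability_of_identity`,
    reported alongside duplicate groups to qualify the risk that two
    unrelated genotypes share a full multilocus profile by chance.
    """
    from ssrpop.diversity import probability_of_identity

    per_locus, cumulative = probability_of_identity(freqs)
    return cumulative
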