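"""Likelihood-based two-parent (trio) parentage reconstruction.

For an offspring genotype g_o and a candidate parent pair (g_A, g_B), the
per-locus likelihood ratio compares Mendelian segregation from the pair
against a random Hardy-Weinberg draw from the population:

    LOD = sum_l ln [ P(g_o | g_A, g_B; e) / P(g_o) ]

with an error-tolerant transmission model: each transmitted allele copy
is, with probability ``e``, replaced by a random draw from the population
allele frequencies (mistyping / null alleles / mutation). The Delta
statistic is the LOD gap between the best and second-best candidate pair;
its acceptance threshold is calibrated by simulating offspring of known
parentage and locating the smallest Delta at which the requested fraction
(95 % by default) of accepted assignments is correct. A hard constraint
of at most one Mendelian-impossible locus per trio is applied throughout.
Only complete pairs are considered -- single-parent inference is
deliberately out of scope -- and parent order carries no meaning (the pair
is reported sorted by id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ssrpop.diversity import AlleleFrequencies, allele_frequencies
from ssrpop.io import GenotypeTable

DEFAULT_ERROR_RATE = 0.01
DEFAULT_MAX_MISMATCH = 1


@dataclass(frozen=True)
class TrioCandidate:
    offspring_id: str
    parent_a: str                 # pair sorted by id; order carries no meaning
    parent_b: str
    lod: float
    delta: float                  # LOD gap to the second-best pair
    mismatching_loci: int
    confidence: str               # "high_95" or "unassigned"


@dataclass
class ConfidenceCalibration:
    n_simulations: int
    sampled_fraction: float
    error_rate: float
    delta_threshold: float
    precision_at_threshold: float   # correct fraction among accepted sims
    recovery_at_threshold: float    # correctly accepted / all simulations
    n_assigned: int


def trio_lod(
    offspring: list,
    parent_a: list,
    parent_b: list,
    freqs: AlleleFrequencies,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> tuple[float, int]:
    """LOD and Mendelian-mismatch count for one trio.

    Profiles are per-locus call tuples aligned with ``freqs.loci``. Loci
    missing in any of the three members are skipped. The mismatch count is
    the number of loci that are Mendelian-impossible at e = 0; at
    ``error_rate == 0`` any such locus makes the LOD -inf.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    lod = 0.0
    mismatch = 0
    for locus, g_o, g_a, g_b in zip(freqs.loci, offspring, parent_a, parent_b):
        if len(g_o) != 2 or len(g_a) != 2 or len(g_b) != 2:
            continue
        p = freqs.freqs[locus]
        o1, o2 = g_o
        ta1, ta2 = _transmission(g_a, o1, o2, p, error_rate)
        tb1, tb2 = _transmission(g_b, o1, o2, p, error_rate)
        if o1 != o2:
            num = ta1 * tb2 + ta2 * tb1
            den = 2.0 * p[o1] * p[o2]
        else:
            num = ta1 * tb1
            den = p[o1] ** 2
        possible = ((o1 in g_a and o2 in g_b) or (o2 in g_a and o1 in g_b))
        if not possible:
            mismatch += 1
        if num == 0.0:
            lod = -math.inf
        elif math.isfinite(lod):
            lod += math.log(num / den)
    return lod, mismatch


def _transmission(parent, o1, o2, p, e):
    """P(parent transmits o1), P(transmits o2) under the error model."""
    m1 = (parent[0] == o1) * 0.5 + (parent[1] == o1) * 0.5
    m2 = (parent[0] == o2) * 0.5 + (parent[1] == o2) * 0.5
    return (1 - e) * m1 + e * p[o1], (1 - e) * m2 + e * p[o2]


# -- vectorized candidate machinery -----------------------------------------

class _Pool:
    """Candidate-parent pool with precomputed arrays for fast screening."""

    def __init__(self, table: GenotypeTable, freqs: AlleleFrequencies | None = None,
                 error_rate: float = DEFAULT_ERROR_RATE):
        self.ids = table.accession_ids
        self.calls = table.calls
        self.loci = table.locus_names
        self.arr = table.diploid_matrix()              # (m, L, 2), -1 missing
        self.scored = self.arr[:, :, 0] >= 0
        self.freqs = freqs or allele_frequencies(table)["all"]
        self.error_rate = error_rate

    def carries(self, off_row: np.ndarray):
        """Booleans: does each pool member carry offspring allele 1 / 2, per locus."""
        o1 = off_row[:, 0][None, :]
        o2 = off_row[:, 1][None, :]
        c1 = (self.arr[:, :, 0] == o1) | (self.arr[:, :, 1] == o1)
        c2 = (self.arr[:, :, 0] == o2) | (self.arr[:, :, 1] == o2)
        return c1, c2

    def candidate_parents(self, off_row, off_scored, max_mismatch):
        """Members sharing >= 1 allele with the offspring at all but
        <= max_mismatch jointly scored loci (necessary trio condition)."""
        c1, c2 = self.carries(off_row)
        both = self.scored & off_scored[None, :]
        nonshare = (both & ~(c1 | c2)).sum(axis=1)
        return np.nonzero(nonshare <= max_mismatch)[0], c1, c2, both


def enumerate_trios(
    table: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    offspring_ids: list[str] | None = None,
    error_rate: float = DEFAULT_ERROR_RATE,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    _pool: _Pool | None = None,
) -> dict[str, list[TrioCandidate]]:
    """Score all parent pairs with <= ``max_mismatch`` impossible loci.

    Candidate parents are every unique genotype except the offspring
    itself and any member with an identical profile (self/clone guard).
    For each offspring the surviving pairs are ranked by LOD; Delta is the
    gap to the second-best pair (or the best LOD itself when it has no
    competitor). Offspring with no surviving pair map to an empty list.
    """
    pool = _pool or _Pool(table, freqs, error_rate)
    if offspring_ids is None:
        offspring_ids = pool.ids
    results: dict[str, list[TrioCandidate]] = {}
    for off_id in offspring_ids:
        i = pool.ids.index(off_id)
        results[off_id] = _trios_for_offspring(
            pool, pool.arr[i], pool.scored[i], pool.calls[i],
            exclude={i}, max_mismatch=max_mismatch, offspring_id=off_id)
    return results


def _trios_for_offspring(pool: _Pool, off_row, off_scored, off_calls,
                         exclude, max_mismatch, offspring_id):
    cand, c1, c2, both = pool.candidate_parents(off_row, off_scored, max_mismatch)
    cand = [j for j in cand
            if j not in exclude and pool.arr[j][pool.scored[j] & off_scored].size
            and not _identical_profile(pool.arr[j], off_row,
                                       pool.scored[j], off_scored)]
    scored_pairs = []
    for ai in range(len(cand)):
        for bi in range(ai, len(cand)):   # a parent may be crossed with itself? no:
            if bi == ai:
                continue
            j, k = cand[ai], cand[bi]
            ok_l = (c1[j] & c2[k]) | (c2[j] & c1[k])
            all3 = both[j] & both[k]
            mm = int((all3 & ~ok_l).sum())
            if mm > max_mismatch:
                continue
            lod, mm_exact = trio_lod(off_calls, pool.calls[j], pool.calls[k],
                                     pool.freqs, pool.error_rate)
            if not math.isfinite(lod):
                continue
            pa, pb = sorted((pool.ids[j], pool.ids[k]))
            scored_pairs.append((lod, pa, pb, mm_exact))
    scored_pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    out = []
    for rank, (lod, pa, pb, mm) in enumerate(scored_pairs):
        if rank == 0:
            delta = (lod - scored_pairs[1][0]) if len(scored_pairs) > 1 else lod
            delta = max(delta, 0.0)
        else:
            delta = 0.0
        out.append(TrioCandidate(offspring_id, pa, pb, lod, delta, mm,
                                 "unassigned"))
    return out


def _identical_profile(row_a, row_b, scored_a, scored_b) -> bool:
    both = scored_a & scored_b
    return bool(both.any() and np.array_equal(row_a[both], row_b[both]))


# -- simulation-based confidence --------------------------------------------

def calibrate_confidence(
    table: GenotypeTable,
    n_simulations: int = 10_000,
    error_rate: float = DEFAULT_ERROR_RATE,
    sampled_fraction: float = 0.9,
    confidence: float = 0.95,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seed: int = 0,
) -> ConfidenceCalibration:
    """Find the Delta threshold giving the requested assignment confidence.

    Offspring are simulated from random parent pairs drawn from the
    observed unique genotypes; each true parent is present in the
    candidate pool with probability ``sampled_fraction``. The threshold is
    the smallest Delta at which the fraction of correct best-trio
    assignments above it reaches ``confidence``.
    """
    rng = np.random.default_rng(seed)
    pool = _Pool(table, error_rate=error_rate)
    m, n_loci = pool.arr.shape[0], pool.arr.shape[1]
    if m < 3:
        raise ValueError("need at least 3 unique genotypes to calibrate")
    loci = pool.loci
    freq_arrays = {
        l: (np.array(list(pool.freqs.freqs[l].keys())),
            np.array(list(pool.freqs.freqs[l].values())))
        for l in loci
    }

    deltas, corrects = [], []
    for _ in range(n_simulations):
        pa, pb = rng.choice(m, size=2, replace=False)
        off_calls, off_row, off_scored = _simulate_offspring(
            pool, pa, pb, freq_arrays, error_rate, rng)
        drop = rng.random(2) > sampled_fraction   # each true parent is in the
        exclude = set(np.array([pa, pb])[drop].tolist())  # pool w.p. sampled_fraction
        trios = _trios_for_offspring(pool, off_row, off_scored, off_calls,
                                     exclude=exclude, max_mismatch=max_mismatch,
                                     offspring_id="sim")
        if not trios:
            continue
        best = trios[0]
        truth = tuple(sorted((pool.ids[pa], pool.ids[pb])))
        deltas.append(best.delta)
        corrects.append((best.parent_a, best.parent_b) == truth)
    if not deltas:
        raise ValueError("no simulated offspring produced an assignment; "
                         "increase n_simulations")

    order = np.argsort(deltas)[::-1]
    d_sorted = np.asarray(deltas)[order]
    c_sorted = np.asarray(corrects)[order]
    precision = np.cumsum(c_sorted) / np.arange(1, len(c_sorted) + 1)
    valid = np.nonzero(precision >= confidence)[0]
    if valid.size == 0:
        threshold, prec, recov = np.inf, np.nan, 0.0
    else:
        cut = valid[-1]
        threshold = float(d_sorted[cut])
        prec = float(precision[cut])
        recov = float(c_sorted[:cut + 1].sum() / n_simulations)
    return ConfidenceCalibration(
        n_simulations=n_simulations, sampled_fraction=sampled_fraction,
        error_rate=error_rate, delta_threshold=threshold,
        precision_at_threshold=prec, recovery_at_threshold=recov,
        n_assigned=len(deltas))


def _simulate_offspring(pool, pa, pb, freq_arrays, error_rate, rng):
    """Mendelian offspring of pool members pa x pb with genotyping error."""
    calls = []
    for l, locus in enumerate(pool.loci):
        if not (pool.scored[pa, l] and pool.scored[pb, l]):
            calls.append(())
            continue
        alleles = []
        for parent in (pa, pb):
            a = int(pool.arr[parent, l, rng.integers(2)])
            if rng.random() < error_rate:
                sizes, probs = freq_arrays[locus]
                a = int(rng.choice(sizes, p=probs))
            alleles.append(a)
        calls.append(tuple(sorted(alleles)))
    row = np.array([c if len(c) == 2 else (-1, -1) for c in calls])
    scored = row[:, 0] >= 0
    return calls, row, scored


def infer_trios(
    table: GenotypeTable,
    error_rate: float = DEFAULT_ERROR_RATE,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    confidence: float = 0.95,
    n_simulations: int = 10_000,
    sampled_fraction: float = 0.9,
    seed: int = 0,
    calibration: ConfidenceCalibration | None = None,
) -> tuple[list[TrioCandidate], ConfidenceCalibration]:
    """Full parentage scan of a unique-genotype table.

    Every genotype is tested as an offspring against all pairs of other
    genotypes; the best pair is accepted when its Delta reaches the
    simulation-calibrated threshold and the trio has at most
    ``max_mismatch`` Mendelian-impossible loci. Accepted trios carry
    ``confidence="high_95"``.
    """
    if calibration is None:
        calibration = calibrate_confidence(
            table, n_simulations=n_simulations, error_rate=error_rate,
            sampled_fraction=sampled_fraction, confidence=confidence, seed=seed)
    pool = _Pool(table, error_rate=error_rate)
    accepted = []
    for i, off_id in enumerate(pool.ids):
        trios = _trios_for_offspring(pool, pool.arr[i], pool.scored[i],
                                     pool.calls[i], exclude={i},
                                     max_mismatch=max_mismatch,
                                     offspring_id=off_id)
        if trios and trios[0].delta >= calibration.delta_threshold:
            best = trios[0]
            accepted.append(TrioCandidate(
                best.offspring_id, best.parent_a, best.parent_b, best.lod,
                best.delta, best.mismatching_loci, "high_95"))
    accepted.sort(key=lambda t: t.offspring_id)
    return accepted, calibration
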