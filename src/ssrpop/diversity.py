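"""Per-locus and per-group diversity statistics for co-dominant SSR data.

Statistics follow the conventions of the classical population-genetics
toolchain for microsatellites: allele counts (N_A), rare-allele counts
(N_B, frequency below a threshold), effective allele number
(N_E = 1/sum p_i^2), observed heterozygosity (Ho), Nei's unbiased expected
heterozygosity (He, gene diversity with the N/(N-1) small-sample
correction on gene copies), probability of identity (P_ID), hypergeometric
rarefaction of allelic richness to a standard number of gene copies, and
private/unique allele counts across a partition of the accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ssrpop.io import GenotypeTable


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies and gene-copy counts for one group.

    ``freqs[locus]`` maps allele size -> frequency (summing to 1);
    ``counts[locus]`` maps allele size -> copy count; ``n_copies[locus]``
    is the number of scored gene copies (2 x scored diploids).
    """

    loci: list[str]
    counts: dict[str, dict[int, int]]
    freqs: dict[str, dict[int, float]] = field(default_factory=dict)
    n_copies: dict[str, int] = field(default_factory=dict)
    undefined_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.freqs:
            for locus in self.loci:
                n = sum(self.counts[locus].values())
                self.n_copies[locus] = n
                if n == 0:
                    self.freqs[locus] = {}
                    if locus not in self.undefined_loci:
                        self.undefined_loci.append(locus)
                else:
                    self.freqs[locus] = {a: c / n
                                         for a, c in self.counts[locus].items()}
        self.validate()

    def validate(self) -> None:
        for locus in self.loci:
            p = self.freqs.get(locus, {})
            if p and abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at locus {locus} are not normalized")


def allele_frequencies(
    table: GenotypeTable,
    grouping: dict[str, str] | None = None,
) -> dict[str, AlleleFrequencies]:
    """Allele frequencies per group (diploid calls only; missing excluded).

    ``grouping`` maps accession_id -> group label; accessions absent from
    the map are ignored. Without a grouping a single group ``"all"`` is
    returned. Each allele copy is counted once; loci where a group has no
    scored copies are listed in ``undefined_loci``.
    """
    if grouping is None:
        grouping = {a: "all" for a in table.accession_ids}
    groups = sorted(set(grouping.values()))
    counts = {g: {l: {} for l in table.locus_names} for g in groups}
    for acc, row in zip(table.accessions, table.calls):
        g = grouping.get(acc.accession_id)
        if g is None:
            continue
        for locus, call in zip(table.locus_names, row):
            if len(call) == 2:
                for a in call:
                    counts[g][locus][a] = counts[g][locus].get(a, 0) + 1
    return {g: AlleleFrequencies(loci=list(table.locus_names), counts=counts[g])
            for g in groups}


def probability_of_identity(freqs: AlleleFrequencies) -> tuple[pd.Series, float]:
    """Probability that two random unrelated genotypes match, per locus.

    P_ID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2, i.e. the probability that
    two independent Hardy-Weinberg genotypes are identical. The cumulative
    value is the product over (independent) loci; loci without data
    contribute a factor of 1.
    """
    per_locus = {}
    for locus in freqs.loci:
        p = np.array(list(freqs.freqs[locus].values()))
        if p.size == 0:
            per_locus[locus] = 1.0
            continue
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        per_locus[locus] = 2.0 * s2**2 - s4   # = s4 + sum_{i<j} (2 p_i p_j)^2
    series = pd.Series(per_locus, name="P_ID")
    return series, float(series.prod())


def allelic_richness(counts: dict[int, int] | np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a sample of ``g`` gene copies.

    Hypergeometric rarefaction: A_R(g) = sum_i [1 - C(N-N_i, g) / C(N, g)]
    where N_i are the observed copy counts and N their total. ``g`` is in
    gene copies (2n), not individuals.
    """
    ni = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                    dtype=np.int64)
    if np.any(ni <= 0):
        raise ValueError("allele copy counts must be positive integers")
    n = int(ni.sum())
    if not 1 <= g <= n:
        raise ValueError(f"rarefaction size g={g} must be in [1, {n}]")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = ni <= n - g  # alleles with N - N_i < g are always sampled
    terms = np.ones_like(ni, dtype=float)
    if keep.any():
        terms[keep] = 1.0 - np.exp(log_comb(n - ni[keep], g) - log_comb(n, g))
    return float(terms.sum())


def diversity_stats(
    table: GenotypeTable,
    grouping: dict[str, str] | None = None,
    rare_threshold: float = 0.05,
    rarefy_to: int | None = None,
) -> pd.DataFrame:
    """Per-locus diversity statistics, one row per (group, locus).

    Columns: N (gene copies), N_A, N_B (alleles with frequency strictly
    below ``rare_threshold``), N_E, Ho, He (Nei unbiased), He_uncorrected,
    P_ID and, if ``rarefy_to`` is given, A_R at that many gene copies.
    A summary row (locus ``"mean"``) averages over loci.
    """
    if grouping is None:
        grouping = {a: "all" for a in table.accession_ids}
    freq_by_group = allele_frequencies(table, grouping)

    het = {g: {l: [0, 0] for l in table.locus_names} for g in freq_by_group}
    for acc, row in zip(table.accessions, table.calls):
        g = grouping.get(acc.accession_id)
        if g is None:
            continue
        for locus, call in zip(table.locus_names, row):
            if len(call) == 2:
                het[g][locus][1] += 1
                if call[0] != call[1]:
                    het[g][locus][0] += 1

    rows = []
    for g, freqs in freq_by_group.items():
        for locus in freqs.loci:
            p = np.array(list(freqs.freqs[locus].values()))
            n = freqs.n_copies[locus]
            if n < 2:
                rows.append((g, locus, n) + (np.nan,) * 7)
                continue
            s2 = float(np.sum(p**2))
            he_raw = 1.0 - s2
            he = he_raw * n / (n - 1)
            n_het, n_ind = het[g][locus]
            ho = n_het / n_ind if n_ind else np.nan
            ar = (allelic_richness(freqs.counts[locus], rarefy_to)
                  if rarefy_to is not None else np.nan)
            rows.append((g, locus, n, len(p),
                         int(np.sum(p < rare_threshold)), 1.0 / s2,
                         ho, he, he_raw, ar))
    df = pd.DataFrame(rows, columns=["group", "locus", "N", "N_A", "N_B",
                                     "N_E", "Ho", "He", "He_uncorrected", "A_R"])
    means = (df.groupby("group", as_index=False)
               .mean(numeric_only=True).assign(locus="mean"))
    return pd.concat([df, means[df.columns]], ignore_index=True)


def private_and_unique_alleles(
    table: GenotypeTable,
    grouping: dict[str, str],
) -> pd.DataFrame:
    """Counts of private and unique alleles per group.

    A *private* allele occurs in exactly one group of the partition; a
    *unique* allele is carried by exactly one accession overall (counted
    here for the group holding that accession). Accessions outside the
    grouping do not contribute.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("private alleles require at least two groups")
    present: dict[tuple[str, int], set[str]] = {}
    carriers: dict[tuple[str, int], set[str]] = {}
    for acc, row in zip(table.accessions, table.calls):
        g = grouping.get(acc.accession_id)
        if g is None:
            continue
        for locus, call in zip(table.locus_names, row):
            for a in call:
                present.setdefault((locus, a), set()).add(g)
                carriers.setdefault((locus, a), set()).add(acc.accession_id)

    private = {g: 0 for g in groups}
    unique = {g: 0 for g in groups}
    total = {g: 0 for g in groups}
    for key, gs in present.items():
        for g in gs:
            total[g] += 1
        if len(gs) == 1:
            (g,) = gs
            private[g] += 1
        if len(carriers[key]) == 1:
            acc_id = next(iter(carriers[key]))
            unique[grouping[acc_id]] += 1
    return pd.DataFrame({
        "group": groups,
        "n_alleles": [total[g] for g in groups],
        "private": [private[g] for g in groups],
        "unique": [unique[g] for g in groups],
    })


def frequent_allele_chi2(
    table: GenotypeTable,
    grouping: dict[str, str],
    frequent_threshold: float = 0.05,
    mc_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Chi-square test of frequent-allele distribution across groups, per locus.

    Frequent alleles are defined on the pooled frequencies (> threshold);
    copies of all other alleles are pooled into an ``other`` column to
    stabilize expected counts. When expected counts still fall below 1,
    the asymptotic p-value is replaced by a seeded Monte-Carlo permutation
    p-value (group labels of gene copies permuted).
    """
    rng = np.random.default_rng(seed)
    pooled = allele_frequencies(table)["all"]
    by_group = allele_frequencies(table, grouping)
    groups = sorted(by_group)
    rows = []
    for locus in table.locus_names:
        frequent = sorted(a for a, p in pooled.freqs[locus].items()
                          if p > frequent_threshold)
        cols = frequent + ["other"]
        obs = np.zeros((len(groups), len(cols)))
        for gi, g in enumerate(groups):
            for a, c in by_group[g].counts[locus].items():
                j = frequent.index(a) if a in frequent else len(frequent)
                obs[gi, j] += c
        obs = obs[:, obs.sum(axis=0) > 0]
        if obs.shape[1] < 2 or obs.shape[0] < 2 or (obs.sum(axis=1) == 0).any():
            rows.append((locus, np.nan, np.nan, np.nan, "undefined"))
            continue
        chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
        method = "asymptotic"
        if (expected < 1).any():
            method = "monte_carlo"
            p = _chi2_permutation_p(obs, chi2, mc_permutations, rng)
        rows.append((locus, chi2, dof, p, method))
    return pd.DataFrame(rows, columns=["locus", "chi2", "df", "p_value", "method"])


def _chi2_permutation_p(obs: np.ndarray, observed_stat: float,
                        n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p-value for a contingency table with fixed margins."""
    row_tot = obs.sum(axis=1).astype(int)
    labels = np.repeat(np.arange(obs.shape[1]),
                       obs.sum(axis=0).astype(int))
    n_rows = obs.shape[0]
    count = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = np.zeros_like(obs)
        start = 0
        for gi in range(n_rows):
            seg = labels[start:start + row_tot[gi]]
            perm[gi] = np.bincount(seg, minlength=obs.shape[1])
            start += row_tot[gi]
        stat = stats.chi2_contingency(perm + 1e-12, correction=False)[0]
        count += stat >= observed_stat - 1e-12
    return (count + 1) / (n_perm + 1)
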