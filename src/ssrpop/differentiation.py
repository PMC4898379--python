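"""Population differentiation: pairwise F_ST and AMOVA with permutation tests.

F_ST uses the multi-allelic Weir & Cockerham (1984) theta: variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are summed over alleles and loci before taking
the ratio (ratio of sums, not mean of ratios). AMOVA decomposes allelic
variance among vs within groups on the infinite-allele 0/1 mismatch
distance between gene copies, the usual non-stepwise treatment of SSRs.
Significance of both comes from permuting whole individuals (both allele
copies together) between groups, with the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ssrpop.io import GenotypeTable


@dataclass
class AmovaResult:
    partition: str
    df_among: int
    df_within: int
    sigma_among: float
    sigma_within: float
    pct_among: float      # clamped at 0 when the raw component is negative
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int


@dataclass
class FstMatrix:
    groups: list[str]
    fst: pd.DataFrame       # symmetric, zero diagonal; raw (may be < 0)
    p_values: pd.DataFrame


# -- internal per-locus encodings -------------------------------------------

def _locus_encodings(table: GenotypeTable, ids: list[str] | None = None):
    """Per locus: dosage (n, A) and heterozygote-indicator (n, A) matrices.

    Rows are accessions (order of ``ids``); unscored individuals have
    all-zero rows. Only diploid calls contribute.
    """
    sub = table if ids is None else table.subset(ids)
    mat = sub.diploid_matrix()
    out = []
    for l in range(sub.n_loci):
        calls = mat[:, l, :]
        scored = calls[:, 0] >= 0
        alleles = np.unique(calls[scored])
        amap = {a: k for k, a in enumerate(alleles)}
        n = calls.shape[0]
        dosage = np.zeros((n, len(alleles)))
        het = np.zeros((n, len(alleles)))
        for i in np.nonzero(scored)[0]:
            a, b = calls[i]
            dosage[i, amap[a]] += 1
            dosage[i, amap[b]] += 1
            if a != b:
                het[i, amap[a]] = 1
                het[i, amap[b]] = 1
        out.append((dosage, het, scored))
    return out


def _theta_from_encodings(encodings, labels: np.ndarray) -> float:
    """Weir-Cockerham theta over loci for integer group labels."""
    a_sum = 0.0
    abc_sum = 0.0
    groups = np.unique(labels)
    onehot_all = labels[:, None] == groups[None, :]
    for dosage, het, scored in encodings:
        m = onehot_all[scored]                      # (n_scored, G)
        d, h = dosage[scored], het[scored]
        n_i = m.sum(axis=0).astype(float)
        use = n_i > 0
        if use.sum() < 2:
            continue
        m, n_i = m[:, use], n_i[use]
        r = float(use.sum())
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1)
        psum = m.T @ d                              # (G, A) copy counts
        hsum = m.T @ h
        p_i = psum / (2 * n_i[:, None])
        p_bar = psum.sum(axis=0) / (2 * r * n_bar)
        s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = hsum.sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_sum += a.sum()
        abc_sum += (a + b + c).sum()
    if abc_sum == 0:
        return np.nan
    return a_sum / abc_sum


def weir_cockerham_theta(table: GenotypeTable, grouping: dict[str, str]) -> float:
    """Multi-locus, multi-allelic theta for an arbitrary partition."""
    ids = [a for a in table.accession_ids if a in grouping]
    groups = sorted({grouping[a] for a in ids})
    labels = np.array([groups.index(grouping[a]) for a in ids])
    return _theta_from_encodings(_locus_encodings(table, ids), labels)


def pairwise_fst(
    table: GenotypeTable,
    grouping: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> FstMatrix:
    """Pairwise theta between all groups, with permutation p-values.

    For each pair, individuals are permuted between the two groups
    ``n_permutations`` times; p = (#permuted theta >= observed + 1) /
    (n_permutations + 1). Pairs where a group has fewer than 2 scored
    individuals are reported NA.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(set(grouping.values()))
    fst = pd.DataFrame(0.0, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    members = {g: [a for a in table.accession_ids if grouping.get(a) == g]
               for g in groups}
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            ga, gb = groups[gi], groups[gj]
            if len(members[ga]) < 2 or len(members[gb]) < 2:
                fst.loc[ga, gb] = fst.loc[gb, ga] = np.nan
                continue
            ids = members[ga] + members[gb]
            labels = np.array([0] * len(members[ga]) + [1] * len(members[gb]))
            enc = _locus_encodings(table, ids)
            obs = _theta_from_encodings(enc, labels)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(labels)
                count += _theta_from_encodings(enc, perm) >= obs - 1e-12
            fst.loc[ga, gb] = fst.loc[gb, ga] = obs
            p = (count + 1) / (n_permutations + 1)
            pvals.loc[ga, gb] = pvals.loc[gb, ga] = p
    return FstMatrix(groups=groups, fst=fst, p_values=pvals)


# -- AMOVA -------------------------------------------------------------------

def _amova_components(encodings, labels: np.ndarray):
    """Summed variance components (among, within) over loci.

    Copy-level AMOVA on the 0/1 allele-mismatch distance. With d in {0,1}
    the sum of squared distances within a set of N copies with allele
    counts c_a is C(N,2) - sum_a C(c_a,2), divided by N.
    """

    def pairs(x):
        return x * (x - 1) / 2.0

    groups = np.unique(labels)
    onehot_all = labels[:, None] == groups[None, :]
    sig_a = 0.0
    sig_w = 0.0
    df_a = len(groups) - 1
    df_w_total = 0
    for dosage, het, scored in encodings:
        m = onehot_all[scored]
        d = dosage[scored]
        c_ga = m.T @ d                       # (G, A) copy counts per group
        n_g = c_ga.sum(axis=1)
        use = n_g > 0
        c_ga, n_g = c_ga[use], n_g[use]
        g_count = use.sum()
        if g_count < 2:
            continue
        c_a = c_ga.sum(axis=0)
        n_tot = c_a.sum()
        ssd_t = (pairs(n_tot) - pairs(c_a).sum()) / n_tot
        ssd_w = ((pairs(n_g) - pairs(c_ga).sum(axis=1)) / n_g).sum()
        ssd_a = ssd_t - ssd_w
        df_w = n_tot - g_count
        if df_w <= 0:
            continue
        sw = ssd_w / df_w
        n0 = (n_tot - np.sum(n_g**2) / n_tot) / (g_count - 1)
        sa = (ssd_a / (g_count - 1) - sw) / n0
        sig_a += sa
        sig_w += sw
        df_w_total += df_w
    return sig_a, sig_w, df_a, df_w_total


def amova(
    table: GenotypeTable,
    grouping: dict[str, str],
    partition: str = "groups",
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA (among vs within groups) with a permutation test.

    Negative among-group components are reported as computed; the
    percentage is clamped at 0 (standard AMOVA practice). A single-group
    partition yields among = 0 with an undefined (NaN) p-value.
    """
    rng = np.random.default_rng(seed)
    ids = [a for a in table.accession_ids if a in grouping]
    groups = sorted({grouping[a] for a in ids})
    labels = np.array([groups.index(grouping[a]) for a in ids])
    enc = _locus_encodings(table, ids)

    if len(groups) < 2:
        _, sig_w, _, df_w = _amova_components(enc, np.zeros(len(ids), dtype=int))
        return AmovaResult(partition, 0, df_w, 0.0, sig_w, 0.0, 100.0,
                           0.0, np.nan, 0)

    sig_a, sig_w, df_a, df_w = _amova_components(enc, labels)
    total = sig_a + sig_w
    pct_a = max(0.0, 100.0 * sig_a / total) if total > 0 else 0.0
    count = 0
    for _ in range(n_permutations):
        perm_a, _, _, _ = _amova_components(enc, rng.permutation(labels))
        count += perm_a >= sig_a - 1e-12
    p = (count + 1) / (n_permutations + 1) if n_permutations else np.nan
    return AmovaResult(
        partition=partition, df_among=df_a, df_within=df_w,
        sigma_among=sig_a, sigma_within=sig_w,
        pct_among=pct_a, pct_within=100.0 - pct_a,
        phi_st=sig_a / total if total > 0 else np.nan,
        p_value=p, n_permutations=n_permutations)
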