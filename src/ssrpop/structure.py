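"""Bayesian admixture clustering of multilocus SSR genotypes.

Implements the admixture model with correlated allele frequencies: each
individual i has ancestry proportions q_i over K clusters (Dirichlet(alpha)
prior, alpha shared and updated by Metropolis); each allele copy carries a
latent cluster-of-origin z; cluster allele frequencies P_k at every locus
follow an F-model prior, Dirichlet(p_anc * (1 - F_k) / F_k), centered on
inferred ancestral frequencies p_anc with one drift parameter F_k per
cluster. Gibbs updates are used for z, q and P; Metropolis updates for
alpha, F_k and p_anc.

Model choice across K uses Evanno's delta-K on the model evidence estimate
lnP(D) = mean(lnL) - var(lnL)/2 over post-burn-in samples; replicate runs
are aligned CLUMPP-style (optimal column permutation against the first
run) before averaging Q. Assignment thresholds follow germplasm practice:
max q >= 0.80 is a strong assignment, max q < 0.55 is unambiguous
admixture, anything between is plain admixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from ssrpop.io import GenotypeTable

logger = logging.getLogger(__name__)

STRONG_Q = 0.80            # strong-assignment membership threshold
UNAMBIGUOUS_ADMIXED_Q = 0.55  # below this at max q: unambiguously admixed

_P_FLOOR = 1e-9            # numerical floor for sampled frequencies
_F_PRIOR_SHAPE = 0.04      # Gamma prior on F_k: mean 0.01, sd 0.05
_F_PRIOR_SCALE = 0.25


@dataclass(frozen=True)
class StructureConfig:
    """MCMC settings.

    The *desk* profile (default) is sized for laptop-scale verification;
    the *full* profile matches production-scale germplasm practice (200k
    burn-in, 500k iterations, 10 runs). Tests never run the full profile.
    """

    K: int = 3
    burnin: int = 2_000
    iterations: int = 10_000
    n_runs: int = 3
    alpha_init: float = 1.0
    alpha_step: float = 0.025
    alpha_max: float = 10.0
    freq_model: str = "correlated"   # or "independent"
    lambda_: float = 1.0
    f_init: float = 0.05   # mid-range start; initializing at the prior mean
                           # (0.01) pins clusters to p_anc and slows escape
                           # from the symmetric no-structure mode
    f_step: float = 0.01
    anc_step: float = 0.02
    seed: int = 0

    @classmethod
    def desk(cls, K: int = 3, **kw) -> "StructureConfig":
        return cls(K=K, burnin=2_000, iterations=10_000, n_runs=3, **kw)

    @classmethod
    def full(cls, K: int = 3, **kw) -> "StructureConfig":
        return cls(K=K, burnin=200_000, iterations=500_000, n_runs=10, **kw)


@dataclass
class StructureRun:
    """Posterior summaries of one MCMC chain."""

    K: int
    ids: list[str]
    Q: pd.DataFrame                  # individuals x K posterior mean ancestry
    P: np.ndarray                    # (K, L, A_max) posterior mean frequencies
    lnl_trace: np.ndarray            # post-burn-in data log-likelihood samples
    lnpd: float                      # mean(lnL) - var(lnL)/2
    acceptance: dict
    config: StructureConfig


@dataclass
class QMatrix:
    """Aligned mean ancestry with per-individual assignment."""

    q: pd.DataFrame                  # individuals x K
    assignments: pd.DataFrame        # columns: group, max_q, status

    @property
    def ids(self) -> list[str]:
        return list(self.q.index)


@dataclass
class DeltaKResult:
    table: pd.DataFrame              # per K: mean/sd lnP(D), L', |L''|, delta_k
    selected_k: int


# ---------------------------------------------------------------------------

def _prepare(table: GenotypeTable):
    """Integer-code diploid calls: copy lists + per-locus allele maps."""
    mat = table.diploid_matrix()
    n, L, _ = mat.shape
    allele_maps = []
    a_max = 1
    coded = np.full((n, L, 2), -1, dtype=np.int64)
    for l in range(L):
        scored = mat[:, l, 0] >= 0
        alleles = np.unique(mat[scored, l, :])
        amap = {a: k for k, a in enumerate(alleles)}
        allele_maps.append(amap)
        a_max = max(a_max, len(alleles))
        for a, k in amap.items():
            coded[:, l, :][mat[:, l, :] == a] = k
    ind, loc, copy = np.nonzero(coded >= 0)
    allele = coded[ind, loc, copy]
    valid = np.zeros((L, a_max), dtype=bool)
    for l, amap in enumerate(allele_maps):
        valid[l, :len(amap)] = True
    return ind, loc, allele, allele_maps, valid, n, L, a_max


def run_admixture_mcmc(table: GenotypeTable, config: StructureConfig) -> StructureRun:
    """One MCMC chain; reproducible given ``config.seed``.

    Q and P are posterior means over post-burn-in sweeps. For K = 1 the
    ancestry simplex is a point and every q is exactly 1.
    """
    if config.K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(config.seed)
    ind, loc, allele, allele_maps, valid, n, L, a_max = _prepare(table)
    K = config.K
    C = ind.size
    col = loc * a_max + allele            # flat (locus, allele) index

    # pooled empirical frequencies initialize the ancestral vector
    pooled = np.zeros((L, a_max))
    np.add.at(pooled, (loc, allele), 1.0)
    pooled += valid * 0.5
    p_anc = pooled / pooled.sum(axis=1, keepdims=True)

    alpha = config.alpha_init
    f = np.full(K, config.f_init)
    z = _warm_start_z(ind, col, n, L * a_max, K, rng)
    q = np.full((n, K), 1.0 / K)
    # initialize q and P from the warm-start origins so the first z-update
    # already sees a structured state
    if K > 1:
        n_ik = np.zeros((n, K))
        np.add.at(n_ik, (ind, z), 1.0)
        g0 = rng.standard_gamma(alpha + n_ik)
        q = np.maximum(g0 / g0.sum(axis=1, keepdims=True), 1e-300)
    c0 = np.zeros((K, L * a_max))
    np.add.at(c0, (z, col), 1.0)
    prior0 = p_anc[None] * ((1.0 - f) / f)[:, None, None]
    g0 = rng.standard_gamma((prior0 + c0.reshape(K, L, a_max)) * valid[None])
    g0 = g0 * valid[None] + _P_FLOOR * valid[None]
    p = g0 / g0.sum(axis=2, keepdims=True)

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, a_max))
    lnl_trace = []
    acc = {"alpha": 0, "f": 0, "anc": 0}
    n_post = 0
    total = config.burnin + config.iterations
    correlated = config.freq_model == "correlated"

    for sweep in range(total):
        # -- z | q, P (Gibbs) and the free data log-likelihood -------------
        p_flat = p.reshape(K, L * a_max)
        probs = q[ind] * p_flat[:, col].T            # (C, K)
        rowsum = probs.sum(axis=1)
        lnl = float(np.log(rowsum).sum())
        if K > 1:
            u = rng.random(C) * rowsum
            z = np.minimum((probs.cumsum(axis=1) < u[:, None]).sum(axis=1), K - 1)

        # -- q | z (Gibbs, Dirichlet) --------------------------------------
        if K > 1:
            n_ik = np.zeros((n, K))
            np.add.at(n_ik, (ind, z), 1.0)
            g = rng.standard_gamma(alpha + n_ik)
            q = g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300)
            q = np.maximum(q, 1e-300)

        # -- P | z (Gibbs, Dirichlet with F-model or flat prior) -----------
        c_kla = np.zeros((K, L * a_max))
        np.add.at(c_kla, (z, col), 1.0)
        c_kla = c_kla.reshape(K, L, a_max)
        if correlated:
            prior = p_anc[None] * ((1.0 - f) / f)[:, None, None]
        else:
            prior = np.full((K, L, a_max), config.lambda_)
        g = rng.standard_gamma((prior + c_kla) * valid[None]) * valid[None]
        g += _P_FLOOR * valid[None]
        p = g / g.sum(axis=2, keepdims=True)

        if correlated:
            lnp = np.log(np.where(valid[None], p, 1.0))

            # -- F_k (Metropolis, Gamma prior) -----------------------------
            f_prop = f + rng.normal(0.0, config.f_step, size=K)
            ok = (f_prop > 1e-5) & (f_prop < 0.9)
            for k in np.nonzero(ok)[0]:
                delta = (_f_loglik(p_anc, lnp[k], valid, f_prop[k], L)
                         - _f_loglik(p_anc, lnp[k], valid, f[k], L)
                         + _f_logprior(f_prop[k]) - _f_logprior(f[k]))
                if np.log(rng.random()) < delta:
                    f[k] = f_prop[k]
                    acc["f"] += 1

            # -- p_anc (Metropolis, two-allele mass transfer) --------------
            acc["anc"] += _update_p_anc(p_anc, lnp, valid, f, config.anc_step, rng)

        # -- alpha (Metropolis, uniform prior) -----------------------------
        if K > 1:
            a_prop = alpha + rng.uniform(-config.alpha_step, config.alpha_step)
            if 0.0 < a_prop < config.alpha_max:
                lsq = float(np.log(q).sum())
                delta = (n * (gammaln(K * a_prop) - K * gammaln(a_prop))
                         - n * (gammaln(K * alpha) - K * gammaln(alpha))
                         + (a_prop - alpha) * lsq)
                if np.log(rng.random()) < delta:
                    alpha = a_prop
                    acc["alpha"] += 1

        if sweep >= config.burnin:
            q_sum += q
            p_sum += p
            lnl_trace.append(lnl)
            n_post += 1

    q_mean = q_sum / n_post
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    lnl_trace = np.asarray(lnl_trace)
    lnpd = float(lnl_trace.mean() - lnl_trace.var() / 2.0)
    rates = {k: v / total for k, v in acc.items()}
    rates["anc"] /= max(L, 1)
    rates["f"] /= K
    return StructureRun(
        K=K, ids=table.accession_ids,
        Q=pd.DataFrame(q_mean, index=table.accession_ids,
                       columns=[f"q{k + 1}" for k in range(K)]),
        P=p_sum / n_post, lnl_trace=lnl_trace, lnpd=lnpd,
        acceptance=rates, config=config)


def _warm_start_z(ind, col, n, n_cols, K, rng):
    """Initial allele-copy origins from k-means on the dosage matrix.

    Random z initialization starts every chain in the symmetric
    no-structure mode, which short chains escape slowly; clustering
    individuals first (k-means on the top principal components of the
    allele-dosage matrix, randomized per run) starts each chain near a
    structured mode. The stationary distribution is unaffected.
    """
    if K == 1:
        return np.zeros(ind.size, dtype=np.int64)
    dosage = np.zeros((n, n_cols))
    np.add.at(dosage, (ind, col), 1.0)
    dosage -= dosage.mean(axis=0)
    n_pc = min(10, max(2, K - 1), min(n, n_cols) - 1)
    try:
        _, s, vt = np.linalg.svd(dosage, full_matrices=False)
        pcs = dosage @ vt[:n_pc].T
        from scipy.cluster.vq import kmeans2

        _, labels = kmeans2(pcs, K, minit="++", seed=rng)
    except Exception:   # degenerate input: fall back to random labels
        labels = rng.integers(0, K, size=n)
    return labels[ind]


def _f_loglik(p_anc, lnp_k, valid, f_val, L):
    c = (1.0 - f_val) / f_val
    theta = p_anc * c
    t = np.where(valid, (theta - 1.0) * lnp_k - gammaln(np.where(valid, theta, 1.0)), 0.0)
    return float(L * gammaln(c) + t.sum())


def _f_logprior(f_val):
    return (_F_PRIOR_SHAPE - 1.0) * np.log(f_val) - f_val / _F_PRIOR_SCALE


def _update_p_anc(p_anc, lnp, valid, f, step, rng):
    """One symmetric mass-transfer proposal per locus; accepts in place."""
    L, a_max = p_anc.shape
    c = (1.0 - f) / f                       # (K,)
    accepted = 0
    n_valid = valid.sum(axis=1)
    for l in range(L):
        if n_valid[l] < 2:
            continue
        a_idx, b_idx = rng.choice(np.nonzero(valid[l])[0], size=2, replace=False)
        delta_m = rng.uniform(0.0, step)
        pa_new = p_anc[l, a_idx] - delta_m
        pb_new = p_anc[l, b_idx] + delta_m
        if pa_new <= 1e-6:
            continue
        ta_old, tb_old = p_anc[l, a_idx] * c, p_anc[l, b_idx] * c
        ta_new, tb_new = pa_new * c, pb_new * c
        delta = float(np.sum(
            (ta_new - ta_old) * lnp[:, l, a_idx]
            + (tb_new - tb_old) * lnp[:, l, b_idx]
            - gammaln(ta_new) + gammaln(ta_old)
            - gammaln(tb_new) + gammaln(tb_old)))
        if np.log(rng.random()) < delta:
            p_anc[l, a_idx] = pa_new
            p_anc[l, b_idx] = pb_new
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------

def run_replicates(table: GenotypeTable, config: StructureConfig) -> list[StructureRun]:
    """``config.n_runs`` chains with per-run seeds derived from the master seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    return [run_admixture_mcmc(table, replace(config, seed=int(s) % (2**31)))
            for s in seeds]


def sweep_k(table: GenotypeTable, config: StructureConfig,
            k_values) -> dict[int, list[StructureRun]]:
    """Replicate runs for each K; seeds derived from (master seed, K)."""
    out = {}
    for k in k_values:
        sub_seed = int(np.random.SeedSequence((config.seed, k)).generate_state(1)[0]
                       % (2**31))
        out[k] = run_replicates(table, replace(config, K=k, seed=sub_seed))
    return out


def align_runs(runs: list[StructureRun]) -> tuple[list[np.ndarray], QMatrix]:
    """Resolve label switching across replicate runs and average Q.

    Each run's cluster columns are permuted to best match the first run
    (minimum Frobenius distance between Q matrices). Because that cost
    decomposes over columns, the optimal permutation is found exactly by
    the Hungarian algorithm for any K.
    """
    if len({r.K for r in runs}) != 1:
        raise ValueError("all runs must share the same K")
    if len({tuple(r.ids) for r in runs}) != 1:
        raise ValueError("all runs must share the same individuals")
    ref = runs[0].Q.to_numpy()
    perms = []
    total = np.zeros_like(ref)
    for run in runs:
        qr = run.Q.to_numpy()
        # maximize sum_k <qr[:, perm[k]], ref[:, k]>
        cost = -(qr.T @ ref)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(run.K, dtype=int)
        perm[cols] = rows
        perms.append(perm)
        total += qr[:, perm]
    mean_q = total / len(runs)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    qdf = pd.DataFrame(mean_q, index=runs[0].ids, columns=runs[0].Q.columns)
    return perms, QMatrix(q=qdf, assignments=assign_groups(qdf))


def assign_groups(q: pd.DataFrame) -> pd.DataFrame:
    """Assignment and status per individual from mean ancestry.

    Group is the argmax cluster (1-based; ties break toward the lowest
    index and are logged). Status: ``strong`` (max q >= 0.80),
    ``unambiguous_admixed`` (max q < 0.55), else ``admixed``.
    """
    arr = q.to_numpy()
    group = arr.argmax(axis=1)
    ties = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("argmax ties at %d individuals broken toward lowest index",
                    int(ties.sum()))
    max_q = arr.max(axis=1)
    status = np.where(max_q >= STRONG_Q, "strong",
                      np.where(max_q < UNAMBIGUOUS_ADMIXED_Q,
                               "unambiguous_admixed", "admixed"))
    return pd.DataFrame({"group": group + 1, "max_q": max_q, "status": status},
                        index=q.index)


def delta_k(runs_by_k) -> DeltaKResult:
    """Evanno's delta-K over a sweep of K values.

    ``runs_by_k`` maps K -> list of runs (or of lnP(D) floats). delta-K is
    |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)), defined for
    interior K only; the selected K is its argmax.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("delta-K needs >= 3 consecutive K values")
    lnpd = {}
    for k in ks:
        vals = [r.lnpd if isinstance(r, StructureRun) else float(r)
                for r in runs_by_k[k]]
        if len(vals) < 2:
            raise ValueError("delta-K needs >= 2 runs per K")
        lnpd[k] = np.asarray(vals)
    mean = {k: lnpd[k].mean() for k in ks}
    sd = {k: lnpd[k].std(ddof=1) for k in ks}
    rows = []
    best_k, best = None, -np.inf
    for k in ks:
        d1 = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            if sd[k] == 0:
                raise ValueError(
                    f"sd of lnP(D) at K={k} is zero; add runs or jitter seeds")
            d2 = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = d2 / sd[k]
            if dk > best:
                best_k, best = k, dk
        else:
            d2, dk = np.nan, np.nan
        rows.append((k, mean[k], sd[k], d1, d2, dk))
    table = pd.DataFrame(rows, columns=["K", "mean_lnpd", "sd_lnpd",
                                        "L1", "abs_L2", "delta_k"])
    return DeltaKResult(table=table, selected_k=int(best_k))


def nested_structure(
    table: GenotypeTable,
    parent: QMatrix,
    config: StructureConfig,
    k_values=range(1, 6),
    min_group_size: int = 25,
) -> tuple[dict[int, DeltaKResult], dict[int, QMatrix], pd.Series]:
    """Second-level clustering inside each parent group.

    Every individual joins its argmax parent group (admixed ones
    included); each group is then re-analyzed independently with its own
    K sweep and delta-K choice. Returns per-group delta-K tables, per-group
    aligned Q matrices, and combined subgroup labels like ``K2.1``. Groups
    below ``min_group_size`` are skipped (their members keep the parent
    label, e.g. ``K2``).
    """
    labels = pd.Series(index=parent.q.index, dtype=object)
    dk_by_group: dict[int, DeltaKResult] = {}
    q_by_group: dict[int, QMatrix] = {}
    for g in sorted(parent.assignments["group"].unique()):
        members = parent.assignments.index[parent.assignments["group"] == g]
        if len(members) < min_group_size:
            logger.warning("group K%d has %d members (< %d): substructure "
                           "analysis skipped", g, len(members), min_group_size)
            labels.loc[members] = f"K{g}"
            continue
        sub = table.subset(list(members))
        runs_by_k = sweep_k(sub, replace(config, seed=config.seed + 1000 * int(g)),
                            k_values)
        dk = delta_k(runs_by_k)
        dk_by_group[int(g)] = dk
        _, qm = align_runs(runs_by_k[dk.selected_k])
        q_by_group[int(g)] = qm
        labels.loc[members] = [f"K{g}.{s}" for s in qm.assignments["group"]]
    return dk_by_group, q_by_group, labels
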