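"""Synthetic germplasm collections with known truth.

Emulates the statistical structure of a multi-collection SSR dataset of a
clonally propagated, self-incompatible fruit crop: a 16-locus panel with
many alleles per locus and expected heterozygosity around 0.8; a few
weakly differentiated genepools (Balding-Nichols drift around shared
ancestral frequencies, F around 0.02-0.05), optionally with nested
subgroups; admixed individuals; clonal duplicate groups of size 2-9 whose
members may differ by small scoring slips at up to two loci; ~8 %
putative-triploid profiles; and planted parent-pair/offspring trios.

Allele "sizes" live on a 2-bp ladder so a single-step mutation is well
defined. Every generator is a pure function of (config, seed) and emits a
truth object from which all planted features can be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrpop.io import Accession, Call, GenotypeTable, LocusDef


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the target collection structure."""

    n_loci: int = 16
    alleles_per_locus: tuple[int, int] = (8, 30)
    dirichlet_conc: float = 0.5      # ancestral-frequency skew: few common,
                                     # many rare alleles, He ~ 0.8
    n_groups: int = 3
    drift_f: float = 0.05            # Balding-Nichols drift per genepool
    nested_splits: dict = field(default_factory=dict)  # group -> (n_sub, sub_F)
    n_per_group: int = 50
    alpha_home: float = 8.0          # Dirichlet weight on the home genepool
    alpha_away: float = 0.4          # ... and on the others (admixture level)
    n_clone_groups: int = 0
    clone_size_range: tuple[int, int] = (2, 9)
    clone_mutated_loci: tuple[int, int] = (0, 2)
    triploid_fraction: float = 0.0   # set 0.08 for collection-like data
    n_trios: int = 0
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.01   # applied to trio offspring only
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated collection."""

    ancestral_freqs: list[dict[int, float]]          # per locus
    pop_freqs: dict[str, list[dict[int, float]]]     # per leaf population
    q: pd.DataFrame                                  # individuals x leaf pops
    group_labels: pd.Series                          # home top-level group
    leaf_labels: pd.Series                           # home leaf population
    clone_groups: dict[str, list[str]] = field(default_factory=dict)
    triploid_ids: list[str] = field(default_factory=list)
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)

    def write_truth_files(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.q.to_csv(out / "truth_q.csv")
        pd.DataFrame({"group": self.group_labels,
                      "leaf": self.leaf_labels}).to_csv(out / "truth_labels.csv")
        rows = [(g, m) for g, ms in self.clone_groups.items() for m in ms]
        pd.DataFrame(rows, columns=["group_id", "member"]).to_csv(
            out / "truth_clones.csv", index=False)
        pd.DataFrame(self.pedigree, columns=["offspring", "parent_a", "parent_b"]
                     ).to_csv(out / "truth_pedigree.csv", index=False)
        pd.DataFrame({"triploid": self.triploid_ids}).to_csv(
            out / "truth_ploidy.csv", index=False)
        recs = [(pop, l, a, p)
                for pop, per_locus in self.pop_freqs.items()
                for l, fr in enumerate(per_locus) for a, p in fr.items()]
        pd.DataFrame(recs, columns=["population", "locus", "allele", "freq"]
                     ).to_csv(out / "truth_freqs.csv", index=False)


def _ladder(n_alleles: int) -> np.ndarray:
    return 100 + 2 * np.arange(n_alleles)


def simulate_structured_population(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Draw a structured diploid collection (no clones/triploids/trios yet).

    Leaf populations are the nested subgroups where a split is requested
    and the top-level genepools elsewhere. Each individual's ancestry q is
    Dirichlet over leaf populations with weight ``alpha_home`` on its home
    leaf and ``alpha_away`` elsewhere; every allele copy picks an origin
    from q and then an allele from that population's frequencies.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_alleles = rng.integers(config.alleles_per_locus[0],
                             config.alleles_per_locus[1] + 1,
                             size=config.n_loci)
    anc = []
    for a in n_alleles:
        p = rng.dirichlet(np.full(a, config.dirichlet_conc))
        p = np.maximum(p, 1e-6)
        anc.append(p / p.sum())

    # leaf populations with Balding-Nichols drift (nested where requested)
    leaf_names: list[str] = []
    leaf_group: list[int] = []
    pop_freqs: dict[str, list[np.ndarray]] = {}
    for g in range(config.n_groups):
        c = (1.0 - config.drift_f) / config.drift_f
        group_p = [rng.dirichlet(np.maximum(p * c, 1e-4)) for p in anc]
        if g in config.nested_splits:
            n_sub, sub_f = config.nested_splits[g]
            cs = (1.0 - sub_f) / sub_f
            for s in range(n_sub):
                name = f"K{g + 1}.{s + 1}"
                pop_freqs[name] = [rng.dirichlet(np.maximum(p * cs, 1e-4))
                                   for p in group_p]
                leaf_names.append(name)
                leaf_group.append(g)
        else:
            name = f"K{g + 1}"
            pop_freqs[name] = group_p
            leaf_names.append(name)
            leaf_group.append(g)

    # individuals: home leaves round-robin within each group
    homes: list[int] = []
    for g in range(config.n_groups):
        leaves_g = [j for j, gg in enumerate(leaf_group) if gg == g]
        homes.extend(leaves_g[i % len(leaves_g)]
                     for i in range(config.n_per_group))
    n_ind = len(homes)
    n_leaf = len(leaf_names)

    alpha = np.full((n_ind, n_leaf), config.alpha_away)
    alpha[np.arange(n_ind), homes] = config.alpha_home
    gam = rng.standard_gamma(alpha)
    q = gam / gam.sum(axis=1, keepdims=True)

    ladders = [_ladder(a) for a in n_alleles]
    ids = [f"ACC{i + 1:04d}" for i in range(n_ind)]
    calls: list[list[Call]] = []
    for i in range(n_ind):
        row: list[Call] = []
        for l in range(config.n_loci):
            if config.missing_rate and rng.random() < config.missing_rate:
                row.append(())
                continue
            alleles = []
            for _ in range(2):
                k = rng.choice(n_leaf, p=q[i])
                a = rng.choice(n_alleles[l], p=pop_freqs[leaf_names[k]][l])
                alleles.append(int(ladders[l][a]))
            row.append(tuple(sorted(alleles)))
        calls.append(row)

    table = GenotypeTable(
        loci=[LocusDef(f"SSR{l + 1:02d}") for l in range(config.n_loci)],
        accessions=[Accession(i) for i in ids],
        calls=calls)
    truth = SyntheticTruth(
        ancestral_freqs=[{int(s): float(p) for s, p in zip(ladders[l], anc[l])}
                         for l in range(config.n_loci)],
        pop_freqs={name: [{int(s): float(p) for s, p in zip(ladders[l], fr[l])}
                          for l in range(config.n_loci)]
                   for name, fr in pop_freqs.items()},
        q=pd.DataFrame(q, index=ids, columns=leaf_names),
        group_labels=pd.Series([f"K{leaf_group[h] + 1}" for h in homes],
                               index=ids),
        leaf_labels=pd.Series([leaf_names[h] for h in homes], index=ids))
    return table, truth


def plant_clones_and_triploids(
    table: GenotypeTable,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Add clonal duplicate groups and convert a fraction to triploids.

    Each clone copies a distinct source accession and then perturbs 0-2
    loci by moving one allele copy a single ladder step, which keeps every
    planted group inside the duplicate-detection tolerance. Triploids get
    a third distinct allele at >= 3 loci; clone-group members are never
    converted, so planted groups stay recoverable.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    lo, hi = config.clone_mutated_loci
    if hi > 2:
        raise ValueError("clone mutation at more than 2 loci would break the "
                         "duplicate-recovery contract")
    accessions = list(table.accessions)
    calls = [list(r) for r in table.calls]
    base_ids = table.accession_ids
    sources = rng.choice(len(base_ids), size=config.n_clone_groups, replace=False)
    clone_members: set[str] = set()
    counter = 0
    for gi, src in enumerate(sources):
        size = int(rng.integers(config.clone_size_range[0],
                                config.clone_size_range[1] + 1))
        members = [base_ids[src]]
        for _ in range(size - 1):
            counter += 1
            new_id = f"CLO{counter:04d}"
            row = [tuple(c) for c in calls[src]]
            n_mut = int(rng.integers(lo, hi + 1))
            mutable = [l for l in range(len(row)) if len(row[l]) == 2]
            for l in rng.choice(mutable, size=min(n_mut, len(mutable)),
                                replace=False):
                a, b = row[l]
                which = rng.integers(2)
                step = 2 if rng.random() < 0.5 else -2
                new = (a + step, b) if which == 0 else (a, b + step)
                row[l] = tuple(sorted(new))
            accessions.append(Accession(new_id))
            calls.append(row)
            members.append(new_id)
        truth.clone_groups[f"TRUE{gi + 1:03d}"] = sorted(members)
        clone_members.update(members)

    # triploids: existing non-clone accessions gain a third allele
    eligible = [i for i, a in enumerate(accessions)
                if a.accession_id not in clone_members]
    n_tri = int(round(config.triploid_fraction * len(accessions)))
    pooled = _pooled_freqs(truth)
    for i in rng.choice(eligible, size=min(n_tri, len(eligible)), replace=False):
        row = calls[i]
        # a third distinct allele only shows at heterozygous loci
        het_loci = [l for l in range(len(row))
                    if len(row[l]) == 2 and row[l][0] != row[l][1]]
        if len(het_loci) < 3:
            continue
        k = int(np.clip(rng.binomial(len(het_loci), 0.45), 3, len(het_loci)))
        for l in rng.choice(het_loci, size=k, replace=False):
            sizes = np.array([s for s in pooled[l] if s not in row[l]])
            if sizes.size == 0:
                continue
            probs = np.array([pooled[l][s] for s in sizes])
            extra = int(rng.choice(sizes, p=probs / probs.sum()))
            row[l] = tuple(sorted(row[l] + (extra,)))
        truth.triploid_ids.append(accessions[i].accession_id)
    truth.triploid_ids.sort()
    return GenotypeTable(loci=list(table.loci), accessions=accessions,
                         calls=calls), truth


def _pooled_freqs(truth: SyntheticTruth) -> list[dict[int, float]]:
    pooled: list[dict[int, float]] = []
    pops = list(truth.pop_freqs)
    for l in range(len(truth.ancestral_freqs)):
        d: dict[int, float] = {}
        for pop in pops:
            for a, p in truth.pop_freqs[pop][l].items():
                d[a] = d.get(a, 0.0) + p / len(pops)
        pooled.append(d)
    return pooled


def plant_trios(
    table: GenotypeTable,
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Add offspring of random parent pairs (Mendelian + genotyping error).

    Parents are drawn from diploid, non-clone, non-triploid accessions;
    at each locus the offspring receives one random allele copy from each
    parent, then each copy is independently replaced by a pooled-frequency
    draw with probability ``genotyping_error_rate``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    clone_members = {m for ms in truth.clone_groups.values() for m in ms[1:]}
    bad = clone_members | set(truth.triploid_ids)
    parents_pool = [i for i, a in enumerate(table.accessions)
                    if a.accession_id not in bad]
    accessions = list(table.accessions)
    calls = [list(r) for r in table.calls]
    pooled = _pooled_freqs(truth)
    for t in range(config.n_trios):
        pa, pb = rng.choice(parents_pool, size=2, replace=False)
        row: list[Call] = []
        for l in range(table.n_loci):
            ca, cb = calls[pa][l], calls[pb][l]
            if len(ca) != 2 or len(cb) != 2:
                row.append(())
                continue
            alleles = []
            for parent_call in (ca, cb):
                a = parent_call[rng.integers(2)]
                if rng.random() < config.genotyping_error_rate:
                    sizes = np.array(list(pooled[l].keys()))
                    probs = np.array(list(pooled[l].values()))
                    a = int(rng.choice(sizes, p=probs / probs.sum()))
                alleles.append(a)
            row.append(tuple(sorted(alleles)))
        off_id = f"OFF{t + 1:04d}"
        accessions.append(Accession(off_id))
        calls.append(row)
        truth.pedigree.append((off_id,
                               *sorted((accessions[pa].accession_id,
                                        accessions[pb].accession_id))))
    return GenotypeTable(loci=list(table.loci), accessions=accessions,
                         calls=calls), truth


def simulate_collection(
    config: SimConfig,
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Full pipeline: structured population + clones/triploids + trios."""
    rng = np.random.default_rng(config.seed)
    table, truth = simulate_structured_population(config, rng)
    table, truth = plant_clones_and_triploids(table, truth, config, rng)
    table, truth = plant_trios(table, truth, config, rng)
    return table, truth
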