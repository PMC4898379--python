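"""Admixture MCMC, run alignment, delta-K and assignment thresholds."""

import numpy as np
import pandas as pd
import pytest

from ssrpop.simulate import SimConfig, simulate_structured_population
from ssrpop.structure import (
    QMatrix,
    StructureConfig,
    align_runs,
    assign_groups,
    delta_k,
    nested_structure,
    run_admixture_mcmc,
)
from tests.conftest import make_table


def disjoint_two_pop_table(rng, n_per=15, n_loci=10):
    """Two populations fixed for non-overlapping allele sets."""
    calls, ids = [], []
    for g, pool in enumerate([(100, 102), (110, 112)]):
        for i in range(n_per):
            ids.append(f"P{g}_{i:02d}")
            calls.append([tuple(sorted(rng.choice(pool, 2)))
                          for _ in range(n_loci)])
    return make_table(calls, ids=ids)


SHORT = dict(burnin=300, iterations=1500)


class TestMcmc:
    def test_k1_gives_exact_unit_ancestry(self, collection):
        _, table, _ = collection
        run = run_admixture_mcmc(table.subset(table.accession_ids[:20]),
                                 StructureConfig(K=1, **SHORT, seed=0))
        assert np.all(run.Q.to_numpy() == 1.0)

    def test_rows_sum_to_one(self, rng):
        run = run_admixture_mcmc(disjoint_two_pop_table(rng),
                                 StructureConfig(K=3, **SHORT, seed=1))
        np.testing.assert_allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_disjoint_populations(self, rng):
        table = disjoint_two_pop_table(rng)
        run = run_admixture_mcmc(table, StructureConfig(K=2, **SHORT, seed=2))
        q = run.Q.to_numpy()
        assert q.max(axis=1).min() >= 0.99
        labels = q.argmax(axis=1)
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_same_seed_is_bit_identical(self, rng):
        table = disjoint_two_pop_table(rng)
        cfg = StructureConfig(K=2, **SHORT, seed=7)
        r1 = run_admixture_mcmc(table, cfg)
        r2 = run_admixture_mcmc(table, cfg)
        assert np.array_equal(r1.Q.to_numpy(), r2.Q.to_numpy())
        assert np.array_equal(r1.lnl_trace, r2.lnl_trace)

    def test_metropolis_acceptance_rates_reasonable(self, rng):
        # at the canonical 150-individual scale the default step sizes keep
        # every Metropolis move inside the healthy-mixing band
        cfg = SimConfig(n_per_group=50, drift_f=0.05, seed=3)
        table, _ = simulate_structured_population(cfg)
        run = run_admixture_mcmc(table, StructureConfig(K=3, **SHORT, seed=4))
        for name in ("alpha", "f", "anc"):
            assert 0.1 < run.acceptance[name] < 0.9, name

    def test_likelihood_prefers_true_configuration(self, rng):
        """lnL at the true (q, P) of a noiseless two-population setup beats
        shuffled labels."""
        table = disjoint_two_pop_table(rng)
        run = run_admixture_mcmc(table, StructureConfig(K=2, **SHORT, seed=5))
        # posterior mean ln L must be far above the K=1 (pooled) model
        run1 = run_admixture_mcmc(table, StructureConfig(K=1, **SHORT, seed=5))
        assert run.lnl_trace.mean() > run1.lnl_trace.mean() + 50

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            run_admixture_mcmc(disjoint_two_pop_table(rng),
                               StructureConfig(K=0, **SHORT))


class TestAlignRuns:
    def _fake_run(self, q, K=3):
        ids = [f"I{i}" for i in range(q.shape[0])]
        from ssrpop.structure import StructureRun

        return StructureRun(K=K, ids=ids,
                            Q=pd.DataFrame(q, index=ids,
                                           columns=[f"q{k+1}" for k in range(K)]),
                            P=np.zeros((K, 1, 1)), lnl_trace=np.zeros(2),
                            lnpd=0.0, acceptance={}, config=StructureConfig(K=K))

    def test_column_swap_is_undone(self, rng):
        q = rng.dirichlet(np.ones(3), size=30)
        r1 = self._fake_run(q)
        r2 = self._fake_run(q[:, [2, 0, 1]])
        perms, qm = align_runs([r1, r2])
        np.testing.assert_allclose(qm.q.to_numpy(), q, atol=1e-12)

    def test_self_alignment_is_identity(self, rng):
        q = rng.dirichlet(np.ones(4), size=10)
        r = self._fake_run(q, K=4)
        perms, _ = align_runs([r, r])
        assert all(np.array_equal(p, np.arange(4)) for p in perms)

    def test_noisy_replicates_average_close_to_truth(self, rng):
        q = rng.dirichlet(np.ones(3), size=50)
        runs = []
        for i in range(3):
            noisy = np.clip(q + rng.normal(0, 0.01, q.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            # later runs arrive with shuffled cluster labels
            perm = np.arange(3) if i == 0 else rng.permutation(3)
            runs.append(self._fake_run(noisy[:, perm]))
        _, qm = align_runs(runs)
        assert np.abs(qm.q.to_numpy() - q).max() < 0.02

    def test_mismatched_k_is_an_error(self, rng):
        r1 = self._fake_run(rng.dirichlet(np.ones(3), size=5))
        r2 = self._fake_run(rng.dirichlet(np.ones(2), size=5), K=2)
        with pytest.raises(ValueError):
            align_runs([r1, r2])


class TestDeltaK:
    @staticmethod
    def _runs(mean, sd):
        x = sd / np.sqrt(2.0)
        return [mean + x, mean - x]    # two runs with exact mean and sd

    def test_hand_computed_example(self):
        runs_by_k = {1: self._runs(-1000, 5), 2: self._runs(-900, 10),
                     3: self._runs(-880, 5), 4: self._runs(-878, 5)}
        res = delta_k(runs_by_k)
        tab = res.table.set_index("K")
        assert tab.loc[2, "abs_L2"] == pytest.approx(80.0)
        assert tab.loc[2, "delta_k"] == pytest.approx(8.0)
        assert res.selected_k == 2

    def test_linear_means_give_zero_everywhere(self):
        runs_by_k = {k: self._runs(-1000 + 100 * k, 3) for k in range(1, 5)}
        tab = delta_k(runs_by_k).table.set_index("K")
        assert np.allclose(tab.loc[[2, 3], "delta_k"], 0.0, atol=1e-9)

    def test_zero_sd_is_an_error(self):
        runs_by_k = {1: [-1000, -1000], 2: [-900, -900], 3: [-880, -880]}
        with pytest.raises(ValueError, match="sd"):
            delta_k(runs_by_k)

    def test_needs_three_consecutive_k(self):
        with pytest.raises(ValueError):
            delta_k({1: self._runs(-10, 1), 3: self._runs(-8, 1)})


class TestAssignment:
    @pytest.mark.parametrize("q, group, status", [
        ((0.85, 0.10, 0.05), 1, "strong"),
        ((0.60, 0.25, 0.15), 1, "admixed"),
        ((0.45, 0.42, 0.13), 1, "unambiguous_admixed"),
        ((0.80, 0.15, 0.05), 1, "strong"),            # boundary: >= 0.80
        ((0.10, 0.35, 0.55), 3, "admixed"),           # boundary: not < 0.55
    ])
    def test_thresholds(self, q, group, status):
        res = assign_groups(pd.DataFrame([q], index=["x"],
                                         columns=["q1", "q2", "q3"]))
        assert res.loc["x", "group"] == group
        assert res.loc["x", "status"] == status

    def test_ties_break_toward_lowest_index(self):
        res = assign_groups(pd.DataFrame([[0.4, 0.4, 0.2]], index=["x"],
                                         columns=["q1", "q2", "q3"]))
        assert res.loc["x", "group"] == 1


class TestNested:
    def test_subgroup_labels_partition_each_parent_group(self):
        cfg = SimConfig(n_per_group=25, n_groups=3, drift_f=0.12,
                        nested_splits={0: (2, 0.12)}, seed=8,
                        alpha_home=30.0, alpha_away=0.2)
        table, truth = simulate_structured_population(cfg)
        q_true = truth.q.copy()
        # collapse leaf ancestry to the 3 top-level groups
        top = pd.DataFrame({
            "q1": q_true[[c for c in q_true if c.startswith("K1")]].sum(axis=1),
            "q2": q_true["K2"], "q3": q_true["K3"]})
        parent = QMatrix(q=top, assignments=assign_groups(top))
        scfg = StructureConfig(burnin=300, iterations=1200, n_runs=2, seed=9)
        dks, qs, labels = nested_structure(table, parent, scfg,
                                           k_values=range(1, 4),
                                           min_group_size=20)
        assert set(labels.index) == set(table.accession_ids)
        for acc, g in parent.assignments["group"].items():
            assert labels.loc[acc].startswith(f"K{g}")
        # the deliberately split group shows supported substructure
        assert dks[1].selected_k == 2

    def test_small_groups_are_skipped(self, collection):
        _, table, _ = collection
        sub = table.subset(table.accession_ids[:30])
        q = pd.DataFrame({"q1": [1.0] * 25 + [0.0] * 5,
                          "q2": [0.0] * 25 + [1.0] * 5},
                         index=sub.accession_ids)
        parent = QMatrix(q=q, assignments=assign_groups(q))
        scfg = StructureConfig(burnin=100, iterations=400, n_runs=2, seed=1)
        dks, qs, labels = nested_structure(sub, parent, scfg,
                                           k_values=range(1, 4),
                                           min_group_size=20)
        assert 2 not in dks                 # skipped: below the floor
        assert (labels[q["q2"] == 1.0] == "K2").all()
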