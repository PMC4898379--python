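"""End-to-end orchestration of the germplasm analysis workflow.

Stage order mirrors curation practice: harmonize allele sizes (optional)
-> duplicate resolution -> triploid and excess-missing filtering ->
diversity statistics -> admixture clustering with delta-K -> nested
substructure -> AMOVA / pairwise F_ST -> PCoA / NJ tree -> trio parentage.
Downstream stages always consume the unique diploid genotype set produced
by the filtering stages. Every run writes its artifacts plus a text
summary with the seeds and filter counts used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ssrpop import diversity, differentiation, ordination, parentage, redundancy
from ssrpop import structure as structure_mod
from ssrpop.io import GenotypeTable, read_genotype_table
from ssrpop.structure import StructureConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_path: str | None = None
    input_format: str = "wide_csv"
    outdir: str = "ssrpop_out"
    seed: int = 0
    # stage toggles
    run_dedup: bool = True
    run_diversity: bool = True
    run_structure: bool = True
    run_nested: bool = True
    run_differentiation: bool = True
    run_ordination: bool = True
    run_parentage: bool = True
    # parameters
    max_mismatch_loci: int = 2
    min_shared_loci: int = 12
    max_missing_loci: int = 4
    rare_threshold: float = 0.05
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    structure: StructureConfig = field(default_factory=StructureConfig.desk)
    nested_min_group: int = 25
    n_permutations: int = 999
    parentage_error_rate: float = 0.01
    parentage_simulations: int = 2_000


def run_full_analysis(
    config: PipelineConfig,
    table: GenotypeTable | None = None,
) -> dict:
    """Run the configured stages; returns the consolidated report dict.

    Artifacts are written under ``config.outdir``. Any stage failure
    raises :class:`StageError` naming the stage; artifacts of completed
    stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed,
                    "config": {k: str(v) for k, v in
                               dataclasses.asdict(config).items()}}

    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or an input_path is required")
        table = read_genotype_table(config.input_path, config.input_format)
    report["n_accessions"] = table.n_accessions
    report["n_loci"] = table.n_loci
    working = table
    assignment = None

    if config.run_dedup:
        working = _stage_dedup(config, working, out, report)
    working = _stage_filter(config, working, out, report)

    if config.run_diversity:
        _run_stage("diversity", _stage_diversity, config, working, out, report)
    if config.run_structure:
        assignment = _run_stage("structure", _stage_structure, config, working,
                                out, report)
        if config.run_nested and assignment is not None:
            _run_stage("nested_structure", _stage_nested, config, working, out,
                       report, assignment)
    elif config.run_nested:
        logger.info("nested structure skipped: structure stage disabled")
    if config.run_differentiation and assignment is not None:
        _run_stage("differentiation", _stage_differentiation, config, working,
                   out, report, assignment)
    if config.run_ordination:
        _run_stage("ordination", _stage_ordination, config, working, out, report)
    if config.run_parentage:
        _run_stage("parentage", _stage_parentage, config, working, out, report)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _run_stage(name, fn, config, working, out, report, *extra):
    logger.info("running stage %s", name)
    try:
        return fn(config, working, out, report, *extra)
    except Exception as exc:                      # noqa: BLE001 - stage-named
        raise StageError(name, exc) from exc


def _stage_dedup(config, table, out, report):
    try:
        groups, reduced = redundancy.find_duplicate_groups(
            table, max_mismatch_loci=config.max_mismatch_loci,
            min_shared_loci=config.min_shared_loci)
    except Exception as exc:                      # noqa: BLE001
        raise StageError("dedup", exc) from exc
    pd.DataFrame(
        [(g.group_id, m, g.representative) for g in groups for m in g.members],
        columns=["group_id", "member", "representative"],
    ).to_csv(out / "duplicate_groups.csv", index=False)
    flags = redundancy.flag_triploids(table)
    pd.DataFrame([dataclasses.asdict(f) for f in flags]).to_csv(
        out / "ploidy_flags.csv", index=False)
    report["n_duplicate_groups"] = len(groups)
    report["n_redundant_removed"] = table.n_accessions - reduced.n_accessions
    logger.info("dedup: %d groups, removed %d redundant accessions",
                len(groups), report["n_redundant_removed"])
    return reduced


def _stage_filter(config, table, out, report):
    """Drop putative triploids, then accessions with too much missing data."""
    triploid = {f.accession_id for f in redundancy.flag_triploids(table)
                if f.is_putative_triploid}
    keep = [a for a in table.accession_ids if a not in triploid]
    table = table.subset(keep)
    n_missing_drop = [a for a in table.accession_ids
                      if table.missing_count(a) > config.max_missing_loci]
    table = table.subset([a for a in table.accession_ids
                          if a not in set(n_missing_drop)])
    report["n_triploids_removed"] = len(triploid)
    report["n_missing_removed"] = len(n_missing_drop)
    report["n_unique_diploid"] = table.n_accessions
    logger.info("filter: removed %d triploids, %d excess-missing; %d unique "
                "diploid genotypes remain", len(triploid), len(n_missing_drop),
                table.n_accessions)
    table.write_csv(out / "unique_diploid.csv")
    return table


def _stage_diversity(config, table, out, report):
    stats = diversity.diversity_stats(table, rare_threshold=config.rare_threshold)
    stats.to_csv(out / "diversity_per_locus.csv", index=False)
    freqs = diversity.allele_frequencies(table)["all"]
    per_locus_pid, cumulative = diversity.probability_of_identity(freqs)
    per_locus_pid.to_csv(out / "pid_per_locus.csv")
    mean_row = stats[stats["locus"] == "mean"].iloc[0]
    report["mean_He"] = float(mean_row["He"])
    report["mean_Na"] = float(mean_row["N_A"])
    report["cumulative_pid"] = float(cumulative)


def _stage_structure(config, table, out, report):
    runs_by_k = structure_mod.sweep_k(table, config.structure, config.k_values)
    dk = structure_mod.delta_k(runs_by_k)
    dk.table.to_csv(out / "delta_k.csv", index=False)
    _, qmatrix = structure_mod.align_runs(runs_by_k[dk.selected_k])
    qmatrix.q.to_csv(out / "ancestry_q.csv")
    qmatrix.assignments.to_csv(out / "assignments.csv")
    report["selected_K"] = dk.selected_k
    report["fraction_strong"] = float(
        (qmatrix.assignments["status"] == "strong").mean())
    report["mean_max_q"] = float(qmatrix.assignments["max_q"].mean())
    return qmatrix


def _stage_nested(config, table, out, report, qmatrix):
    sub_cfg = dataclasses.replace(config.structure)
    dk_by_group, q_by_group, labels = structure_mod.nested_structure(
        table, qmatrix, sub_cfg,
        k_values=range(1, max(4, min(config.k_values[-1], 5)) + 1),
        min_group_size=config.nested_min_group)
    labels.to_frame("subgroup").to_csv(out / "subgroup_labels.csv")
    for g, dk in dk_by_group.items():
        dk.table.to_csv(out / f"delta_k_group{g}.csv", index=False)
    report["nested_subgroups"] = {int(g): int(dk.selected_k)
                                  for g, dk in dk_by_group.items()}


def _stage_differentiation(config, table, out, report, qmatrix):
    grouping = {acc: f"K{g}" for acc, g in
                qmatrix.assignments["group"].items()}
    res = differentiation.amova(table, grouping, partition="structure_groups",
                                n_permutations=config.n_permutations,
                                seed=config.seed)
    pd.DataFrame([dataclasses.asdict(res)]).to_csv(out / "amova.csv", index=False)
    fst = differentiation.pairwise_fst(table, grouping,
                                       n_permutations=config.n_permutations,
                                       seed=config.seed)
    fst.fst.to_csv(out / "pairwise_fst.csv")
    fst.p_values.to_csv(out / "pairwise_fst_pvalues.csv")
    report["amova_pct_among"] = res.pct_among
    report["amova_p"] = res.p_value
    report["overall_fst"] = float(
        differentiation.weir_cockerham_theta(table, grouping))


def _stage_ordination(config, table, out, report):
    dm = ordination.simple_matching_dissimilarity(table)
    pcoa_res = ordination.pcoa(dm)
    pcoa_res.coordinates.to_csv(out / "pcoa_coordinates.csv")
    tree = ordination.neighbor_joining(dm)
    (out / "nj_tree.nwk").write_text(tree.newick + "\n")
    if len(pcoa_res.proportion_explained):
        report["pcoa_axis1_pct"] = float(100 * pcoa_res.proportion_explained[0])


def _stage_parentage(config, table, out, report):
    trios, calibration = parentage.infer_trios(
        table, error_rate=config.parentage_error_rate,
        n_simulations=config.parentage_simulations, seed=config.seed)
    pd.DataFrame([dataclasses.asdict(t) for t in trios]).to_csv(
        out / "trios.csv", index=False)
    report["n_trios_accepted"] = len(trios)
    report["parentage_delta_threshold"] = calibration.delta_threshold
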