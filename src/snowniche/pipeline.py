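"""End-to-end orchestration: filter -> fold changes -> responders ->
cluster -> label -> group abundance / contributions -> NRI/NTI ->
guild composition, run independently per stratum (location x depth).

Outputs are TSVs named after their content plus a JSON run report with
stage-by-stage counts; re-running with the same config and seed
reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import __version__
from .containers import AbundanceTable, Strategy, Transition
from .diffabund import (
    add_pvalues,
    adjust_fdr,
    auto_pseudo,
    fold_change_table,
    prevalence_filter,
    select_responders,
    timepoint_summaries,
)
from .guilds import guild_composition
from .phylo import ses_relatedness
from .strategies import assign_strategies, contribution_ranking, group_abundance

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "recovery_report"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str | Path
    alpha: float = 0.05
    prevalence: float = 0.25
    pseudo: float | None = None  # None -> half the smallest nonzero proportion
    k: int = 3  # clusters per stratum (3 for archaea/bacteria, 4 for fungi)
    n_perm: int = 1000
    seed: int = 0
    pool: str = "all"  # regional pool for NRI/NTI: 'all' or 'responders'
    top_n: int = 10
    rank: str = "genus"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if self.pool not in ("all", "responders"):
            raise ValueError("pool must be 'all' or 'responders'")


@dataclass
class PipelineResult:
    fold_changes: pd.DataFrame
    assignments: pd.DataFrame  # otu_id, location, depth, cluster_id, strategy
    group_abundances: pd.DataFrame
    contributions: pd.DataFrame
    relatedness: pd.DataFrame
    guild_compositions: pd.DataFrame
    report: dict


def run_pipeline(
    config: RunConfig,
    table: AbundanceTable,
    tree: skbio.TreeNode | None = None,
    taxonomy: pd.DataFrame | None = None,
    guilds: pd.Series | None = None,
) -> PipelineResult:
    """Run the full inference chain and write all outputs.

    ``tree`` enables the NRI/NTI stage and ``guilds`` the guild
    composition stage; both are optional (their outputs are then empty).
    Any stage failure aborts with the stratum named; warnings (constant
    profiles, degenerate nulls, unannotated OTUs) are recorded in the
    run report and never abort.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "snowniche",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "prevalence": config.prevalence,
        "k": config.k,
        "n_perm": config.n_perm,
        "pool": config.pool,
        "n_otus_input": int(table.data.shape[0]),
        "n_samples": int(table.data.shape[1]),
        "strata": [],
        "warnings": [],
    }

    filtered = prevalence_filter(table, config.prevalence)
    report["n_otus_filtered"] = int(filtered.data.shape[0])
    pseudo = config.pseudo if config.pseudo is not None else auto_pseudo(filtered)
    report["pseudo"] = pseudo

    tree_tips = {t.name for t in tree.tips()} if tree is not None else set()
    rng = np.random.default_rng(config.seed)

    fc_frames: list[pd.DataFrame] = []
    assign_frames: list[pd.DataFrame] = []
    ga_frames: list[pd.DataFrame] = []
    contrib_frames: list[pd.DataFrame] = []
    relate_rows: list[dict] = []
    guild_frames: list[pd.DataFrame] = []

    for location, depth in filtered.strata():
        stage = f"stratum ({location}, {depth})"
        try:
            stratum = filtered.subset_samples(
                filtered.stratum_samples(location, depth)
            )
            summaries = timepoint_summaries(stratum)
            records = adjust_fdr(
                add_pvalues(fold_change_table(summaries, pseudo)), config.alpha
            )
            fc_frames.append(records)
            responders = select_responders(records, config.alpha)
            stratum_report = {
                "location": location,
                "depth": depth,
                "n_responders": len(responders),
                "strategy_sizes": {},
            }

            if len(responders) >= config.k:
                assignment = assign_strategies(summaries, responders, config.k)
            else:
                assignment = pd.DataFrame(
                    {
                        "cluster_id": pd.Series(dtype=int),
                        "strategy": pd.Series(dtype=object),
                    }
                )
                if responders:
                    report["warnings"].append(
                        f"{stage}: {len(responders)} responder(s) is fewer "
                        f"than k={config.k}; clustering skipped"
                    )
            located = assignment.copy()
            located["location"] = location
            located["depth"] = depth
            assign_frames.append(located)
            sizes = assignment["strategy"].value_counts().to_dict() if len(assignment) else {}
            stratum_report["strategy_sizes"] = {k: int(v) for k, v in sizes.items()}
            report["strata"].append(stratum_report)
            if not len(assignment):
                continue

            ga_frames.append(group_abundance(stratum, assignment))
            for strategy in sorted(set(assignment["strategy"])):
                if strategy == Strategy.UNASSIGNED.value:
                    continue
                for transition in Transition:
                    try:
                        contrib_frames.append(
                            contribution_ranking(
                                stratum,
                                assignment,
                                taxonomy,
                                strategy,
                                transition.value,
                                location,
                                depth,
                                top_n=config.top_n,
                                rank=config.rank,
                                pseudo=pseudo,
                            )
                        )
                    except ValueError:
                        report["warnings"].append(
                            f"{stage}: zero group change for "
                            f"({strategy}, {transition.value})"
                        )
            if guilds is not None and len(guilds):
                gc = guild_composition(assignment, guilds)
                gc.insert(0, "depth", depth)
                gc.insert(0, "location", location)
                guild_frames.append(gc)
            relate_rows.extend(
                _relatedness_rows(
                    stratum, assignment, tree, tree_tips, config, rng,
                    location, depth, report, responders,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc

    fold_changes = (
        pd.concat(fc_frames, ignore_index=True) if fc_frames else pd.DataFrame()
    )
    assignments = (
        pd.concat(
            [
                a.reset_index(names="otu_id")
                for a in assign_frames
                if len(a)
            ],
            ignore_index=True,
        )
        if any(len(a) for a in assign_frames)
        else pd.DataFrame(
            columns=["otu_id", "cluster_id", "strategy", "location", "depth"]
        )
    )
    group_abundances = (
        pd.concat(ga_frames, ignore_index=True) if ga_frames else pd.DataFrame()
    )
    contributions = (
        pd.concat(contrib_frames, ignore_index=True)
        if contrib_frames
        else pd.DataFrame()
    )
    relatedness = pd.DataFrame(relate_rows)
    guild_compositions = (
        pd.concat(guild_frames, ignore_index=True) if guild_frames else pd.DataFrame()
    )

    _write_tsv(fold_changes, outdir / "foldchanges.tsv")
    cols = ["otu_id", "location", "depth", "cluster_id", "strategy"]
    _write_tsv(
        assignments[cols] if len(assignments) else assignments,
        outdir / "strategies.tsv",
    )
    _write_tsv(group_abundances, outdir / "group_abundance.tsv")
    _write_tsv(contributions, outdir / "contributions.tsv")
    _write_tsv(relatedness, outdir / "relatedness.tsv")
    _write_tsv(guild_compositions, outdir / "guild_composition.tsv")
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        fold_changes=fold_changes,
        assignments=assignments,
        group_abundances=group_abundances,
        contributions=contributions,
        relatedness=relatedness,
        guild_compositions=guild_compositions,
        report=report,
    )


def _relatedness_rows(
    stratum: AbundanceTable,
    assignment: pd.DataFrame,
    tree,
    tree_tips: set,
    config: RunConfig,
    rng: np.random.Generator,
    location: str,
    depth: str,
    report: dict,
    responders: set,
) -> list[dict]:
    """NRI/NTI rows for every strategy group of one stratum."""
    if tree is None:
        return []
    present = stratum.data.index[(stratum.data.to_numpy() > 0).any(axis=1)]
    if config.pool == "all":
        pool = [t for t in present if t in tree_tips]
    else:
        pool = sorted(t for t in responders if t in tree_tips)
    rows = []
    for strategy in sorted(set(assignment["strategy"])):
        if strategy == Strategy.UNASSIGNED.value:
            continue
        group_all = assignment.index[assignment["strategy"] == strategy]
        members = [o for o in group_all if o in tree_tips and o in set(pool)]
        if len(members) < len(group_all):
            report["warnings"].append(
                f"({location}, {depth}, {strategy}): "
                f"{len(group_all) - len(members)} OTU(s) missing from "
                "tree/pool, skipped in NRI/NTI"
            )
        if len(members) < 2 or len(pool) <= len(members):
            report["warnings"].append(
                f"({location}, {depth}, {strategy}): group or pool too "
                "small for relatedness"
            )
            continue
        res = ses_relatedness(members, pool, tree, n_perm=config.n_perm, seed=rng)
        if res.degenerate:
            report["warnings"].append(
                f"({location}, {depth}, {strategy}): degenerate null"
            )
        rows.append(
            {
                "location": location,
                "depth": depth,
                "strategy": strategy,
                "n_otus": res.n_group,
                "mpd_obs": res.mpd_obs,
                "mntd_obs": res.mntd_obs,
                "null_mean_mpd": res.null_mean_mpd,
                "null_sd_mpd": res.null_sd_mpd,
                "null_mean_mntd": res.null_mean_mntd,
                "null_sd_mntd": res.null_sd_mntd,
                "nri": res.nri,
                "nti": res.nti,
                "p_mpd": res.p_mpd,
                "p_mntd": res.p_mntd,
                "n_perm": res.n_perm,
                "degenerate": res.degenerate,
            }
        )
    return rows


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def recovery_report(result: PipelineResult, truth) -> dict:
    """Compare pipeline output against planted truth.

    Returns responder sensitivity (fraction of planted non-background
    OTU x stratum combinations recovered as responders), the
    false-discovery proportion among responders, and strategy-label
    accuracy among recovered true responders.
    """
    planted = truth.labels
    assignments = result.assignments
    if len(assignments):
        unknown = set(assignments["otu_id"]) - set(planted.index)
        if unknown:
            raise ValueError(
                f"assignments contain unknown OTUs: {sorted(unknown)[:5]}"
            )
    signal = {
        Strategy.WINTER_ADAPTED.value,
        Strategy.SNOWMELT_SPECIALIST.value,
        Strategy.SPRING_ADAPTED.value,
        Strategy.FALL.value,
    }
    n_strata = max(
        1, len({(s["location"], s["depth"]) for s in result.report["strata"]})
    )
    planted_signal = set(planted.index[planted.isin(signal)])

    n_recovered = n_false = n_correct = n_true_assigned = total_assigned = 0
    for _, row in assignments.iterrows():
        total_assigned += 1
        otu = row["otu_id"]
        if otu in planted_signal:
            n_recovered += 1
            n_true_assigned += 1
            if row["strategy"] == planted[otu]:
                n_correct += 1
        else:
            n_false += 1
    sensitivity = (
        n_recovered / (len(planted_signal) * n_strata)
        if planted_signal
        else float("nan")
    )
    fdp = n_false / total_assigned if total_assigned else 0.0
    accuracy = n_correct / n_true_assigned if n_true_assigned else float("nan")
    confusion = (
        assignments.assign(planted=assignments["otu_id"].map(planted))
        .groupby(["planted", "strategy"])
        .size()
        .unstack(fill_value=0)
        .to_dict()
        if len(assignments)
        else {}
    )
    return {
        "responder_sensitivity": sensitivity,
        "responder_fdp": fdp,
        "strategy_accuracy": accuracy,
        "n_planted_signal": len(planted_signal),
        "n_assigned": total_assigned,
        "confusion": confusion,
    }
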