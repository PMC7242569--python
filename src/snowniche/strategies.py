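"""Life-strategy classification of responder OTUs by temporal profile.

Responder OTUs within a stratum are clustered on the shape of their
seasonal abundance trajectory: the four timepoint means are z-scored
per OTU (so magnitude drops out and shape remains), pairwise Euclidean
distances are agglomerated with average linkage (UPGMA), and the
dendrogram is cut at a single height into ``k`` clusters.  Each cluster
is labelled by the timepoint at which its centroid peaks:

    SEP -> fall, MAR -> winter-adapted, MAY -> snowmelt-specialist,
    JUN -> spring-adapted.

Three clusters are used for archaea/bacteria; fungi show an additional
fall-peaking group and use four.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import (
    AbundanceTable,
    PEAK_TO_STRATEGY,
    TIMEPOINT_ORDER,
    TRANSITION_ENDPOINTS,
    Strategy,
    Transition,
)
from .diffabund import TimepointSummary, Z95, fold_change

logger = logging.getLogger(__name__)

__all__ = [
    "build_profiles",
    "cluster_profiles",
    "label_strategies",
    "assign_strategies",
    "group_abundance",
    "contribution_ranking",
]

_TIMEPOINTS = [t.value for t in TIMEPOINT_ORDER]


def build_profiles(summaries: pd.DataFrame, responders: set[str]) -> pd.DataFrame:
    """Z-scored 4-point temporal profile of each responder in one stratum.

    ``summaries`` must come from a single stratum and cover all four
    timepoints for every responder.  Returns a frame indexed by otu_id
    with columns SEP, MAR, MAY, JUN and a boolean ``constant`` flag;
    constant (zero-variance) profiles are all-zero vectors.
    """
    strata = summaries[["location", "depth"]].drop_duplicates()
    if len(strata) != 1:
        raise ValueError("build_profiles expects summaries from a single stratum")
    sub = summaries[summaries["otu_id"].isin(responders)]
    wide = sub.pivot_table(
        index="otu_id", columns="timepoint", values="mean", aggfunc="first"
    )
    missing_tp = [t for t in _TIMEPOINTS if t not in wide.columns]
    missing_otu = set(responders) - set(wide.index)
    if missing_tp or missing_otu or wide[_TIMEPOINTS].isna().any().any():
        raise ValueError(
            f"incomplete summaries: timepoints {missing_tp}, "
            f"OTUs {sorted(missing_otu)[:5]}"
        )
    wide = wide[_TIMEPOINTS].sort_index()
    vals = wide.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd: z-scores get sd 1
    constant = (sd[:, 0] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=wide.index, columns=_TIMEPOINTS)
    out["constant"] = constant
    if constant.any():
        logger.warning("%d constant profile(s) flagged", int(constant.sum()))
    return out


def cluster_profiles(profiles: pd.DataFrame, k: int) -> pd.Series:
    """UPGMA-cluster non-constant profiles into exactly ``k`` groups.

    Pairwise Euclidean distance, average linkage, single horizontal cut
    at the smallest height yielding ``k`` clusters.  Deterministic under
    input-order permutation: rows are processed in lexicographic otu_id
    order.  Constant profiles receive cluster id -1.  Returns a Series
    otu_id -> cluster id (1..k).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    active = profiles.index[~profiles["constant"]].sort_values()
    if k > len(active):
        raise ValueError(f"k={k} exceeds {len(active)} non-constant profiles")
    x = profiles.loc[active, _TIMEPOINTS].to_numpy(float)
    labels = np.full(len(profiles), -1, dtype=int)
    order = pd.Series(np.arange(len(profiles)), index=profiles.index)
    if len(active) == 1 or k == len(active):
        ids = np.arange(1, len(active) + 1) if k == len(active) else np.ones(1, int)
        labels[order[active].to_numpy()] = ids
    else:
        z = linkage(pdist(x, metric="euclidean"), method="average")
        ids = fcluster(z, t=k, criterion="maxclust")
        labels[order[active].to_numpy()] = ids
    return pd.Series(labels, index=profiles.index, name="cluster_id")


def label_strategies(clusters: pd.Series, profiles: pd.DataFrame) -> pd.DataFrame:
    """Label each cluster by the argmax timepoint of its centroid profile.

    Ties break toward the later timepoint.  Constant profiles (cluster
    id -1) are UNASSIGNED.  Returns a frame indexed by otu_id with
    columns ``cluster_id`` and ``strategy``; several clusters may share
    a strategy label.
    """
    out = pd.DataFrame({"cluster_id": clusters})
    out["strategy"] = Strategy.UNASSIGNED.value
    for cid in sorted(set(clusters) - {-1}):
        members = clusters.index[clusters == cid]
        centroid = profiles.loc[members, _TIMEPOINTS].mean(axis=0).to_numpy()
        # argmax with ties broken toward the later timepoint
        peak = len(centroid) - 1 - int(np.argmax(centroid[::-1]))
        strategy = PEAK_TO_STRATEGY[TIMEPOINT_ORDER[peak]]
        out.loc[members, "strategy"] = strategy.value
    return out


def assign_strategies(
    summaries: pd.DataFrame, responders: set[str], k: int = 3
) -> pd.DataFrame:
    """Profile -> cluster -> label for one stratum, in one call."""
    profiles = build_profiles(summaries, responders)
    clusters = cluster_profiles(profiles, k)
    return label_strategies(clusters, profiles)


def group_abundance(table: AbundanceTable, assignment: pd.DataFrame) -> pd.DataFrame:
    """Summed member abundance per (strategy, location, depth, timepoint).

    Per sample the member proportions are summed, then averaged over
    replicate samples within each stratum x timepoint.  Returns a tidy
    frame with a ``group_abundance`` column; empty groups yield 0.
    """
    meta = table.metadata
    rows = []
    strategies = sorted(set(assignment["strategy"]))
    for strategy in strategies:
        members = assignment.index[assignment["strategy"] == strategy]
        members = members.intersection(table.data.index)
        summed = (
            table.data.loc[members].sum(axis=0)
            if len(members)
            else pd.Series(0.0, index=table.data.columns)
        )
        for (location, depth) in table.strata():
            in_stratum = (meta["location"] == location) & (meta["depth"] == depth)
            for tp in TIMEPOINT_ORDER:
                cols = meta.index[in_stratum & (meta["timepoint"] == tp.value)]
                if len(cols) == 0:
                    continue
                rows.append(
                    {
                        "strategy": strategy,
                        "location": location,
                        "depth": depth,
                        "timepoint": tp.value,
                        "group_abundance": float(summed[cols].mean()),
                    }
                )
    return pd.DataFrame(rows)


def _lowest_rank(taxonomy: pd.DataFrame, otu_id: str) -> str:
    """Genus if assigned, else the lowest assigned rank, else the OTU id."""
    if taxonomy is None or otu_id not in taxonomy.index:
        return otu_id
    lineage = taxonomy.loc[otu_id]
    for rank in reversed(lineage.index):
        name = str(lineage[rank])
        if name and name != "unassigned":
            return name
    return otu_id


def contribution_ranking(
    table: AbundanceTable,
    assignment: pd.DataFrame,
    taxonomy: pd.DataFrame | None,
    strategy: str,
    transition: str,
    location: str,
    depth: str,
    top_n: int = 10,
    rank: str = "genus",
    pseudo: float = 1e-12,
) -> pd.DataFrame:
    """Rank a strategy group's taxa by contribution to its abundance change.

    Member OTUs are aggregated to genus (lowest assigned rank; OTUs
    without taxonomy keep their id) unless ``rank='otu'``.  For the
    requested transition, each taxon's change in stratum-mean abundance
    is expressed as a percent of the group's total change; taxon-level
    log2 fold changes are recomputed from the aggregated abundances.
    Contributions over all members sum to 100%; negative contributions
    (members opposing the group direction) are allowed and sort last.
    """
    t1, t2 = TRANSITION_ENDPOINTS[Transition(transition)]
    members = assignment.index[assignment["strategy"] == strategy]
    members = members.intersection(table.data.index)
    if len(members) == 0:
        raise ValueError(f"no members for strategy {strategy}")
    meta = table.metadata
    in_stratum = (meta["location"] == location) & (meta["depth"] == depth)
    cols1 = meta.index[in_stratum & (meta["timepoint"] == t1.value)]
    cols2 = meta.index[in_stratum & (meta["timepoint"] == t2.value)]

    sub = table.data.loc[members]
    if rank == "otu":
        taxa = pd.Series(list(members), index=members)
    elif rank == "genus":
        taxa = pd.Series({o: _lowest_rank(taxonomy, o) for o in members})
    else:
        raise ValueError(f"rank must be 'genus' or 'otu', got {rank!r}")
    agg = sub.groupby(taxa).sum()  # per-sample taxon abundance

    mean1 = agg[cols1].mean(axis=1)
    mean2 = agg[cols2].mean(axis=1)
    delta = mean2 - mean1
    delta_group = float(delta.sum())
    if delta_group == 0:
        raise ValueError(
            f"group change is zero for ({strategy}, {transition}); "
            "percent contributions undefined"
        )
    records = []
    for taxon in agg.index:
        n1, n2 = len(cols1), len(cols2)
        ci1 = Z95 * agg.loc[taxon, cols1].std(ddof=1) / np.sqrt(n1) if n1 > 1 else 0.0
        ci2 = Z95 * agg.loc[taxon, cols2].std(ddof=1) / np.sqrt(n2) if n2 > 1 else 0.0
        s1 = TimepointSummary(taxon, location, depth, t1.value, float(mean1[taxon]), float(ci1), n1)
        s2 = TimepointSummary(taxon, location, depth, t2.value, float(mean2[taxon]), float(ci2), n2)
        _, _, log2fc = fold_change(s1, s2, pseudo)
        records.append(
            {
                "taxon": taxon,
                "strategy": strategy,
                "transition": transition,
                "location": location,
                "depth": depth,
                "log2fc": log2fc,
                "pct_contribution": 100.0 * float(delta[taxon]) / delta_group,
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["pct_contribution", "taxon"], ascending=[False, True], kind="stable"
    )
    return out.head(top_n).reset_index(drop=True)
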