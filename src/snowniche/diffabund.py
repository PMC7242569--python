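"""Differential abundance across seasonal transitions.

For each OTU and each of the three consecutive transitions (winter:
SEP->MAR, snowmelt: MAR->MAY, spring: MAY->JUN) within a stratum
(location x depth), the fold change of mean relative abundance is
computed together with a 95% confidence interval obtained by error
propagation for a ratio:

    CI_fc = |FC| * sqrt( (CI_t1 / mean_t1)^2 + (CI_t2 / mean_t2)^2 )

where mean_t and CI_t are the mean relative abundance and its 95% CI
half-width over replicate samples at each date.  A two-sided p-value is
back-derived from the CI on the log scale (delta method: the standard
error of ln FC is the relative CI half-width divided by 1.96), and
p-values are adjusted jointly per stratum by Benjamini-Hochberg FDR.
OTUs with at least one significant transition are "responders" and feed
the life-strategy classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .containers import (
    AbundanceTable,
    TIMEPOINT_ORDER,
    TRANSITION_ENDPOINTS,
    Transition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimepointSummary",
    "prevalence_filter",
    "timepoint_summaries",
    "auto_pseudo",
    "fold_change",
    "fold_change_table",
    "p_from_ci",
    "add_pvalues",
    "bh_adjust",
    "adjust_fdr",
    "select_responders",
]

Z95 = 1.96  # CI half-width multiplier; fixed normal quantile, not a t-quantile


@dataclass(frozen=True)
class TimepointSummary:
    """Replicate-level summary of one OTU at one date within a stratum."""

    otu_id: str
    location: str
    depth: str
    timepoint: str
    mean: float
    ci95: float  # 95% CI half-width: 1.96 * sd / sqrt(n); 0 when n == 1
    n: int


def prevalence_filter(table: AbundanceTable, threshold: float = 0.25) -> AbundanceTable:
    """Retain OTUs detected in at least ``threshold`` of all samples.

    An OTU passes if it is nonzero in >= ceil(threshold * n_samples)
    samples.  Column proportions are NOT renormalized afterwards: they
    remain relative to the full community.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n_samples = table.data.shape[1]
    needed = math.ceil(threshold * n_samples)
    present = (table.data.to_numpy() > 0).sum(axis=1)
    keep = table.data.index[present >= needed]
    if len(keep) == 0:
        logger.warning("prevalence filter removed every OTU (threshold=%g)", threshold)
    return AbundanceTable(table.data.loc[keep], table.metadata.copy())


def timepoint_summaries(table: AbundanceTable) -> pd.DataFrame:
    """Mean and 95% CI of each OTU per (location, depth, timepoint).

    Returns a tidy frame with columns otu_id, location, depth,
    timepoint, mean, ci95, n.  Every stratum must be sampled at all four
    dates; a missing stratum x timepoint cell is an error.
    """
    meta = table.metadata
    frames = []
    for location, depth in table.strata():
        in_stratum = (meta["location"] == location) & (meta["depth"] == depth)
        observed = set(meta.loc[in_stratum, "timepoint"])
        missing = [t.value for t in TIMEPOINT_ORDER if t.value not in observed]
        if missing:
            raise ValueError(
                f"stratum ({location}, {depth}) missing timepoint(s): {missing}"
            )
        for tp in TIMEPOINT_ORDER:
            cols = meta.index[in_stratum & (meta["timepoint"] == tp.value)]
            sub = table.data[cols].to_numpy()
            n = sub.shape[1]
            mean = sub.mean(axis=1)
            if n > 1:
                sd = sub.std(axis=1, ddof=1)
                ci95 = Z95 * sd / math.sqrt(n)
            else:
                ci95 = np.zeros_like(mean)
            frames.append(
                pd.DataFrame(
                    {
                        "otu_id": table.data.index,
                        "location": location,
                        "depth": depth,
                        "timepoint": tp.value,
                        "mean": mean,
                        "ci95": ci95,
                        "n": n,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def auto_pseudo(table: AbundanceTable) -> float:
    """Default pseudo-abundance: half the smallest nonzero proportion."""
    vals = table.data.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("abundance table is all zeros")
    return float(nonzero.min() / 2.0)


def fold_change(
    s1: TimepointSummary, s2: TimepointSummary, pseudo: float
) -> tuple[float, float, float]:
    """Fold change t1 -> t2 with its error-propagated 95% CI half-width.

    A pseudo-abundance is added to both means so that zero means do not
    divide by zero.  Returns ``(fold_change, ci_fc, log2fc)``.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo must be positive, got {pseudo}")
    if (s1.otu_id, s1.location, s1.depth) != (s2.otu_id, s2.location, s2.depth):
        raise ValueError("summaries must share OTU and stratum")
    m1 = s1.mean + pseudo
    m2 = s2.mean + pseudo
    fc = m2 / m1
    rel = math.sqrt((s1.ci95 / m1) ** 2 + (s2.ci95 / m2) ** 2)
    return fc, abs(fc) * rel, math.log2(fc)


def p_from_ci(fc: float, ci_fc: float) -> float:
    """Two-sided p-value recovered from the fold-change CI.

    The relative CI half-width r = ci_fc / FC equals 1.96 times the
    delta-method standard error of ln FC, so z = |ln FC| / (r / 1.96).
    Degenerate cases: zero-width CI gives p = 1 when FC = 1 and p = 0
    otherwise.
    """
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    if ci_fc < 0:
        raise ValueError(f"ci_fc must be non-negative, got {ci_fc}")
    lnfc = math.log(fc)
    r = ci_fc / fc
    if r == 0:
        return 1.0 if lnfc == 0 else 0.0
    z = abs(lnfc) / (r / Z95)
    return float(2.0 * norm.sf(z))


def fold_change_table(summaries: pd.DataFrame, pseudo: float) -> pd.DataFrame:
    """Per-OTU fold-change records for all three transitions (vectorized).

    Returns columns: otu_id, location, depth, transition, mean_t1,
    ci_t1, mean_t2, ci_t2, fold_change, ci_fc, log2fc.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo must be positive, got {pseudo}")
    wide = summaries.pivot_table(
        index=["otu_id", "location", "depth"],
        columns="timepoint",
        values=["mean", "ci95"],
        aggfunc="first",
        observed=True,
    )
    records = []
    for transition in Transition:
        t1, t2 = TRANSITION_ENDPOINTS[transition]
        m1 = wide[("mean", t1.value)].to_numpy() + pseudo
        m2 = wide[("mean", t2.value)].to_numpy() + pseudo
        c1 = wide[("ci95", t1.value)].to_numpy()
        c2 = wide[("ci95", t2.value)].to_numpy()
        fc = m2 / m1
        rel = np.sqrt((c1 / m1) ** 2 + (c2 / m2) ** 2)
        idx = wide.index.to_frame(index=False)
        idx["transition"] = transition.value
        idx["mean_t1"] = m1 - pseudo
        idx["ci_t1"] = c1
        idx["mean_t2"] = m2 - pseudo
        idx["ci_t2"] = c2
        idx["fold_change"] = fc
        idx["ci_fc"] = np.abs(fc) * rel
        idx["log2fc"] = np.log2(fc)
        records.append(idx)
    return pd.concat(records, ignore_index=True)


def add_pvalues(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the CI-derived two-sided p-value to each fold-change record."""
    fc = records["fold_change"].to_numpy(float)
    ci = records["ci_fc"].to_numpy(float)
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    lnfc = np.log(fc)
    r = ci / fc
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(lnfc) / (r / Z95)
    p = 2.0 * norm.sf(z)
    p = np.where(r == 0, np.where(lnfc == 0, 1.0, 0.0), p)
    out = records.copy()
    out["p"] = p
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-stable)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values jointly over all OTU x transition tests per stratum."""
    out = records.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(["location", "depth"], sort=False).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def select_responders(records: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """OTUs with at least one FDR-significant transition (q < alpha)."""
    if len(records) == 0:
        return set()
    if "q" not in records.columns or records["q"].isna().any():
        raise ValueError("records must carry BH-adjusted q-values")
    hits = records.loc[records["q"] < alpha, "otu_id"]
    return set(hits)
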