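"""Phylogenetic relatedness of life-strategy groups: NRI and NTI.

For a group of OTUs (tree tips) drawn from a regional species pool, two
metrics on patristic distances are computed: MPD (mean pairwise
distance) and MNTD (mean nearest-taxon distance), both unweighted.
Each is standardized against a null distribution obtained by drawing
random same-size tip sets from the pool ("random taxa shuffling", the
taxa-labels null for presence-only metrics):

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

Positive values indicate phylogenetic clustering (the group is more
related than random draws from the pool), negative values indicate
overdispersion.  Significance is a two-sided rank-based permutation
p-value.  An exhaustive-enumeration oracle over all subsets is provided
for small pools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import skbio
from skbio import DistanceMatrix

__all__ = [
    "RelatednessResult",
    "patristic_distances",
    "mpd",
    "mntd",
    "ses_relatedness",
    "exhaustive_null",
]


@dataclass(frozen=True)
class RelatednessResult:
    """Observed and null relatedness of one strategy group."""

    n_group: int
    mpd_obs: float
    mntd_obs: float
    null_mean_mpd: float
    null_sd_mpd: float
    null_mean_mntd: float
    null_sd_mntd: float
    nri: float
    nti: float
    p_mpd: float
    p_mntd: float
    n_perm: int
    degenerate: bool


def patristic_distances(tree: skbio.TreeNode, tips=None) -> DistanceMatrix:
    """Patristic (sum of branch lengths) distances between tree tips."""
    if tips is not None:
        tips = list(tips)
        have = {t.name for t in tree.tips()}
        unknown = [t for t in tips if t not in have]
        if unknown:
            raise ValueError(f"tip(s) not in tree: {unknown}")
        if len(tips) == 1:
            return DistanceMatrix([[0.0]], ids=tips)
    return tree.tip_tip_distances(endpoints=tips)


def _submatrix(group, dm: DistanceMatrix) -> np.ndarray:
    idx = [dm.index(t) for t in group]
    return dm.data[np.ix_(idx, idx)]


def _mpd_from_matrix(d: np.ndarray) -> float:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def _mntd_from_matrix(d: np.ndarray) -> float:
    dd = d + np.diag(np.full(d.shape[0], np.inf))
    return float(dd.min(axis=1).mean())


def mpd(group, dm: DistanceMatrix) -> float:
    """Mean pairwise patristic distance over all unordered tip pairs."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("MPD requires a group of at least 2 tips")
    return _mpd_from_matrix(_submatrix(group, dm))


def mntd(group, dm: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest other member."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("MNTD requires a group of at least 2 tips")
    return _mntd_from_matrix(_submatrix(group, dm))


def _null_draws(
    pool_d: np.ndarray, group_size: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """MPD and MNTD of ``n_perm`` uniform random subsets of the pool."""
    n_pool = pool_d.shape[0]
    null_mpd = np.empty(n_perm)
    null_mntd = np.empty(n_perm)
    iu = np.triu_indices(group_size, k=1)
    inf_diag = np.diag(np.full(group_size, np.inf))
    for i in range(n_perm):
        idx = rng.choice(n_pool, size=group_size, replace=False)
        d = pool_d[np.ix_(idx, idx)]
        null_mpd[i] = d[iu].mean()
        null_mntd[i] = (d + inf_diag).min(axis=1).mean()
    return null_mpd, null_mntd


def _perm_p(null: np.ndarray, obs: float) -> float:
    """Two-sided rank-based permutation p, bounded below by 1/(n+1)."""
    n = len(null)
    r_lo = 1 + int((null <= obs).sum())
    r_hi = 1 + int((null >= obs).sum())
    return min(1.0, 2.0 * min(r_lo, r_hi) / (n + 1))


def ses_relatedness(
    group,
    pool,
    tree: skbio.TreeNode,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RelatednessResult:
    """Standardized effect sizes of MPD/MNTD against the taxa-shuffle null.

    ``group`` must be a subset of ``pool`` (tip names).  The null
    distribution is the metric over ``n_perm`` uniform random subsets of
    the pool of the group's size; its sd uses the n-1 denominator.  When
    the null sd is zero (e.g. pool == group, or a star phylogeny) the
    result is flagged degenerate and the index set to 0.
    """
    group = sorted(set(group))
    pool = sorted(set(pool))
    if len(group) < 2:
        raise ValueError("group must have at least 2 tips")
    if not set(group) <= set(pool):
        raise ValueError("group must be a subset of the pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dm = patristic_distances(tree, tips=pool)
    pool_d = dm.data
    gidx = [dm.index(t) for t in group]
    obs_d = pool_d[np.ix_(gidx, gidx)]
    mpd_obs = _mpd_from_matrix(obs_d)
    mntd_obs = _mntd_from_matrix(obs_d)

    null_mpd, null_mntd = _null_draws(pool_d, len(group), n_perm, rng)
    mean_mpd, sd_mpd = float(null_mpd.mean()), float(null_mpd.std(ddof=1))
    mean_mntd, sd_mntd = float(null_mntd.mean()), float(null_mntd.std(ddof=1))

    # a null sd at float-noise level means every draw was identical
    tol_mpd = 1e-10 * max(1.0, abs(mean_mpd))
    tol_mntd = 1e-10 * max(1.0, abs(mean_mntd))
    flat_mpd = sd_mpd <= tol_mpd or len(pool) == len(group)
    flat_mntd = sd_mntd <= tol_mntd or len(pool) == len(group)
    degenerate = flat_mpd or flat_mntd
    nri = 0.0 if flat_mpd else -(mpd_obs - mean_mpd) / sd_mpd
    nti = 0.0 if flat_mntd else -(mntd_obs - mean_mntd) / sd_mntd
    return RelatednessResult(
        n_group=len(group),
        mpd_obs=mpd_obs,
        mntd_obs=mntd_obs,
        null_mean_mpd=mean_mpd,
        null_sd_mpd=sd_mpd,
        null_mean_mntd=mean_mntd,
        null_sd_mntd=sd_mntd,
        nri=nri,
        nti=nti,
        p_mpd=_perm_p(null_mpd, mpd_obs),
        p_mntd=_perm_p(null_mntd, mntd_obs),
        n_perm=n_perm,
        degenerate=degenerate,
    )


def exhaustive_null(
    group_size: int, pool, tree: skbio.TreeNode, metric: str = "mpd"
) -> tuple[float, float, np.ndarray]:
    """Exact null moments by enumerating every subset of the pool.

    Testing oracle for :func:`ses_relatedness`; refuses pools with more
    than 1e5 subsets.  Returns ``(mean, sd, distribution)`` with the
    n-1 sd denominator (sd = 0 for a single subset).
    """
    pool = sorted(set(pool))
    n_subsets = math.comb(len(pool), group_size)
    if n_subsets > 10**5:
        raise ValueError(f"too many subsets to enumerate: {n_subsets}")
    dm = patristic_distances(tree, tips=pool)
    fn = {"mpd": _mpd_from_matrix, "mntd": _mntd_from_matrix}[metric]
    values = np.array(
        [
            fn(dm.data[np.ix_(idx, idx)])
            for idx in itertools.combinations(range(len(pool)), group_size)
        ]
    )
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd, values
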