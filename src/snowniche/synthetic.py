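"""Synthetic seasonal microbiome data with planted ground truth.

Emulates the study design end-to-end: four sampling dates (SEP, MAR,
MAY, JUN), two locations x three depth classes, replicate samples per
stratum x date, OTU abundance profiles peaked at the timepoint of a
planted life strategy, compositional sampling noise, a simulated
phylogeny with tunable phylogenetic conservatism of strategy labels,
and FUNGuild-style guild labels for a fungal fraction.  Every stage of
the analysis pipeline can thereby be verified against known truth.

The abundance model: a baseline community is drawn from a symmetric
Dirichlet (concentration 0.5, giving realistic rank-abundance skew);
an OTU planted with a strategy has its expected abundance multiplied by
``2**effect_log2`` at that strategy's peak timepoint (winter-adapted ->
MAR, snowmelt-specialist -> MAY, spring-adapted -> JUN, fall -> SEP);
replicates multiply the expectation by i.i.d. lognormal noise with a
given coefficient of variation and are renormalized per sample, so the
data are compositional like real relative abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .containers import (
    AbundanceTable,
    Depth,
    Location,
    PEAK_TO_STRATEGY,
    TIMEPOINT_ORDER,
    Strategy,
    TrophicMode,
)
from .phylo import patristic_distances

__all__ = [
    "SimulationSpec",
    "PlantedTruth",
    "SyntheticDataset",
    "simulate_tree",
    "plant_labels",
    "simulate_abundances",
    "simulate_taxonomy",
    "plant_guilds",
    "generate",
    "write_dataset",
]

DEFAULT_STRATA: tuple[tuple[str, str], ...] = tuple(
    (loc.value, dep.value) for loc in Location for dep in Depth
)

STRATEGY_PEAK: dict[str, str] = {
    strategy.value: tp.value for tp, strategy in PEAK_TO_STRATEGY.items()
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the field design: six strata (2 locations x 3
    depths) sampled at four dates with 6 replicates each, a quarter of
    OTUs planted in each of the three snowmelt-related strategies, a
    peak-vs-baseline log2 ratio of 2 (4-fold bloom) and 20% replicate
    noise.  ``conservatism`` controls how strategy labels sit on the
    phylogeny: +1 clade-inherited, 0 random, -1 maximally overdispersed.
    """

    seed: int
    n_otus: int = 200
    n_reps: int = 6
    strata: tuple[tuple[str, str], ...] = DEFAULT_STRATA
    strategy_fractions: dict[str, float] = field(
        default_factory=lambda: {
            Strategy.WINTER_ADAPTED.value: 0.25,
            Strategy.SNOWMELT_SPECIALIST.value: 0.25,
            Strategy.SPRING_ADAPTED.value: 0.25,
            Strategy.FALL.value: 0.0,
            Strategy.BACKGROUND.value: 0.25,
        }
    )
    effect_log2: float = 2.0
    noise_cv: float = 0.2
    conservatism: float = 0.0
    fungal_fraction: float = 0.3
    dirichlet_concentration: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.strategy_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"strategy fractions must sum to 1, got {total}")
        if self.n_otus < 1 or self.n_reps < 1:
            raise ValueError("n_otus and n_reps must be positive")
        if not -1.0 <= self.conservatism <= 1.0:
            raise ValueError("conservatism must lie in [-1, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: planted labels and the phylogeny."""

    labels: pd.Series  # otu_id -> planted strategy
    tree: skbio.TreeNode
    expected_profiles: pd.DataFrame | None = None  # otu x timepoint, pre-normalization


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    truth: PlantedTruth
    table: AbundanceTable
    taxonomy: pd.DataFrame
    guilds: pd.Series


def _otu_name(i: int) -> str:
    return f"OTU{i + 1:05d}"


def simulate_tree(n_tips: int, seed: int | np.random.Generator) -> skbio.TreeNode:
    """Yule (pure-birth, unit rate) tree with exponential waiting times.

    Fully bifurcating with ``n_tips`` uniquely named tips and strictly
    positive branch lengths; deterministic for a given seed.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = skbio.TreeNode()
    t = 0.0
    birth: dict[int, float] = {}
    active: list[skbio.TreeNode] = []
    for _ in range(2):
        child = skbio.TreeNode()
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = skbio.TreeNode()
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth.pop(id(node))
    root.length = None
    for i, tip in enumerate(root.tips()):
        tip.name = _otu_name(i)
    return root


def _strategy_sizes(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer group sizes matching fractions (largest-remainder rounding)."""
    keys = [k for k in fractions if k != Strategy.BACKGROUND.value]
    sizes = {k: int(math.floor(fractions[k] * n)) for k in keys}
    remainders = sorted(
        keys, key=lambda k: (fractions[k] * n) - sizes[k], reverse=True
    )
    target_nonbg = round(n * (1.0 - fractions.get(Strategy.BACKGROUND.value, 0.0)))
    shortfall = target_nonbg - sum(sizes.values())
    for k in remainders[: max(0, shortfall)]:
        sizes[k] += 1
    return {k: v for k, v in sizes.items() if v > 0}


def _clade_pick(tree, unassigned: set[str], size: int, d: pd.DataFrame) -> list[str]:
    """Tips of the subtree whose unassigned-tip count best matches ``size``.

    Prefers the smallest clade with at least ``size`` unassigned tips;
    if no clade is large enough, starts from the largest available clade
    and pads with the nearest unassigned tips by patristic distance.
    """
    best_over, best_under = None, None
    for node in tree.traverse(include_self=True):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        avail = [t for t in tips if t in unassigned]
        if len(avail) >= size:
            if best_over is None or len(avail) < len(best_over):
                best_over = avail
        elif avail:
            if best_under is None or len(avail) > len(best_under):
                best_under = avail
    if best_over is not None:
        if len(best_over) == size:
            return best_over
        # trim from a seed tip outward so the picked tips stay contiguous
        seed_tip = best_over[0]
        ranked = sorted(best_over, key=lambda t: (d.loc[seed_tip, t], t))
        return ranked[:size]
    chosen = list(best_under or [])
    rest = sorted(unassigned - set(chosen))
    while len(chosen) < size and rest:
        nearest = min(
            rest, key=lambda t: (min(d.loc[t, c] for c in chosen), t)
        )
        chosen.append(nearest)
        rest.remove(nearest)
    return chosen


def _spread_assign(
    tips: list[str], d: pd.DataFrame, sizes: dict[str, int]
) -> dict[str, list[str]]:
    """Interleaved greedy farthest-point selection, one chain per strategy.

    Strategies take turns; on its turn a strategy claims the unassigned
    tip farthest (max-min patristic distance) from its own tips so far,
    so every group — not just the first to pick — ends up maximally
    spread.  A single strategy of size 2 receives exactly the pool's
    most distant pair.
    """
    unassigned = set(tips)
    chosen: dict[str, list[str]] = {s: [] for s in sizes}
    remaining = dict(sizes)
    order = sorted(sizes)
    pos = 0
    while any(remaining.values()):
        strategy = order[pos % len(order)]
        pos += 1
        if remaining[strategy] == 0:
            continue
        rest = sorted(unassigned)
        if not chosen[strategy]:
            assigned_all = [t for t in tips if t not in unassigned]
            if assigned_all:
                pick = max(
                    rest, key=lambda t: (min(d.loc[t, c] for c in assigned_all), t)
                )
            else:
                sub = d.loc[rest, rest].to_numpy()
                i, _ = np.unravel_index(np.argmax(sub), sub.shape)
                pick = rest[i]
        else:
            pick = max(
                rest, key=lambda t: (min(d.loc[t, c] for c in chosen[strategy]), t)
            )
        chosen[strategy].append(pick)
        unassigned.discard(pick)
        remaining[strategy] -= 1
    return chosen


def plant_labels(
    tree: skbio.TreeNode,
    fractions: dict[str, float],
    conservatism: float,
    seed: int | np.random.Generator,
) -> PlantedTruth:
    """Assign planted strategies to tree tips with tunable conservatism.

    conservatism +1: each non-background strategy occupies a contiguous
    clade (padded from nearest tips when no clade is big enough);
    0: uniform random assignment; -1: greedy farthest-point spread.
    Intermediate magnitudes keep the structured assignment but
    re-shuffle each tip's label with probability ``1 - |conservatism|``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    sizes = _strategy_sizes(fractions, n)
    labels = pd.Series(Strategy.BACKGROUND.value, index=tips, dtype=object)

    if conservatism == 0:
        order = list(rng.permutation(n))
        pos = 0
        for strategy in sorted(sizes):
            for k in range(sizes[strategy]):
                labels.iloc[order[pos + k]] = strategy
            pos += sizes[strategy]
        return PlantedTruth(labels=labels, tree=tree)

    dm = patristic_distances(tree)
    d = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    unassigned = set(tips)
    if conservatism > 0:
        for strategy in sorted(sizes):
            chosen = _clade_pick(tree, unassigned, sizes[strategy], d)
            labels.loc[chosen] = strategy
            unassigned -= set(chosen)
    else:
        for strategy, chosen in _spread_assign(tips, d, sizes).items():
            labels.loc[chosen] = strategy

    reshuffle_p = 1.0 - abs(conservatism)
    if reshuffle_p > 0:
        mark = rng.random(n) < reshuffle_p
        shuffled = rng.permutation(labels.to_numpy()[mark])
        vals = labels.to_numpy(dtype=object)
        vals[mark] = shuffled
        labels = pd.Series(vals, index=tips, dtype=object)
    return PlantedTruth(labels=labels, tree=tree)


def simulate_abundances(
    truth: PlantedTruth,
    spec: SimulationSpec,
    seed: int | np.random.Generator | None = None,
) -> AbundanceTable:
    """Compositional abundance table realizing the planted profiles.

    Fills ``truth.expected_profiles`` with each OTU's pre-normalization
    expected trajectory as a side effect.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(spec.seed if seed is None else seed)
    )
    otus = list(truth.labels.index)
    n = len(otus)
    baseline = rng.dirichlet(np.full(n, spec.dirichlet_concentration))
    baseline = np.maximum(baseline, 1e-12)  # Dirichlet can underflow to 0

    tp_names = [t.value for t in TIMEPOINT_ORDER]
    expected = np.tile(baseline[:, None], (1, 4))
    mult = 2.0**spec.effect_log2
    for i, otu in enumerate(otus):
        strategy = truth.labels[otu]
        peak = STRATEGY_PEAK.get(strategy)
        if peak is not None and strategy != Strategy.BACKGROUND.value:
            expected[i, tp_names.index(peak)] *= mult
    truth.expected_profiles = pd.DataFrame(expected, index=otus, columns=tp_names)

    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    columns, meta_rows = {}, []
    for location, depth in spec.strata:
        for j, tp in enumerate(tp_names):
            for rep in range(1, spec.n_reps + 1):
                sample_id = f"{location}.{depth}.{tp}.r{rep}"
                noise = (
                    rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
                    if sigma > 0
                    else np.ones(n)
                )
                vals = expected[:, j] * noise
                columns[sample_id] = vals / vals.sum()
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "location": location,
                        "depth": depth,
                        "timepoint": tp,
                        "replicate": f"r{rep}",
                    }
                )
    data = pd.DataFrame(columns, index=otus)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return AbundanceTable(data, metadata)


def simulate_taxonomy(
    otu_ids, seed: int | np.random.Generator, otus_per_genus: int = 5
) -> pd.DataFrame:
    """Mock ranked lineages: OTUs grouped into genera, genera nested upward."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    otus = list(otu_ids)
    n_genera = max(1, len(otus) // otus_per_genus)
    genus_of = rng.integers(n_genera, size=len(otus))
    rows = []
    for otu, g in zip(otus, genus_of):
        g = int(g)
        rows.append(
            {
                "otu_id": otu,
                "domain": "Bacteria",
                "phylum": f"Phylum{g // 27 + 1:02d}",
                "class": f"Class{g // 9 + 1:02d}",
                "order": f"Order{g // 3 + 1:03d}",
                "family": f"Family{g + 1:03d}",
                "genus": f"Genus{g + 1:03d}",
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


#: Baseline guild frequencies: saprotrophs dominate, as in temperate soils.
BASE_GUILD_PROBS: dict[str, float] = {
    TrophicMode.SAPROTROPH.value: 0.70,
    TrophicMode.EMF.value: 0.06,
    TrophicMode.AMF.value: 0.04,
    TrophicMode.ENDOPHYTE.value: 0.05,
    TrophicMode.OTHER.value: 0.05,
    TrophicMode.UNKNOWN.value: 0.10,
}

#: With EMF enrichment, spring-adapted fungi shift toward ectomycorrhizae.
SPRING_EMF_GUILD_PROBS: dict[str, float] = {
    TrophicMode.SAPROTROPH.value: 0.51,
    TrophicMode.EMF.value: 0.25,
    TrophicMode.AMF.value: 0.04,
    TrophicMode.ENDOPHYTE.value: 0.05,
    TrophicMode.OTHER.value: 0.05,
    TrophicMode.UNKNOWN.value: 0.10,
}


def plant_guilds(
    truth: PlantedTruth,
    spec: SimulationSpec,
    seed: int | np.random.Generator,
    emf_enrichment: bool = True,
) -> pd.Series:
    """Guild labels for a fungal fraction of OTUs.

    Saprotrophs are the majority class everywhere; when
    ``emf_enrichment`` is on, spring-adapted fungi draw from an
    EMF-enriched distribution (mycorrhizal spring flush).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    otus = list(truth.labels.index)
    n_fungal = round(spec.fungal_fraction * len(otus))
    if n_fungal == 0:
        return pd.Series(dtype=object, name="trophic_mode")
    fungal = sorted(rng.choice(otus, size=n_fungal, replace=False))
    modes = list(BASE_GUILD_PROBS)
    base_p = np.array([BASE_GUILD_PROBS[m] for m in modes])
    spring_p = np.array([SPRING_EMF_GUILD_PROBS[m] for m in modes])
    out = {}
    for otu in fungal:
        is_spring = truth.labels[otu] == Strategy.SPRING_ADAPTED.value
        p = spring_p if (emf_enrichment and is_spring) else base_p
        out[otu] = modes[int(rng.choice(len(modes), p=p))]
    return pd.Series(out, name="trophic_mode", dtype=object)


def generate(spec: SimulationSpec, emf_enrichment: bool = True) -> SyntheticDataset:
    """Build a complete synthetic dataset from one spec (deterministic)."""
    ss = np.random.SeedSequence(spec.seed)
    r_tree, r_labels, r_abund, r_tax, r_guild = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    tree = simulate_tree(spec.n_otus, r_tree)
    truth = plant_labels(tree, spec.strategy_fractions, spec.conservatism, r_labels)
    table = simulate_abundances(truth, spec, r_abund)
    taxonomy = simulate_taxonomy(truth.labels.index, r_tax)
    guilds_ = plant_guilds(truth, spec, r_guild, emf_enrichment=emf_enrichment)
    return SyntheticDataset(
        spec=spec, truth=truth, table=table, taxonomy=taxonomy, guilds=guilds_
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write abundance.tsv, metadata.tsv, tree.nwk, taxonomy.tsv, guilds.tsv, truth.tsv."""
    from pathlib import Path

    from .io import write_abundance_table, write_guild_table, write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(
        dataset.table, outdir / "abundance.tsv", outdir / "metadata.tsv"
    )
    write_newick(dataset.truth.tree, outdir / "tree.nwk")
    dataset.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index_label="otu_id")
    write_guild_table(dataset.guilds, outdir / "guilds.tsv")
    dataset.truth.labels.rename("planted_strategy").to_csv(
        outdir / "truth.tsv", sep="\t", index_label="otu_id"
    )
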