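# snowniche

Soil microbial communities in seasonally snow-covered ecosystems bloom
beneath the winter snowpack and crash after snowmelt, releasing one of
the year's largest pulses of soil nitrogen. `snowniche` is a Python
package for asking *who* drives that bloom and crash: it classifies
archaeal, bacterial and fungal OTUs into snowmelt-related **life
strategies** from a seasonal relative-abundance table, then tests
whether the organisms sharing a strategy are phylogenetically related
(archaea/bacteria) or functionally similar (fungi). It is written for
microbial ecologists with an OTU table, sample metadata, a phylogeny,
and optional taxonomy/guild annotations.

## What it computes

Given samples from four dates bracketing the snowpack (September,
March, May, June) across locations × depths × replicates, per stratum
(location × depth):

1. **Differential abundance.** For each OTU and each transition —
   winter (SEP→MAR), snowmelt (MAR→MAY), spring (MAY→JUN) — the fold
   change of mean relative abundance FC = m₂/m₁, with a 95% CI by
   error propagation for a ratio,

       CI_FC = |FC| · √( (CI₁/m₁)² + (CI₂/m₂)² ),

   a two-sided p-value recovered from the CI on the log scale
   (z = |ln FC| · 1.96 / (CI_FC/FC)), and Benjamini–Hochberg FDR
   across all OTU × transition tests. OTUs with any q < 0.05 are
   *responders*.
2. **Life strategies.** Responders are clustered on their z-scored
   4-point temporal profiles (Euclidean distance, average-linkage
   UPGMA, single cut into k clusters) and each cluster is labelled by
   its centroid's peak: winter-adapted (MAR), snowmelt-specialist
   (MAY), spring-adapted (JUN), fall (SEP). Group relative-abundance
   trajectories and per-genus percent contributions to each group's
   change are reported.
3. **Phylogenetic relatedness.** For each strategy group, NRI and NTI
   — negated standardized effect sizes of MPD and MNTD against a
   random-taxa-shuffling null (uniform same-size subsets of the
   regional pool; 1000 permutations) — with rank-based permutation
   p-values. Positive = phylogenetic clustering.
4. **Fungal guilds.** Percent of member OTUs per trophic mode (AMF,
   EMF, endophyte, saprotroph, other) per strategy, over members with
   known annotations.

A synthetic-data module generates abundance tables, Yule phylogenies
with tunable phylogenetic conservatism of planted strategy labels, and
guild tables, so every stage can be verified against ground truth.
See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic community — 200 OTUs, one stratum, 6 replicates
per date, a quarter of OTUs planted in each of the three snowmelt
strategies with a 4-fold bloom at their peak date — and run the full
pipeline:

```python
from snowniche.synthetic import SimulationSpec, generate
from snowniche.pipeline import RunConfig, run_pipeline, recovery_report

spec = SimulationSpec(seed=42, n_otus=200, n_reps=6,
                      strata=(("hillslope", "D0_5"),))
ds = generate(spec)
cfg = RunConfig(output_dir="out", seed=42, k=4)
res = run_pipeline(cfg, ds.table, tree=ds.truth.tree,
                   taxonomy=ds.taxonomy, guilds=ds.guilds)
print(res.report["strata"][0]["strategy_sizes"])
print(recovery_report(res, ds.truth))
```

This prints:

```
{'WINTER_ADAPTED': 50, 'SPRING_ADAPTED': 50, 'SNOWMELT_SPECIALIST': 50, 'FALL': 50}
{'responder_sensitivity': 1.0, 'responder_fdp': 0.25, 'strategy_accuracy': 1.0, ...}
```

All 150 planted OTUs are recovered as responders with their correct
strategy (sensitivity and accuracy 1.0). The 50 background OTUs also
respond — relative abundances are compositional, so the rest of the
community is diluted at every bloom — and form their own fall-peaking
cluster (hence k=4 and a responder false-discovery proportion of 0.25
*relative to the planted labels*; these are real compositional
changes, not statistical errors). The relatedness table
(`res.relatedness`) reports NRI/NTI per group; with labels planted at
random (`conservatism=0`, the default) they hover around zero, e.g.

```
           strategy  n_otus   nri   nti  p_mpd
SNOWMELT_SPECIALIST      50  0.44  0.06   0.58
     SPRING_ADAPTED      50 -1.04 -0.01   0.28
     WINTER_ADAPTED      50 -1.30 -0.06   0.15
```

while `conservatism=+1` plants each strategy on a clade and yields
strongly positive, significant NRI.

The same analysis is available from a shell:

```sh
snowniche synth --seed 42 --n-otus 200 --out data/
snowniche run --abundance data/abundance.tsv --metadata data/metadata.tsv \
    --tree data/tree.nwk --taxonomy data/taxonomy.tsv --guilds data/guilds.tsv \
    --k 4 --seed 42 --out out/
snowniche recover --run-dir out/ --truth data/truth.tsv
```

Outputs are TSVs (`foldchanges.tsv`, `strategies.tsv`,
`group_abundance.tsv`, `contributions.tsv`, `relatedness.tsv`,
`guild_composition.tsv`) plus a JSON run report with stage counts and
warnings; reruns with the same config and seed are byte-identical.

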