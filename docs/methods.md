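# Methods

`snowniche` classifies soil microbial OTUs into snowmelt-related life
strategies from a seasonal relative-abundance table and asks whether
the organisms sharing a strategy are phylogenetically related and, for
fungi, functionally similar. This note describes the model behind each
stage, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Study design assumed by the pipeline

The pipeline expects a community sampled at four dates bracketing a
winter snowpack — autumn after plant senescence (`SEP`), peak snow
(`MAR`), mid-snowmelt (`MAY`), and post-snowmelt spring (`JUN`) — at
two locations (an upland hillslope and a riparian floodplain), three
soil depth classes (0–5 cm, 5–15 cm, >15 cm), and several replicate
samples per location × depth × date. Each location × depth combination
(a *stratum*) is analyzed independently end to end. Abundances are
within-sample proportions; count tables are renormalized per sample on
input.

## Differential abundance across seasonal transitions

OTUs observed in fewer than 25% of samples (default; an OTU must be
nonzero in at least ⌈0.25 · n_samples⌉ samples) are removed first.
Filtered proportions are deliberately *not* renormalized, so values
remain relative to the full community.

For each OTU, stratum, and date, the replicate samples give a mean
relative abundance m_t and a 95% confidence half-width
CI_t = 1.96 · s_t/√n (s_t the sample standard deviation; CI_t = 0 when
n = 1). For each of the three consecutive transitions — winter
(SEP→MAR), snowmelt (MAR→MAY), spring (MAY→JUN) — the fold change is
FC = m₂/m₁ with the CI propagated as for the product of a ratio:

    CI_FC = |FC| · √( (CI₁/m₁)² + (CI₂/m₂)² )

A pseudo-abundance (default: half the smallest nonzero proportion in
the filtered table) is added to both means so zero means never divide
by zero while large means are perturbed negligibly. The 1.96
multiplier is a fixed normal quantile, not a t-quantile: the
propagation algebra assumes a common multiplier on both terms.

A two-sided p-value is recovered from the CI on the log scale (the
standard back-conversion for a ratio): the relative half-width
r = CI_FC/FC equals 1.96 times the delta-method standard error of
ln FC, so z = |ln FC|·1.96/r and p = 2(1 − Φ(z)). Degenerate inputs
(r = 0) give p = 1 when FC = 1 and p = 0 otherwise. p-values are
Benjamini–Hochberg adjusted jointly over all OTU × transition tests
within a stratum, and an OTU is a *responder* if any of its three
transitions has q < α (default α = 0.05).

The p-values are approximate in two ways worth knowing: the normal
(rather than t) multiplier is slightly anti-conservative at small n,
and the delta method linearizes the log ratio. The FDR-control check
below measures the net effect under the null.

## Life-strategy classification

Responder OTUs are clustered on the *shape* of their seasonal
trajectory: the four timepoint means are z-scored per OTU (population
standard deviation, so each profile has mean 0 and sd 1; zero-variance
profiles are flagged constant, excluded from clustering, and labelled
UNASSIGNED), pairwise Euclidean distances are agglomerated with
average linkage (UPGMA), and the dendrogram is cut at the single
smallest height that yields exactly k clusters. The procedure is
deterministic: profiles are processed in lexicographic OTU order.

Each cluster is labelled by the timepoint at which its centroid peaks
(ties broken toward the later timepoint):

| peak | strategy |
|------|----------|
| SEP  | fall |
| MAR  | winter-adapted |
| MAY  | snowmelt-specialist |
| JUN  | spring-adapted |

Several clusters may share a label.

**Choosing k.** The rule is: k = the number of distinct temporal
shapes expected in the data. Archaea/bacteria typically show the three
snowmelt-related shapes (k = 3); fungi additionally show a
fall-peaking group (k = 4). Relative abundances are compositional, so
whenever the blooming groups are a large fraction of the community,
the non-blooming rest of the community acquires a coherent
mirror-image shape peaking at the quiet timepoint — a fourth shape in
its own right. On synthetic data with three planted strategies plus a
background quarter, k = 4 separates that background cluster cleanly,
whereas k = 3 would merge it into one signal cluster and make that
cluster's label ambiguous.

**Group summaries.** Group relative abundance per stratum × timepoint
is the per-sample sum of member proportions averaged over replicates.
Contribution rankings aggregate member OTUs to genus (the lowest
assigned taxonomic rank; OTUs without taxonomy keep their id), compute
each taxon's change in stratum-mean abundance over a transition, and
express it as a percent of the group's total change; taxon-level log2
fold changes are recomputed from the aggregated abundances. Percent
contributions over *all* members sum to 100 exactly; members opposing
the group's direction get negative percentages and rank last. A group
with zero net change has undefined percentages and is reported as an
error.

## Phylogenetic relatedness (NRI/NTI)

For each strategy group within a stratum, two metrics are computed on
patristic distances (sum of branch lengths along tip-to-tip paths),
both unweighted: MPD (mean over all unordered member pairs) and MNTD
(mean distance of each member to its nearest other member; for a
2-member group MNTD = MPD, an accepted consequence). The null model is
*random taxa shuffling*: the metric over uniform random same-size
subsets of the regional species pool (for unweighted metrics this is
equivalent to shuffling tip labels). The pool defaults to all
prevalence-filtered OTUs observed in the stratum that are present in
the tree; a responders-only pool is available.

    NRI = −(MPD_obs − mean(MPD_null)) / sd(MPD_null)    (NTI analogous)

so positive values mean phylogenetic clustering. The null sd is the
sample sd (n−1 denominator) of the n_perm draws (default 1000).
Significance is a two-sided rank-based permutation p,
p = 2·min(r⁺, r⁻)/(n_perm + 1) with the +1-augmented counts of null
values at or beyond the observation, hence p ≥ 1/(n_perm+1). When
every null draw is identical (pool = group, or a star phylogeny) the
result is flagged degenerate and the index set to 0.

An exhaustive-enumeration oracle (`exhaustive_null`) computes the
exact null distribution for pools with ≤ 10⁵ subsets. One estimator
subtlety: the oracle's n−1 sd over the N distinct subsets and the
Monte-Carlo sample sd (which converges to the *population* sd of the
subset distribution) differ by the factor √(N/(N−1)) — about 9% for
the 4-tip test fixture, under 2% for 8-tip pools, negligible
thereafter. Tests comparing the two align conventions explicitly.

## Fungal guild composition

Within each stratum × strategy, the percent of member OTUs per trophic
mode (AMF, EMF, endophyte, saprotroph, other) is computed over members
with a *known* guild; unknown-annotation members are counted
separately, never dropped. Percentages are exact rationals before
float conversion, so they sum to 100. Counting is by OTU richness, not
abundance, matching how guild tables are conventionally reported.

## Synthetic data with planted truth

The generator exists so that every stage has ground truth.

- **Phylogeny**: a Yule (pure-birth, unit-rate) tree with exponential
  waiting times; fully bifurcating, strictly positive branch lengths,
  deterministic per seed.
- **Labels**: each OTU gets a planted strategy. `conservatism` ∈
  [−1, 1] controls phylogenetic signal: +1 places each strategy on a
  contiguous clade (smallest clade at least the group size, padded
  from nearest tips when none is large enough); 0 assigns labels
  uniformly at random (multiset exactly matching the requested
  fractions); −1 runs interleaved greedy farthest-point selection —
  strategies take turns claiming the unassigned tip farthest from
  their own tips, so every group, not just the first, is maximally
  spread. Intermediate magnitudes keep the structured assignment and
  re-shuffle each tip's label with probability 1 − |conservatism|.
- **Abundances**: a baseline community from a symmetric Dirichlet
  (concentration 0.5, realistic rank-abundance skew); a planted OTU's
  expectation is multiplied by 2^effect_log2 at its strategy's peak
  timepoint (single-peak model — the label rule is argmax-based, so
  this is the minimal structure that exercises it honestly).
  Replicates multiply expectations by i.i.d. lognormal noise with
  coefficient of variation `noise_cv` and are renormalized per sample.
- **Guilds**: a `fungal_fraction` of OTUs gets trophic modes;
  saprotrophs are the majority class (70%) everywhere, and with EMF
  enrichment on, spring-adapted fungi draw from an EMF-enriched
  distribution (25% vs 6% baseline).

Defaults are the study-design conditions: 2 locations × 3 depths, 4
dates, 6 replicates, 200 OTUs, fractions 25/25/25% for the three
snowmelt strategies plus 25% background, effect_log2 = 2 (4-fold
bloom), noise_cv = 0.2.

What the generator does **not** emulate: sequencing counts and their
discreteness (noise is lognormal on proportions, not
Dirichlet-multinomial — the pipeline consumes proportions and the CI
propagation assumes roughly symmetric errors on means), spatial
autocorrelation between plots, smooth multi-timepoint bloom curves,
taxonomy-correlated abundance structure, and OTU-clustering artifacts.
Passing tests therefore show the inference chain is correct under its
own assumptions, not that those assumptions hold for any particular
field dataset.

A consequence of compositionality worth noting: with a quarter of the
community blooming 4-fold at each signal timepoint, the *background*
OTUs genuinely change in relative abundance (they are diluted at every
bloom), are correctly detected as responders, and form the fourth
temporal shape discussed above. The recovery metrics therefore report
label accuracy among planted-signal OTUs and the false-discovery
proportion separately.

## Numerical choices and degenerate inputs

- Ties in UPGMA cluster assignment and in greedy tip selection are
  broken lexicographically by OTU id; the pipeline output is
  byte-identical across reruns with the same config and seed.
- All randomness flows through `numpy.random.Generator` seeded from
  the run seed (child streams via `SeedSequence.spawn`).
- Zero-total samples, duplicate ids, negative values and unknown enum
  values are format errors naming the offending record. OTUs missing
  from the tree/taxonomy/guild tables are allowed; operations needing
  the annotation skip them with a counted warning in the run report.
- Profile z-scores of constant profiles are all-zero vectors, flagged
  and excluded from clustering.
- Problem sizes used by the verification suite and the acceptance
  script (200–1000 OTUs, one or two strata, 99–1000 permutations,
  10–20 seeds per check) were chosen as the smallest sizes at which
  the stochastic checks have comfortable margins; they are package
  defaults, not statements about the upstream study's scale.

## Known limitations

- The CI→p conversion is exact only under log-normality of the fold
  change; with n = 6 replicates it is mildly anti-conservative. The
  null-data check bounds the practical effect (responder fraction
  ≈ 1% at α = 0.05, well under α, because BH over thousands of mostly
  true-null tests is itself conservative).
- "Cut at even height" yields exactly k clusters except when profiles
  are exactly duplicated at merge height 0, in which case fewer
  clusters can result.
- NRI/NTI use an abundance-unweighted null; abundance-weighted SES
  metrics and alternative null models (phylogeny shuffle, independent
  swap) are out of scope.
- The exhaustive oracle is limited to 10⁵ subsets; beyond that only
  the Monte-Carlo null is available.
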