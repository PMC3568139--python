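# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions that were genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design assumed

Four individuals (A–D) sampled in stool at four time-points — two
pre-diarrhea baselines (tp1, tp2), one during PEG-induced osmotic diarrhea
(tp3), one post-diarrhea (tp4) — and, for individuals B–D, sigmoid-mucosa
biopsies at tp2 and tp3. Mucosa samples at other time-points raise a
validation warning, not an error: the design is configurable.

All analyses operate on relative abundances in percent of the sample
total, because the underlying 16S counts are compositional: a genuine
bloom of one taxon necessarily lowers every other relative abundance, and
no claim about absolute cell numbers is possible.

## Normalization and transform

Counts are scaled to the deepest sample of the analysis set
(factor_s = max depth / depth_s), so all scaled columns sum to the maximum
raw depth. Whether the reference should be the global deepest sample or
the deepest within each analysis set is genuinely open; the default is the
analysis set, with a `global` option, because depth normalization is only
meaningful relative to the samples actually being compared.

Before ordination the scaled abundances are transformed as
log2(x + u), u ~ U(0.75, 1.25) drawn independently per matrix entry under
a recorded seed (u = 1 exactly in the deterministic `off` mode). The
jitter breaks the atom at zero and downweights dominant OTUs; drawing per
entry (rather than per OTU) is the natural reading of "adding a value" to
each abundance datum and is what the seed controls.

## Alpha diversity

* **Chao1**, bias-corrected: S_obs + F1(F1−1)/(2(F2+1)). The
  bias-corrected form is total (defined when F2 = 0), unlike the classic
  F1²/(2F2) form; this is a deliberate divergence documented here.
* **ACE** with rare cutoff 10 (the conventional default, configurable):
  S_abund + S_rare/C + (F1/C)·γ², C = 1 − F1/N_rare,
  γ² = max((S_rare/C)·Σ i(i−1)F_i/(N_rare(N_rare−1)) − 1, 0). Two
  degenerate branches are defined explicitly: no rare taxa → S_obs;
  zero coverage (all rare taxa singletons) → fall back to Chao1.
* **Shannon** uses natural log; **evenness** is Pielou's J = H/ln S_obs
  (undefined at S_obs = 1, returned as NaN). Which evenness the original
  ecology tooling used is not stated anywhere authoritative; Pielou's J is
  the standard choice and is documented as such.
* **Rarefaction** is the analytic hypergeometric expectation
  E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)], computed in log-gamma space;
  group curves report mean ± SEM across samples, truncating each sample at
  its own depth. A single-sample group reports SEM 0 and is flagged via
  `n_samples`.

## Slope scoring (*Viz*)

Stool profiles are (pre, diarrhea, post) with pre = (a1 + a2)/2; mucosa
profiles are (pre, diarrhea). A slope from a to b scores 0 when
|b − a| < 0.05 percentage points and sign(b − a) otherwise. The two
published phrasings of the threshold ("change < ±0.05%" scores 0; "at
least 0.05%" is included) conflict exactly at 0.05; they are reconciled as
|Δ| ≥ 0.05 ⇒ scored ±1 and includable, which makes both statements true.

Overall score = 3·s₁ + s₂ is a bijection {−1,0,1}² → {−4..4}; the 9
pattern labels are the slope words joined by a hyphen
(`increase-decrease`, `flat-flat`, ...). An OTU is included when at least
one slope reaches the threshold, so included OTUs are never `flat-flat`.
Two-point profiles use the 3 labels `increase`/`flat`/`decrease`.

An (OTU, pattern) association is emitted when the same included pattern
recurs in at least `min_individuals` (default 2) individuals. The network
node size for stool is the **mean** of the two absolute slope changes
(configurable to sum): the two published descriptions ("sum of changes"
vs "mean relative abundance change") disagree, and the mean keeps stool
and mucosa node sizes on the same scale.

## Stability

CV between the tp2 and tp3 relative abundances uses the two-point sample
standard deviation (n−1 denominator): sd = |x₂−x₃|/√2. The n-denominator
alternative would scale every CV by 1/√2 and thereby shift the effective
10% threshold; the choice is logged here because the original definition
is unstated. "At least 10 reads per individual" is read as ≥ 10 raw reads
summed over the two compared samples (`reads_rule="per_sample"`
available). OTUs absent from both samples have undefined CV and are
excluded from the call set.

## Differential abundance and consensus

* **Permutation t-test (M)**: Welch t on relative abundances; the null
  redistributes group labels over the pooled samples. All C(n, n_A)
  arrangements are enumerated when that count is ≤ 2000 (always true for
  the 4 vs 4 design: 70), giving exact tail p-values with the observed
  arrangement included; otherwise 1000 random permutations with the
  add-one estimate (b+1)/(B+1). OTUs with fewer than 10 raw reads overall
  are too sparse for a t statistic and use two-sided Fisher's exact on the
  pooled (OTU reads vs other reads) × group table. The permutation count
  for the original tool's "default settings" is unstated; 1000 is chosen
  and recorded in the run log.
* **Paired log-ratio t-test (E)**: one-sample t of
  log2((x₃ + 0.001)/(x₂ + 0.001)) against 0 across individuals. This is a
  deliberate, documented stand-in occupying the paired-count-model slot of
  the consensus: it respects the paired design and effect direction
  without importing a negative-binomial GLM framework. A constant nonzero
  log-ratio has zero variance and is flagged in its direction with a
  configurable p (default 0, i.e. detected).
* **Viz (V)**: detection = association in ≥ 2 individuals.

Consensus score = number of methods detecting the OTU; score ≥ 2 defines
the consensus set, mirroring the reference tables' columns (OTU, score,
method letters MEV, mean ± sd percent at tp2 and tp3, taxonomy string).
Detection uses raw p < 0.05 for the per-OTU consensus counts (matching the
deliberately unstringent per-OTU reporting convention at n = 4), and
BH-adjusted p-values for rank-level claims. Rank-level tests are paired t
on abundance differences or ratio-paired t of per-individual ratios
against 1 (raw ratios per the literal definition; individuals with the
taxon absent pre-diarrhea are excluded with a warning), BH-adjusted across
taxa within the rank.

The phylum–pattern association is two-sided Fisher's exact on
(phylum membership) × (direction-group membership) over the distinct
associated OTUs; the direction group of a pattern is its first
(pre-diarrhea → diarrhea) slope, so `flat-*` patterns belong to neither
group.

## Ordination and overlap

PCA is the SVD of the column-centered (unscaled) samples × OTUs matrix of
normalized jittered-log2 abundances; the sign convention makes each
component's largest-magnitude loading positive; variance percentages are
over all retained components and sum to 100. Group separation is a
Student's t-test of within-group vs between-group pairwise Euclidean
distances in the first two PCs — the plotted space; the original test
substrate is unstated, and this choice is recorded here. Confidence
ellipses use the chi-square(2) quantile of the sample covariance at level
0.87.

Phylotype overlap between samples is 100·|∩|/|∪| of the presence sets
(Jaccard); the "mean of per-sample fractions" alternative is available
behind a flag because the original denominator is undefined. Sequence
overlap is the percentage of all reads in the set belonging to shared
OTUs. Phylum composition pools phyla below 2% into "Other"; domain-only
(sub-cutoff) assignments form an explicit "unclassified" bucket that is
never pooled and is retained in rank-level tests.

## Taxonomy strings

RDP-style strings concatenate (name, confidence) pairs with ranks
positional domain → genus. The grammar is ambiguous for names ending in
digits (`TM70.53`, `Incertae sedis 50.87`); the confidence token is the
right-anchored maximal `[01].digits` match, which uniquely resolves every
string in the packaged reference tables (the parse–serialize round trip
over all 84 strings is asserted). Confidences below the 0.80 cutoff mask
that rank and all deeper ranks to `unclassified`.

## Synthetic-data model

Per individual and habitat, phylum-level fractions are a Dirichlet draw
(concentration 200) around the habitat template — stool: Bacteroidetes
0.70, Firmicutes 0.22, Proteobacteria 0.02, minor phyla the rest; mucosa:
Firmicutes 0.75, Bacteroidetes 0.18, Proteobacteria 0.05 — partitioned
within each phylum by per-individual lognormal weights (σ = 1.5), giving
individualized long-tailed communities. Counts are multinomial draws at
negative-binomial depths (mean 20,000, size 60, so normalization factors
vary over a plausible range without being targeted at any particular
interval).

Planted effects, all applied to the composition before counting:

* **Responders** (default 10 up at fold 5 and 10 down at fold 0.2, stool,
  rebounding at tp4), pinned at 0.5–1.0% baseline so their absolute
  changes clear the 0.05-point slope threshold by a wide margin.
* **Stable OTUs** (default 20 at 0.5–1.2% baseline, 60% Firmicutes / 40%
  Bacteroidetes, reflecting the overrepresentation of Firmicutes among
  stable taxa) are pinned at their baseline relative abundance at every
  time-point and exempt from temporal noise — stable phylotypes are stable
  by definition; only multinomial sampling perturbs them.
* **Wash-out**: OTUs below 0.05% baseline are dropped at tp3 with
  probability 0.3 (per individual), and stay absent at tp4 — richness
  remains depressed one week post-diarrhea. Dropped OTUs are recorded in
  the ground truth as `washed_out`: they genuinely changed, so recovery
  metrics count neither hits nor misses on them as false discoveries.
* **Proteobacteria bloom**: mucosal Proteobacteria are multiplied by 3 at
  tp3.
* **Temporal noise**: every non-stable OTU's abundance is multiplied by an
  independent lognormal factor (σ = 0.4 natural-log, ~1.5-fold typical
  day-to-day change) at every time-point. Without it a closed composition
  transmits the responders' displacement as a perfectly consistent
  log-ratio shift to every abundant null — detectable by any paired test —
  which no real longitudinal stool series exhibits; the magnitude is
  consistent with baseline within-group SDs of the order of the means seen
  in real consensus tables.

After all effects the composition is closed (renormalized) holding the
planted-stable OTUs fixed. Everything is reproducible bit-for-bit from the
config seed.

`null_config` switches every effect off **and** shares one baseline
community across individuals, making all samples of a habitat iid: this is
the fully exchangeable null on which permutation p-values are calibrated.
With individualized baselines the unpaired permutation test is
conservative (between-individual variance dominates), which is faithful to
real data but is a different claim than calibration.

### What the generator does not emulate

Sequence-level artifacts (errors, chimeras), phylogenetic correlation
between OTUs, true ecological interactions, enterotype structure, and
realistic taxonomy uncertainty beyond a 3% sub-cutoff fraction. Passing
recovery tests therefore demonstrates that the pipeline detects the
effects it models under realistic sampling noise and individualization —
not that it would achieve the same operating characteristics on real 454
pyrosequencing data.

## Problem sizes used in tests and the acceptance script

Simulated studies use the default 500 OTUs × 22 samples at ~20,000 reads.
Recovery metrics average 10 simulation seeds; the directional wash-out and
Proteobacteria checks use 20 replicate seeds; null calibration uses one
200-OTU exchangeable study (2 × 4 samples, exact enumeration of all 70
label arrangements); oracle sweeps use 100 random count vectors
(estimators) and 1000 random p-vectors (BH). These sizes make the whole
acceptance run complete in well under a minute while leaving the binomial
error of every reported rate small relative to its acceptance margin.

## Known limitations

* The permutation test's exact p-values are granular (multiples of 1/70
  at n = 4 vs 4): BH adjustment across hundreds of OTUs cannot push them
  below conventional thresholds, which is why per-OTU consensus counting
  follows the raw-p convention.
* The paired log-ratio stand-in ignores count overdispersion; it is a
  consensus leg, not a replacement for a count GLM.
* CV-based stability at ~0.5% abundance and 20,000 reads is at the edge of
  multinomial resolution: per-individual sampling noise alone produces a
  CV near the 10% threshold, so single-individual stability calls at low
  abundance carry limited evidence (recovery counts a planted stable OTU
  as found when it is called stable in at least one individual).
* Consensus FDR control is empirical, not guaranteed: the three legs are
  correlated through the shared data, and 2-of-3 voting only attenuates,
  never removes, that correlation.
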