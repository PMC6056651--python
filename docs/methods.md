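# Methods

## Model and procedure

The core statistic is a per-protein comparison of somatic mutation rates
between the merged lysine-modification motif region (k positions) and the
background (n − k positions). Counts are Poisson with region-specific rates
λ₁, λ₂ under independent Gamma(shape, **rate**) priors; the rate
parameterization is used throughout (the prior density carries e^{−βλ}, so β
multiplies λ). The posterior factorizes by conjugacy:

- λ₁ | Y ~ Gamma(ΣY_mod + α₁, k + β₁)
- λ₂ | Y ~ Gamma(ΣY_bg + α₂, n − k + β₂)

Because neither full conditional involves the other rate, the Gibbs chain
has no serial dependence; `gibbs_sample` therefore draws the whole schedule
(5,200 sweeps, 200 burn-in, 5,000 retained) in one vectorized call, which is
the same chain a sequential sweep would produce. R = λ₁/λ₂ is taken from
each joint draw rather than from its own conditional Gamma form — the two
are distributionally identical, and the ratio route is simpler and is
validated against the exact answer. The posterior p-value is
p = #{R ≤ 1}/5,000; "≤" is used (the draw-level event R = 1 has probability
zero). The exact oracle is P(λ₁ ≤ λ₂) = I_{b₁/(b₁+b₂)}(a₁, a₂) via the
Beta representation of a Gamma ratio; it backs the test suite and is the
fast path for large simulation studies. Multiple testing is corrected by
Benjamini–Hochberg **within each (cancer type, modification type) stratum**,
with drivers called at q < 0.05 and cross-cancer recurrence summarized
separately.

Prior hyperparameters default to α = β = 1 for both regions (weakly
informative, prior mean one mutation per position-unit, configurable).
Proteins with an empty motif or background region are excluded with a
reason code rather than tested.

## Region construction

Each site contributes a flanking window of half-width h = 10 (gap-padded at
sequence ends). Windows of one modification type are clustered by k-means on
one-hot encodings (gap = zero vector, Euclidean metric); the cluster count
is chosen by best mean silhouette over k ∈ {2..5} with a fallback to one
cluster for tiny, constant, or unstructured window sets. Per cluster, a
PSSM is built with column probabilities (count + c)/(N_j + 20c)
(pseudocount c = 1) and log-odds against the uniform 1/20 background; an
all-gap column scores zero. The motif half-width is the smallest w ≥ 1 such
that no column beyond ±w is informative at ≥ 0.2 bits. Column information
is the KL divergence to uniform **minus the Miller–Madow small-sample bias
19/(2 ln 2 · N)** (floored at zero): without this correction a cluster of a
handful of windows makes every column appear informative (~2.7 bits of pure
bias at N = 5) and the selected motifs absorb most of the protein. The
width floor w ≥ 1 keeps the modified lysine's immediate neighbours in the
motif. Per-protein partitions are the union of clipped [pos − w, pos + w]
intervals; proteins without any site are excluded from the analysis
entirely rather than treated as all-background.

## Mutation handling

Only non-synonymous SNVs are retained (label set
{Missense_Mutation, nonsynonymous SNV, missense_variant}, configurable);
rows with unparsable positions or identical ref/alt residues are counted
and skipped; duplicates are collapsed on (sample, cancer type, protein,
position, alt residue) keeping the first occurrence. Counts are pooled
across patients per position (the model indexes positions, not patients).
Coordinates are 1-based inclusive protein positions throughout; sample ids
are assumed already harmonized across sources.

## Domain bootstrap

Rates are mutations per 1,000 aa of merged domain (or complementary
disorder) region per protein. The two per-protein rate samples are shifted
to the common grand mean z (means equalized exactly, spreads untouched),
resampled B = 1,000 times with replacement, and compared through a
studentized mean difference. The denominator pairs each sample's variance
with **its own** sample size (Welch convention); the alternative pairing
that divides σ̂²_x by n and σ̂²_y by m is available behind
`printed_denominator=True` for comparison, but the Welch form is the
default because the swapped pairing makes the statistic's scale depend on
which group is labelled first. Sample variances use the n − 1 denominator.
Zero-variance equal-mean data is defined as t = 0, p = 1. The per-domain
filter is an upper-tail hypergeometric test with population = all residues
of the analyzed proteins, marked class = the domain's residues, draw = the
(unique) modification-related mutated positions, BH-corrected across
domains.

## Deleteriousness, conservation, enrichment

The deleterious score of a mutation is the number of five damage-predictor
calls that are true (missing calls count as tolerated, a conservative
choice), hence an integer 0–5. Groups are compared per score threshold by a
two-proportion z-test without continuity correction, alongside the full
score distribution. Conservation scores (phastCons-like, consumed as an
input column) are compared by the asymptotic two-sample KS test with CDF
curves emitted for plotting. Set enrichment (driver census overlap, generic
gene sets) is the exact hypergeometric upper tail; a two-sided option sums
tables of no-larger point probability. Note that on the census worked
example (N = 13,378, K = 699, n = 473, k = 45) the exact upper tail is
7.1 × 10⁻⁵ while an uncorrected two-proportion chi-square gives 2.0 × 10⁻⁵;
the package reports the exact tail and, in the acceptance script, both.
Subcellular summaries count a multi-compartment protein once per
compartment, with unmapped proteins reported.

## Survival

Patients are grouped by whether any of their mutations falls inside a
modification region of an **identified driver protein** (pooled mode;
per-protein grouping is available through `assign_groups` by passing a
single-protein partition map). Kaplan–Meier estimation and the log-rank
test are delegated to lifelines; events precede censorings at tied times,
non-positive or missing times are dropped with a count, and a zero-event
comparison returns p = 1 with a warning rather than failing.

## Network prioritization

The heterogeneous network merges undirected weighted protein–protein and
drug–target edges (duplicates collapse to maximum weight, self-loops
dropped, non-positive weights rejected; drug nodes may only carry
drug-target edges). The walk iterates p ← (1 − r)Wp + r·p₀ with W the
column-normalized weighted adjacency — column-stochastic, so probability
mass is conserved at every step — and p₀ uniform over the seed drivers;
r = 0.7 by default (common practice; the source analysis does not state
it), tolerance 1e−10 (L1), at most 1,000 iterations. No separate
inter-layer jump parameter is used: the merged network is treated as one
graph. The fixed point is unique for r > 0 and the iteration is verified
against the direct solve (I − (1 − r)W)p = r·p₀. Targets are the top-k
(default 10) non-seed protein nodes by global stationary score, ties broken
by node id; drugs are reported when adjacent to a reported target or seed.

## Synthetic data

The generators emulate exactly the structure the model assumes, which is
what makes ground-truth recovery a meaningful check of the implementation —
and no more than that. Defaults: 60 proteins of 200–800 aa (uniform
residue usage), 100 patients, 1.5 modification sites per 100 residues
(about the 7.7 sites/protein of large curated PTM collections), rates drawn
from Gamma(1, 10) (mean 0.1 mutations per position, matching the pooled
per-position density of ~10⁶ mutations over ~13,000 proteins), 20 % of
proteins planted at R = 3, predictor call probabilities (0.8, 0.3) by
mutation class, a logit-scale conservation shift of 1, survival hazard
ratio 2 (baseline mean survival 1,000 days, independent exponential
censoring at mean 2,000 days), and a 50-protein/10-drug network built as a
random spanning tree plus extra edges so it is connected by construction.
Sites are forced to lysine after flank planting; each modification type
plants a weak flanking preference (probability 0.6 at offsets ±1, ±2) so
that clustering and width selection have signal to recover. Each generator
draws from its own stream (config seed + fixed offset), so stages are
independently reproducible.

What the generator does **not** emulate: codon-level mutation processes and
trinucleotide signatures, patient-level mutation-burden heterogeneity,
correlated domain placement (synthetic domains are independent of
mutations, so the domain bootstrap is null on synthetic data by
construction), realistic PPI topology, and any linkage between patients.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's assumptions, not performance on real cohorts.

## Problem sizes and numerical choices

Simulation studies in the tests and acceptance script use 100 count
configurations for sampler/oracle agreement, 500 proteins × 200 replicates
for false-discovery control, 200 full-test replicates for bootstrap and
log-rank calibration, and 20 random networks of ≤ 500 nodes for the solver
check — sizes at which the Monte-Carlo envelopes quoted with each check are
sharp while the whole study runs in well under a minute. Monte-Carlo
agreement between the sampler and the exact posterior is judged at three
binomial standard errors of 5,000 draws; distributional checks use KS at
the 1 % level. The Gibbs seed derives one child seed per protein from a
seed sequence, so per-protein results do not depend on table order.

## Known limitations

Only non-synonymous point mutations are modelled (no indels or
frameshifts), and the background model carries no covariates (replication
timing, expression); rarely mutated proteins have little power and wide
posterior R. The "modification" qualifier of the published k-means variant
is not reproduced anywhere in the available description; the standard
algorithm with the documented encoding and model-selection rule stands in
its place. The census-overlap worked example is reproducible only under a
chi-square reading of the published test (see above).
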