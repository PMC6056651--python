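# lysdriver

Somatic mutations that fall inside the recognition motifs of protein lysine
modifications (ubiquitination, acetylation, SUMOylation, glycation,
malonylation, methylation, succinylation) can disable the modification and
thereby alter protein function. `lysdriver` finds proteins whose lysine
modification motifs carry an unexpectedly high somatic mutation burden
across cancer cohorts, and runs the downstream analyses that characterize
those candidate drivers. It is written for computational cancer-genomics
analysts who have a table of modification sites and a MAF-like table of
non-synonymous SNVs (or who want to study the method itself on synthetic
data with known ground truth).

## The model

For one protein, split the residue positions into the merged modification
region (k positions, the union of per-site motif windows) and the background
(n − k positions). Per-position mutation counts are modelled as

    Y_i ~ Poisson(λ₁)   i = 1..k          (modification region)
    Y_i ~ Poisson(λ₂)   i = k+1..n        (background region)
    λ₁ ~ Gamma(α₁, β₁),  λ₂ ~ Gamma(α₂, β₂)

The quantity of interest is the relative mutation rate **R = λ₁/λ₂**, tested
as H₀: R ≤ 1 vs H₁: R > 1. Conjugacy gives closed-form full conditionals,

    λ₁ | Y ~ Gamma(ΣY_mod + α₁, k + β₁)
    λ₂ | Y ~ Gamma(ΣY_bg  + α₂, n − k + β₂)

which a Gibbs sampler draws for 5,200 iterations (200 burn-in); the
posterior p-value is the fraction of retained draws with R ≤ 1, corrected by
Benjamini–Hochberg within each (cancer type, modification type) stratum and
called a driver at q < 0.05. Because the two rates are a-posteriori
independent, the exact answer is also available in closed form,
P(λ₁ ≤ λ₂) = I_x(a₁, a₂) with x = b₁/(b₁+b₂) (regularized incomplete beta);
the package carries both routes and tests them against each other.

Downstream stages: motif construction (k-means consensus clustering of site
windows + PSSM width selection), a centered two-sample bootstrap comparing
per-kAA mutation rates in domain vs disorder regions, per-domain
hypergeometric enrichment, deleteriousness (five-predictor score, two-
proportion z-tests) and conservation (two-sample KS) comparisons, exact
hypergeometric driver-set enrichment, Kaplan–Meier/log-rank survival
comparison, and random-walk-with-restart prioritization of downstream
targets and drugs over a merged PPI + drug-target network.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(60 proteins, 100 patients, 20 % of proteins planted with R = 3):

```bash
python analysis/01_simulate.py       # writes results/synthetic/
python analysis/02_build_regions.py  # motif clustering + partitions
python analysis/03_map_mutations.py  # filter, dedup, count per position
python analysis/04_call_drivers.py   # Gibbs + BH driver calls
python analysis/05_domain_test.py    # centered bootstrap + per-domain test
python analysis/06_site_stats.py     # deleteriousness, conservation, census
python analysis/07_survival.py       # KM curves + log-rank
python analysis/08_network_rwr.py    # RWR targets and drugs
```

Typical output (seed 42):

```
partitioned 60 proteins; motif residues 1963/28806 (6.8%)
motif-region mutations: 267, background: 2450 over 60 proteins
tested 60 proteins; 17 drivers at q < 0.05
planted-driver recall: 0.58; realized FDR: 0.00
centered bootstrap: t_obs = -0.045, p = 0.969 (B = 1000)
score >= 3: 0.93 (modification-related) vs 0.16 (other), z = 28.5
conservation KS: D = 0.357, p = 2.01e-29
patients: 84 mutated vs 16 non-mutated
log-rank: chi-square = 5.18, p = 0.0229
```

Reading this: region construction recovers close to the planted 7.5 % motif
coverage; the Bayesian stage flags 17 drivers with zero false calls among
them (planted enrichment of moderate-rate proteins is found, very-low-rate
planted proteins are undetectable by design); the domain bootstrap is null
because synthetic domains are placed independently of mutations; the
predictor and conservation contrasts recover the planted class differences;
and patients carrying driver-motif mutations show the planted survival
disadvantage.

The same stages are importable from the `lysdriver` package (see
`lysdriver.pipeline.run_all`) or runnable via the `lysdriver` console
script (`simulate`, `run-all`, `call-drivers`, `rwr`).

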