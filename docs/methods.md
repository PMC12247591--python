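# Methods

## Problem and model

`connectopath` analyses structural brain connectomes represented as square
ROI-by-ROI matrices of tract counts (the output of deterministic diffusion
tractography on a cortical parcellation; the default emulated design uses 62
DKT regions, but every computation is size-agnostic). Edge *length* is the
reciprocal of tract count, so strongly connected regions are "close": for a
connectivity matrix `W`, the distance matrix is `d_ij = 1 / w_ij` (infinite
where `w_ij = 0`, zero on the diagonal).

All-pairs shortest paths `g_ij` are computed on the distance matrix with
Dijkstra's algorithm (binary heap, one run per source; only path lengths are
needed, so ties between equal-length paths are irrelevant). The global
measures are:

* **wCPL** (weighted characteristic path length): the arithmetic mean of
  `g_ij` over unordered node pairs. Disconnected pairs are excluded from the
  average and their count is reported, rather than making the metric
  infinite; this keeps wCPL finite on near-connected empirical networks
  while surfacing the exclusion for QC. A fully disconnected network is an
  error.
* **GE** (global efficiency): the mean of `1 / g_ij`, with disconnected
  pairs contributing 0 — GE handles disconnection natively. On a connected
  graph the AM–HM inequality forces `GE >= 1 / wCPL`, with equality exactly
  when all pairwise distances are equal; this is used as a test invariant.
* **CC** (clustering coefficient): the mean over nodes of the weighted
  clustering coefficient in the geometric-mean-of-triangle-weights form,
  with weights normalized by the global maximum weight (the standard
  toolbox convention; invariant under uniform rescaling of counts). Nodes
  with fewer than two neighbours contribute 0.
* **SWN** (small-worldness): by default the plain ratio `CC / wCPL`. Because
  that ratio is scale-dependent (it scales with the counts), a normalized
  variant is provided that divides CC and wCPL by their means over an
  ensemble of degree-preserving rewired null networks (double edge swaps on
  the binary topology; the original weight multiset is then permuted onto
  the rewired edges, so both the degree sequence and the weight distribution
  are preserved exactly).
* **log-SWN**: natural log of SWN, for the skew-reducing transform used in
  secondary analyses. Non-positive SWN is rejected before the log with a
  clear error.

Scaling laws (used as property tests): multiplying all counts by `c > 0`
multiplies wCPL by `1/c`, GE by `c`, leaves CC unchanged, and scales plain
SWN by `c`; adding tracts to any edge never lengthens a shortest path and
never decreases GE.

## Statistical battery

Group labels are ordered `control < exposed_noptsd < ptsd` (unexposed
controls, trauma-exposed without PTSD, PTSD).

* **Welch's t-test** with Welch–Satterthwaite degrees of freedom; the effect
  size is Cohen's d with the *pooled-SD* convention (the most common
  companion to Welch reporting; documented so users can compare variants).
* **One-way ANOVA** across the three groups.
* **Covariate-adjusted contrasts**: a Gaussian linear model
  `metric ~ group + covariates` with t-tests on pairwise group contrasts.
  Sex and education enter as indicator codes; constant covariate columns are
  dropped (logged), which also makes the model reduce exactly to the pooled
  t-test when covariates are degenerate. The default adjustment set is
  {age, sex, education, body mass}.
* **Trend test**: Cuzick's Wilcoxon-type non-parametric trend test across
  the ordered groups, with ordinal scores 0, 1, 2 and the tie-corrected null
  variance, referred to the standard normal.
* **Adjusted Spearman correlation**: both variables are rank-transformed,
  each rank vector is residualized on the covariates by least squares, and
  rho is the Pearson correlation of the residuals. The p-value uses
  `t = rho * sqrt((n - 2 - q) / (1 - rho^2))` with `q` adjusted-for
  covariate columns. This is the standard partial-Spearman construction;
  note that rank transformation means a covariate acting strongly and
  nonlinearly on the raw scale is only partially removed.
* **BH-FDR**: Benjamini–Hochberg step-up, applied within families — by
  default the five symptom-domain tests within each clinical subgroup
  column.
* **Standardized-beta OLS**: the outcome and all continuous predictors are
  z-scored (binary/dummy columns keep their scale); coefficients, t and p
  per predictor.
* **Distribution diagnostics**: sample skewness (g1) and kurtosis in *both*
  conventions — excess (g2) and Pearson (g2 + 3) — explicitly labelled,
  since published kurtosis values are frequently ambiguous between the two.
* **Outlier sensitivity**: remove the k highest-wCPL subjects *within the
  case group only* (default k = 3), re-run the case-vs-comparison contrasts,
  and report both results plus the exact count of subjects above a
  configurable reporting cutoff (default wCPL > 80).

### Discrimination (ROC)

AUC uses the Mann–Whitney construction (ties count 1/2); the 95% CI uses the
DeLong structural-components variance estimator, chosen because it is the
standard nonparametric interval for a single AUC. The combined score is an
in-sample logistic fit of case status on imaging features (wCPL, cortical
complexity) plus demographics (age, education, body mass); its *apparent*
AUC is reported and flagged as in-sample — no cross-validation or optimism
correction is performed, matching a single-cohort design, and the output
records this limitation. Perfect separation triggers a ridge-penalized
logistic fallback with a warning. The `ptsd_no_mdd` analyses exclude
comorbid-MDD subjects before labelling.

## Synthetic cohort generator

No imaging data ship with the package; the generator produces cohorts with
the statistical structure the analysis assumes so that every stage is
testable end to end.

**Wiring.** ROIs are placed uniformly on a unit sphere (one layout per
cohort seed). An edge between nodes at chord distance `d` exists with
probability `exp(-0.4 d)` (density ~0.6) and carries a log-normal weight
with log-mean `-3.8 - 0.1 d` and log-SD 0.4. The shallow distance decay of
edge *length* is deliberate: it puts direct long-range connections on
shortest paths, where the per-hop fixed cost makes rerouting around them
roughly twice as expensive — this is what gives the group-effect mechanism
(below) leverage over wCPL. A per-subject log-normal global scale (log-SD
0.40) multiplies all weights; since wCPL is inversely proportional to the
scale, the subject-level wCPL distribution is right-skewed (realized sample
skew ~0.8–1.2 at n = 109), and with the chosen log-mean the cohort median
wCPL sits near 58 with a tail of subjects above 80, mirroring the reporting
conventions of the emulated study design. Weights are on an arbitrary scale
(all metrics obey the exact scaling laws above, so only relative weights
matter).

**Group effect.** PTSD subjects have weights on *long-range* node pairs
(above-median inter-node distance) multiplied by `1 / (1 + a)`. Attenuating
long edges is the minimal mechanism that raises wCPL without changing node
count or density. The response of the realized Cohen's d (PTSD vs exposed
wCPL, pooled SD) to `a` is monotone and saturates near d ~0.52 once all
affected pairs have rerouted; `calibrate_attenuation` maps a target d onto
`a` by bisection with common random numbers across knob values (default 16
replicate cohorts per evaluation, tolerance 0.05). The default `a = 0.9`
corresponds to d ~0.42 under the default 53-vs-47 design. Unexposed controls
and exposed non-PTSD subjects share the baseline wiring — the generator does
not emulate an exposure-severity gradient below the diagnosis threshold.

**Covariates and symptoms.** Age, BMI, sex, education, dementia status and
cortical complexity are drawn per group from configurable distributions
(defaults follow the emulated three-group design, e.g. younger and more
often female controls, higher BMI and dementia rate in cases; cortical
complexity is shifted +0.6 SD in cases and drawn independently of wCPL, so
it discriminates at AUC ~0.66 while being uncorrelated with wCPL). The PCL
eligibility score is truncated-normal per group (cases > 40, non-cases
< 30); an eligibility filter re-checks the bounds after generation and
removes violators with a log message (a no-op under the defaults). Symptom
domain scores (re-experiencing, avoidance, hyperarousal, negative affect,
overall severity) are produced by a Gaussian copula on the *realized* wCPL
ranks within three disjoint clinical cells — non-PTSD, PTSD without MDD,
PTSD with MDD — using the latent-correlation inversion
`rho_latent = 2 sin(pi * rho_s / 6)` so the configured Spearman targets are
hit (within ±0.1 at n >= 200) while per-group marginal means/SDs are
preserved. Default targets are positive in the non-PTSD cell and
increasingly negative in the PTSD and PTSD+MDD cells; because the analysis
subgroups (all-no-MDD, all-PTSD) overlap the generation cells, realized
subgroup correlations reproduce the qualitative sign pattern rather than the
cell targets exactly.

**Reproducibility.** Every draw descends from the single cohort seed through
counter-keyed per-subject substreams, so a cohort is byte-identical across
runs and subsetting a cohort leaves the remaining subjects' data unchanged.

**What the generator does not emulate.** Anatomical DKT geometry, tractography
error structure, integer counts, the exposure-related wCPL elevation in the
PTSD-negative group, and metric side effects: attenuating long-range weights
also moves CC, GE and SWN in the synthetic cohorts, more strongly than a real
cohort might show. Passing tests therefore demonstrate that the *pipeline*
recovers what the generator injects — not that real cohorts behave this way.

## Numerical choices and problem sizes

* Matrix validation symmetrizes asymmetries up to a relative tolerance
  (default 1e-6, arithmetic mean) and zeroes the diagonal, both logged;
  larger asymmetries, negative entries, non-square tables and n < 2 are
  distinct errors naming the offending cells.
* Listwise behavior is visible: every result row carries the n actually
  used.
* Degenerate inputs are rejected with explicit errors rather than coerced:
  all-tied trend metric, constant vectors in correlations/diagnostics,
  rank-deficient designs, single-class ROC labels (all-tied scores return
  AUC 0.5 with a warning).
* Test suite problem sizes: shortest-path oracle checks use 200 random
  graphs with up to 12 nodes against a triple-loop Floyd–Warshall; type-I
  error calibration uses 2000 null replicates per test at n = 50–60; FDR
  control uses 5000 replicates of 10 mixed tests; DeLong coverage uses 1000
  replicates at 50 + 50; effect-size recovery uses 48-replicate calibration
  (bisection tolerance 0.03) plus 50 (recovery) / 200 (null) fresh
  validation cohorts of n = 100.
  These sizes keep Monte-Carlo error well inside the asserted bands.

## Known limitations

* Only global metrics are computed; nodal/edge-level statistics, modularity
  and rich-club analyses are out of scope by design.
* The harmonic-mean variant of characteristic path length is not provided;
  wCPL is the arithmetic mean over connected pairs.
* The partial-Spearman p-value is a t-approximation; its finite-sample size
  is verified by simulation (within [0.03, 0.07] at alpha = 0.05) but it is
  not exact.
* Combined-score AUCs are apparent (in-sample) and optimistically biased;
  the tables flag them as such.
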