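# Methods

`planktonet` delineates an interconnected "core microbiota" from decade-long
monthly amplicon time series. The pipeline runs five stages: count-table
preprocessing, season/niche annotation, local similarity analysis (LSA),
removal of environmentally driven edges, and core-network analysis. A
synthetic-community generator with planted ground truth provides the data the
test suite and the reproduction script use. This note documents the models,
the numerical choices, and what the synthetic experiments do and do not show.

## Synthetic communities

The generator emulates a coastal microbial observatory sampled monthly for
ten years (120 samples) at 41.67 N: two organismal size fractions
(picoplankton 0.2–3 µm, nanoplankton 3–20 µm) sequenced separately for
bacteria and protists (four count tables), a fixed rarefied depth of 4907
reads per sample, and a nanoplankton gap of 27 consecutive months plus two
isolated months (configurable; an empty mapping disables gaps).

* **Environment.** Photoperiod is deterministic, from the CBM day-length
  model evaluated on day 15 of each month. Temperature is an annual sinusoid
  (mean 18.2 °C, amplitude 5.5 °C, August peak) plus seeded AR(1) noise.
  Thirteen further variables (nutrients, chlorophyll, salinity, plankton
  stocks, …) are seasonal sinusoids or red noise with magnitudes typical of a
  Mediterranean coastal station, for 15 contextual variables in total.
* **Seasonal OTUs** (fraction 0.5 by default) follow a Gaussian bump over
  circular month-of-year distance (sd 1.2 months) around one season's peak
  month, on a 5% baseline, with log-normal amplitude across OTUs.
* **Direct pairs** share a smooth latent AR(1) driver independent of every
  environmental variable: member abundance is `exp(coupling * z)` times
  log-normal noise (`noise_sd`, default 0.25; coupling 1.2). A small fraction
  (5%) couples with opposite sign.
* **Environmentally driven pairs** are driven the same way by the *z*-scored
  value of a shared environmental variable, with independent member noise and
  no other shared driver, so the pair is conditionally independent given the
  variable — unambiguous ground truth for the indirect-edge stage.
* **Counts** are multinomial draws per sample at the fixed read depth, so
  every column sums exactly to the depth.

Defaults were fixed once: 40 OTUs per table (160 total; the emulated study
had thousands, which is not a desk-scale experiment), 20 direct and 20
environmentally driven pairs, seasonal fraction 0.5, noise 0.25. The
generator reproduces the *statistical structure* the pipeline assumes —
seasonality, compositional sampling, planted dependence — not the taxonomic
richness, rank-abundance tail, zero inflation, or autocorrelated bloom
dynamics of real metabarcoding data. Recovery results on it bound what the
method can do under favorable, known conditions; they are not estimates of
performance on field data.

## Preprocessing

Order of operations: rarefaction → prevalence filter → seasonal imputation →
size-fraction ratio rule → month-normalized relative abundance → resident
selection.

* **Rarefaction** subsamples each sample without replacement (multivariate
  hypergeometric) to the configured depth (default 4907); a shallower sample
  is an error naming the sample.
* **Prevalence filter** keeps OTUs present in at least 10% of a table's
  samples (`ceil(0.10 × n)`).
* **Imputation** fills missing months per OTU series: subtract per-calendar-
  month means (from observed values), fill residuals with a linearly weighted
  moving average (window 2 on each side, widened until an observed neighbour
  exists), add the means back. Observed values are never changed; a calendar
  month with no observation in any year is an error.
* **Size-fraction rule**: for an OTU with reads in both fractions, if the
  total-read ratio strictly exceeds 2:1 the OTU is zeroed out of the minority
  fraction. The ratio uses totals over all samples, so an OTU is never
  removed from both fractions.
* **Relative abundance** is normalized within calendar-month groups: each
  sample is divided by the grand total of its calendar month across the ten
  years, both domains and both fractions, so each month's values sum to 1
  over years and OTUs.
* **Residents** are OTUs present (value > 0, counted on the post-imputation
  series) in at least 36 of 120 months, inclusive; a whitelist can force
  membership for OTUs whose occurrence straddles the imputation.

## Seasons, indicator values, niches

Months are labelled hydrographically: summer = temperature > 17 °C and
photoperiod > 14 h; winter = < 17 °C and < 11 h; autumn = warm/short days;
spring = cool/days > 11 h. Exact boundary values are undefined by these
rules and raise unless the `closed-lower` tie-break is enabled (boundary
counts with the upper region); the pipeline enables it because simulated
temperatures can land arbitrarily close to the split.

The indicator value of OTU *i* for season *j* is `IndVal = A × B × 100`,
where A is mean abundance in *j* over the sum of per-season means and B the
within-season occurrence fraction. Significance is a label-permutation test
on the season maximum with `(r+1)/(n+1)` smoothing (999 permutations by
default). Niche preference is the abundance-weighted mean of an
environmental variable against the null obtained by permuting abundances
across samples (1000 permutations); confidence limits are the 2.5/97.5
percentiles and the classification is `above`/`below` only outside them.
By construction this null detects only niches at the gradient extremes
(warm/cold, long/short days); intermediate (spring/autumn) optima do not
depart from the randomization mean.

## Local similarity analysis

Series are normalized (default: rank-normal scores, i.e. ranks through the
standard normal quantile; robust median/MAD and classical z-scores are
available) and scored with the LS dynamic program: the maximal contiguous
subinterval sum of elementwise products, positive or negative, divided by
the full series length, optionally over bounded alignment delays (default
0 — monthly sampling makes contemporaneous association the target). Ties
prefer smaller |delay|, then earlier start.

The default normalization is rank-normal rather than median/MAD because LS
thresholds such as |LS| > 0.7 presume unit-scale scores: on skewed
abundance series the MAD score has essentially unbounded variance (a single
bloom month can map to a score of ~100), which both inflates LS far beyond
1 and, once the null variance is accounted for, destroys the power of the
theoretical screen. Rank-normal scores give unit variance for any input
shape and make LS invariant to monotone transforms, matching the Spearman
filter applied alongside.

**Theoretical p-value.** Under independence, √n·LS converges to the maximal
segment sum of a mean-zero random walk, which by Lévy's identity has the
law of sup|W(t)| on [0,1]; the classical theta-series CDF gives the tail.
The statistic is standardized by the product of the two series' variances.
Monte-Carlo calibration (10 000 independent pairs, n = 120) shows the
one-sided tail matches the null: p ≈ 0.037–0.040 at the true 5% quantile
and near-exact agreement deep in the tail, which is the regime the screen
and Bonferroni cuts use.

**Mixed testing.** A permutation test (default 1000 permutations of one
series, seeded, `(r+1)/(n+1)`) runs only for pairs whose theoretical p is
below the screening level (0.05); other pairs keep the theoretical p. A
permutation p is floored at 1/(n_perm+1), so a saturated test (zero
exceedances) cannot by itself reach a Bonferroni-adjusted p below 0.001
once thousands of pairs are tested; in that case the reported p is
`min(p_theory, 1/(n_perm+1))` — the permutation test certifies significance
at its resolution and the calibrated theoretical tail refines below it.
Bonferroni uses the total number of evaluated pairs (all OTU–OTU plus
OTU–environment pairs). Spearman's ρ (average ranks) is computed on the raw
series. Series that cannot be normalized (zero dispersion) are dropped and
recorded.

## Environmentally driven edges

Edges entering this stage are associations with mixed p < 0.05
(unadjusted; configurable) — the "initial network". For every OTU–OTU edge
whose endpoints both hold an edge to the same environmental variable, a
triplet (A, B, E) is scored with four criteria:

1. **Sign pattern**: sign(AB) = sign(AE)·sign(BE).
2. **Overlap**: the triple intersection of the three LSA alignment
   intervals covers ≥ 60% of the A–B interval (configurable).
3. **Interaction information**: II = MI(A;B|E) − MI(A;B) in bits, plug-in
   estimates on equal-frequency bins (⌈1+log₂ n⌉ bins, 8 at n = 120);
   significantly negative II (permuting E, 200 permutations, α = 0.05)
   indicates redundancy. The permutation p is computed only when the other
   three criteria and II < 0 leave removal possible; other triplets report
   II with p = NaN, which cannot change any removal decision.
4. **Data processing inequality**: MI(A;B) ≤ min(MI(A;E), MI(B;E)), the
   ordering implied by the Markov chain A–E–B.

An edge is removed only when all four criteria agree for at least one
environmental variable; OTU–environment edges are never removed. In the
near-deterministic limit (member noise → 0) all three MI values coincide
and the plug-in DPI comparison flips by estimation noise, so the recovery
experiment for this stage uses the generator's default member noise (0.25)
with strong coupling, where the Markov margin is real; the low-noise
configuration is used for the direct-pair recall experiment, where it is
the relevant stress case.

## Core network and its characterization

Core edges satisfy |LS| > 0.7, Spearman |ρ| > 0.7 and Bonferroni-adjusted
p < 0.001 (all configurable); core OTUs are exactly the OTUs incident to
surviving edges. Statistics mirror standard network tables: density,
diameter and average path length on the largest component, mean local
clustering (degree < 2 contributes 0), exact maximal-clique enumeration,
and edge-betweenness (Girvan–Newman) modularity — the partition along the
removal dendrogram (including the trivial connected-components partition)
that maximizes Newman–Girvan Q. Girvan–Newman only explores its own
dendrogram, so Q can fall short of the global partition optimum (it never
exceeds it); because the procedure is quadratic in edges the pipeline
computes it only for networks up to 600 edges (configurable) and reports
NaN above.

Betweenness and closeness are computed and normalized *within each
connected component* (the convention of interactive network tools): the
center of a 3-node path component scores 1.0 on both regardless of the
rest of the graph. Hubs are nodes with degree ≥ 24, betweenness ≥ 0.03 and
closeness ≥ 0.3; connectors (exclusive of hubs) have degree ≤ 5,
betweenness ≥ 0.03 and closeness ≥ 0.2. All bounds are closed so that
values printed at two decimals on a threshold satisfy their rule.

Random baselines are edge-matched: Erdős–Rényi G(n, m) exactly;
Watts–Strogatz from the nearest even ring degree with rewiring probability
0.05, then randomly adjusted to the exact edge count; Barabási–Albert with
the attachment parameter minimizing |m(n−m) − target| (for 262 nodes and
1411 edges the closest achievable count is ~9% off — the price of the
model's form). MCODE-style modules use vertex weights = (highest k-core of
the closed neighbourhood: k × core density), greedy expansion admitting
neighbours with weight ≥ 0.8 × seed weight (vwp 0.2), and a haircut to the
2-core; the module score is density × size and "main modules" score > 4.
Note the greedy expansion merges two 5-cliques joined by a single bridge
into one module of ten (all vertices weigh 4, so the bridge endpoint is
admitted); module detection is deliberately not a partition method.

## Problem sizes and runtime

The shipped experiments are sized for a laptop-class single core: recovery
runs use 160 OTUs × 120 months per seed (five seeds per experiment, about
half a minute each), calibration uses 2000 independent pairs, the oracle
check 1000 pairs, and the ER baseline 20 realizations. The permutation
inner loops are JIT-compiled when numba is importable and fall back to
vectorized numpy otherwise, with identical results.

## Known limitations

* The permutation and theoretical p-values assume exchangeable samples;
  monthly autocorrelation makes the test anti-conservative on strongly
  autocorrelated seasonal series. The stringent Bonferroni/effect-size cuts
  absorb much of this, but p-values near the threshold should not be read
  literally for seasonal OTUs.
* Plug-in MI on 8 bins at n = 120 carries substantial bias; it cancels in
  the II permutation test but not in the DPI comparison, which remains the
  least reliable of the four criteria near determinism.
* The niche null model cannot detect mid-gradient optima; this is a
  property of the randomization, not a bug.
* Recovery rates are measured on synthetic communities with planted,
  fairly strong effects; they are upper bounds, not field performance.
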