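# Methods

This note documents the models implemented in `littersuccession`, the
assumptions behind them, the synthetic data the test suite runs them on,
and the numerical choices that matter when reproducing results.

## Source tracking: convex-mixture EM

**Model.** A sink (litter) community with counts `y` over `N` taxa is
multinomial with probabilities `p_i = Σ_k α_k γ_ki + α_u γ_ui`, where
`γ_k` are the named source habitat profiles, `γ_u` a free "unknown"
profile, and `α` lies on the (K+1)-simplex. The log-likelihood up to a
constant is `Σ_i y_i log p_i`.

**Estimation.** EM with responsibilities
`r_ik = α_k γ_ki / p_i`; the M-step sets `α_k ∝ Σ_i y_i r_ik` and
re-estimates only `γ_u ∝ y_i r_iu`. The named source profiles are held
fixed at their empirical frequencies (habitat samples summed, smoothed
with pseudocount 1e-8 per taxon, renormalized). Holding them fixed is a
deliberate simplification of full joint re-estimation: a fully free
unknown component can explain any sink perfectly (the global optimum is
always `α_u = 1, γ_u = y/Σy`), so the estimator's sanity rests on the
unknown starting small and growing only where the sources genuinely fail.

**Initialization.** One non-negative least-squares pass fits the sink
frequencies with the source profiles; the positive residual (floored at
the pseudocount, normalized) seeds `γ_u`, and the residual mass — clipped
to `[1e-4, 1/(K+1)]` — seeds `α_u`, the named sources sharing the rest
evenly. The lower clip keeps `α_u` away from the absorbing state at zero;
the residual-based start keeps the unknown off the likelihood ridge it
would occupy if initialized uniform (on that ridge EM is stationary and
mixtures with redundant components are unidentifiable; near-identical
source profiles, cosine similarity > 0.999, are additionally flagged).

**Convergence.** Relative log-likelihood change below `tol = 1e-6`
(default), `max_iter = 1000`. The trace is recorded and is non-decreasing
by EM construction; tests assert it. Estimates are invariant to taxon
permutation and sink scaling. Rarefaction before fitting uses exact
multivariate hypergeometric subsampling at the minimum total across the
sink and its sources (configurable), seeded. Sinks are paired only with
sources from the same altitude group, since communities from different
altitudes cannot directly exchange colonists; samples without altitude
fall into one shared group.

## Diversity statistics

* **Shannon** uses log base 2 by default (the common amplicon-pipeline
  convention), base e optionally.
* **Unweighted UniFrac** is (branch length unique to one community) /
  (branch length subtending either community); branches subtending
  neither are excluded. The implementation precomputes, per branch, the
  boolean set of subtended tips; a brute-force re-enumeration serves as
  the test oracle (agreement to 1e-12 on random trees).
* **PCoA** double-centers `−½ D²` and reports *all* eigenvalues,
  negatives included, with no Cailliez/Lingoes correction; coordinates
  use positive-eigenvalue axes only and proportions are over the positive
  eigenvalue mass.
* **PERMANOVA** uses Anderson's pseudo-F from total vs within-group sums
  of squared distances. Permutation p-values use the
  `(1 + count)/(1 + n_perm)` estimator (never zero); an exhaustive mode
  enumerates all `n!` label permutations (identity included,
  `p = #{F ≥ F_obs}/n!`) and is feasible to `n ≈ 8`. Pairwise tables are
  Benjamini–Hochberg adjusted by default (bonferroni/none optional).
  Type-I error is calibrated in the test suite: 200 null simulations at
  `n = 20`, 999 permutations, nominal 0.05.
* **Kruskal–Wallis** wraps the rank/tie-corrected statistic with an
  explicit guard: all-identical values return `(H = 0, p = 1)`.
* **Mantel** correlates upper triangles (Pearson) with p from row/column
  permutations of the second matrix, one-sided "greater" by default.
  Constant matrices are flagged (`nan`) rather than raising.

## Co-occurrence network and keystones

The network keeps the `top_n = 400` most abundant ASVs (ties broken by
id) and connects pairs with |Spearman r| strictly above 0.8 and
two-sided p (t-approximation) strictly below 0.01 — both raw, as
thresholding precedes any multiplicity consideration in this design;
Pearson is available. Isolated nodes stay in the node set.

Centralities: degree, unnormalized shortest-path betweenness, and
*harmonic* closeness (sum of reciprocal distances). Harmonic closeness is
the deliberate choice because leave-one-out removal can disconnect the
graph, where classic closeness is undefined. The impact score of node v
is the sum of absolute changes of the three *mean* centralities (means
over nodes present in each graph) between the full network and the
network without v — the three terms are summed without rescaling despite
their different units, so betweenness dominates on large dense graphs;
that is the documented definition, and scores are only compared within
one network. Keystones are the top `ceil(0.10 n)` scores, ties broken by
higher degree then id (deterministic and order-invariant). Origin labels
come from detection (total count ≥ 1) in the phyllosphere and soil
tables: only-phyllosphere / only-soil / both / unknown. Pianka's overlap
treats litter samples as resource states and each group's normalized
summed relative abundance as its utilization distribution; Levins'
asymmetric variant is available.

## Assembly processes: binned βNTI / RC_bray

Taxa are partitioned into phylogenetic bins by a transparent greedy rule:
visit taxa in lexicographic order, placing each into the first bin whose
members are all within patristic distance `ds = 0.2`, else opening a new
bin; bins below `min_bin_size = 24` are merged, smallest first, into the
bin at smallest mean patristic distance (ties by lexicographically
smallest member). This keeps the published framework's bin concept while
replacing its full bin optimization with a rule simple enough to verify
against an independent re-implementation, which the tests do.

Per bin and sample pair, βMNTD is the abundance-weighted mean distance of
each present taxon to its nearest taxon present in the other community
(self-matches count at distance 0); βNTI is its z-score against
`n_null = 999` within-bin tip-label shuffles. Null permutations are drawn
once per bin and reused across sample pairs — the null model is
unchanged, the run time drops from quadratic to linear in samples. A null
standard deviation below 1e-12 (e.g. equidistant star trees) yields `nan`
rather than ±∞, and pairs with fewer than two present taxa in either
community are recorded as missing. RC_bray compares observed within-bin
Bray–Curtis to nulls that preserve each sample's bin-level richness and
total abundance, drawing presence via Gumbel top-k with probability
proportional to the regional pool and abundances as one read per present
taxon plus a multinomial over pool weights; `RC = 2·frac(null ≤ obs) − 1`
with ties counted half, so RC ∈ [−1, 1]. Classification:
βNTI < −2 HoS, > +2 HeS; else RC > 0.95 DL, < −0.95 HD, else DR.
Per-pair bin weights are the mean relative bin abundance of the two
samples; weights renormalize over classified bins, so process fractions
sum to 1 exactly.

## Synthetic data: what it emulates, and what it does not

* **Sources/sinks.** Source habitats get symmetric-Dirichlet composition
  vectors (concentration 0.3 — strongly uneven, as in real ASV tables);
  samples are multinomial draws at depth 20 000 by default. Sinks are
  multinomial draws from an exact convex mixture of the source
  compositions plus an unknown Dirichlet profile — the source-tracking
  model is correctly specified by construction, which makes parameter
  recovery a well-posed oracle. Recovery is tested at 3 sources,
  200 taxa, depth 5×10⁴, true α = (0.5, 0.3, 0.15, 0.05), 20 replicates
  (median L∞ error ≈ 0.013 ≤ 0.05).
* **Trees.** Random bifurcating topology (uniform random joins) with
  i.i.d. exponential branch lengths, rate 1.
* **Correlated blocks.** A Gaussian-copula latent factor: block members
  mix a shared factor with idiosyncratic noise at the loading that yields
  the requested Spearman correlation (`r_latent = 2 sin(π ρ_s / 6)`);
  counts are the rounded exponential of the latent log-abundance, a
  monotone map that preserves ranks. Off-block taxa are independent.
* **Assembly regimes.** *Neutral*: uniform random leaf subsets with
  lognormal abundances. *Filtering*: a niche trait evolves on the tree by
  a Brownian walk with conservatism below the 10% quantile of tip-tip
  patristic distances — clades tighter than that inherit one niche value,
  reflecting the niche conservatism marker-gene ecology assumes. (A pure
  tip-level Brownian walk carries χ²₁ noise on every trait contrast, so
  taxa selected by a shared optimum end up phylogenetically scattered and
  no nearest-taxon statistic can see the selection at these problem
  sizes.) All communities share one optimum, placed where the regional
  trait distribution is densest; the Gaussian kernel width is set by
  bisection so the effective selected pool (inverse Simpson of the
  selection weights) is 1.6× community richness — strong selection with
  taxon turnover between samples. Membership follows the kernel weights;
  abundance is the squared kernel weight times lognormal noise (σ = 0.1).
* **Not emulated:** sequencing error and chimeras, compositional biases,
  read-length effects, taxonomy, spatial structure, time series, and any
  interaction between stages (each generator targets the statistical
  structure one stage assumes). Passing recovery tests therefore shows
  the estimators work when their model holds — not that the model holds
  for any particular field data set.

**Regime recovery granularity.** The neutral/filtering recovery checks run
the classifier at whole-community granularity (a single bin — the
classical whole-community βNTI/RC analysis): at 200 taxa a default-width
bin holds ~10 present taxa per community and the βNTI null z-score is
variance-limited to |z| ≈ 1.5, below the |2| decision cut, for any
single-trait filtering scenario we constructed; at whole-community
granularity the same scenarios are recovered cleanly (HoS fraction
0.89–1.0, neutral |βNTI| ≤ 2 fraction 0.89–0.97 across seeds). The binned
machinery itself is verified by exact oracles (greedy-rule
re-implementation, naive βMNTD double loop, RC tie handling).

## Problem sizes and runtime

The default test suite and the acceptance script use: source-tracking
recovery at 200 taxa × depth 5×10⁴ × 20 replicates; UniFrac oracle on 100
random 10-leaf instances; PERMANOVA calibration with 200 null simulations
× 999 permutations at n = 20; leave-one-out oracle on 20 random 30-node
graphs; assembly regimes at 200 taxa, 20 communities of 50, 999 nulls;
and a 60-taxon demo pipeline run twice for byte-identity. The whole suite
runs in about a minute on one CPU.

## Reproducibility

One integer seed drives everything: stage seeds are derived as named
substreams (`SeedSequence(seed, spawn_key=crc32(label))`), so adding or
reordering stages does not perturb the randomness of the others. Pipeline
reruns with the same config and seed are byte-identical except
`manifest.json`, which records wall-clock stage timings.

## Known limitations

* The EM source tracker fixes named source profiles; source-sample
  noise is not propagated, so contributions on very shallow sources are
  over-confident.
* The greedy binning is order-deterministic but not optimal; bins near
  the `ds` boundary depend on lexicographic visit order.
* The leave-one-out impact sums unscaled centrality changes; a z-scored
  variant would change keystone identity on graphs where one centrality
  dominates numerically.
* RC_bray nulls are multinomial given presence; field data are usually
  overdispersed relative to that null, biasing RC toward +1 (dispersal
  limitation) when abundance noise is strong.
* Exhaustive PERMANOVA is factorial in n and practical only for n ≤ 8.
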