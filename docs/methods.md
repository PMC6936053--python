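# Methods

## Model and assumptions

`coexnet` treats a genes × samples expression matrix as draws from an
unknown joint distribution over genes and asks which gene pairs are
dependent. Two estimators are used, deliberately redundant for linear
dependence and complementary beyond it:

- **Pearson correlation** captures linear dependence. The package keeps
  the magnitude |r| by default (configurable with `absolute=False`):
  positively and negatively co-regulated genes are treated alike, which
  matches the biology (a repressed target is as co-expressed as an
  activated one) and puts the matrix on [0, 1].
- **Mutual information** captures arbitrary dependence. Profiles are
  discretized per gene and MI is the plug-in estimate
  H(X) + H(Y) − H(X,Y) from empirical code frequencies. MI(X,X) = H(X)
  holds exactly; all values are clipped at 0 (the plug-in identity can go
  negative only by float error).

The network is the OR-rule adjacency: edge iff PCC > t_pcc or MI > t_mi,
strict inequalities, no self-loops. The OR-rule makes the hybrid edge set
a superset of either single-measure network at the same cutoffs, so adding
MI can only rescue edges, never remove them.

Assumptions worth stating: samples are treated as exchangeable
(no batch/covariate modelling); association is estimated marginally per
pair (no conditioning, so indirect dependencies stay in the network); and
thresholding assumes the sorted association curve separates a small head
of true associations from a large background bulk.

## Discretization

Default: equal-width bins over each gene's observed range with
B = ⌈√n_samples⌉, the common square-root heuristic for histogram-based MI
estimators; the maximum value is assigned to the last bin. An
equal-frequency scheme is available (codes ⌊rank·B/n⌋ from the stable
rank, so ties break by sample order and bins stay balanced). Constant
genes get a single code; under equal-frequency this is warned, since
balanced bins are then impossible. The plug-in MI estimator is biased
upward at finite n (≈ (B−1)²/2n nats for independent pairs); no bias
correction is applied because thresholds are selected *on the same scale*,
so the bias shifts signal and background together.

## Threshold selection

All p(p−1)/2 off-diagonal values of one association matrix are sorted in
descending order. On data with planted or real co-expression structure
the curve shows a head of strong pairs, a plunge, and a long flat bulk.
The selector:

1. keeps the top `head_fraction` of values (default 0.02, floored at
   3·`smooth_window` values so the moving average is defined);
2. smooths with a centered moving average (`smooth_window` = 51);
3. takes discrete second differences of the smoothed curve; differences
   smaller than `curvature_tol` (= 0.05) × the largest magnitude count as
   zero curvature, so float-level wiggles on straight stretches are not
   inflections;
4. finds the **dominant knee** — the rank with the largest positive
   second difference, i.e. the sharpest leveling-off — and reports the
   inflection that opens it: the first rank of the contiguous run of
   significantly positive curvature containing that knee;
5. **snaps to the drop foot**: a centered moving average delays knee
   detection by up to half a window when the raw curve falls off a cliff
   (a near-discontinuous drop between the last strong pair and the top of
   the bulk). The rank therefore walks back up, within one window, to the
   value just below the nearest raw one-rank step exceeding `snap_factor`
   (= 5) × the head's mean per-rank step. On smooth curves no such step
   exists and the detected rank is kept.

The reported threshold is always an actually observed value, never an
interpolation. On a 1,000-point descending sigmoid with its analytic
inflection at rank 500 the selector returns rank 502; on a straight ramp
there is no significant curvature and the selector falls back to the
observed value at the `fallback_quantile` (default 0.99) upper quantile,
with a warning and `fallback_used=True`.

Design note: an earlier variant that scanned for the *first* second-
difference sign change from the top of the curve proved unusable on
curves whose head contains plateaus of near-tied strong pairs (hundreds of
within-module pairs at almost the same association): curvature noise
inside the plateau then masquerades as the knee and the cutoff lands far
above the signal-to-background transition, severing exactly the
moderate-MI nonlinear edges the hybrid rule exists to keep. Anchoring at
the dominant knee makes the choice scale-aware and, on generator-style
data, lands t_pcc at the top of the background bulk and t_mi just above
the MI background. Both parameters, and manual overrides `t_pcc`/`t_mi`
that bypass selection entirely (needed to reproduce runs whose original
cutoffs are known), are exposed in the library, pipeline config and CLI.

## Modules and node scoring

Modules are connected components with at least `min_module_size` nodes
(default 15, in line with common co-expression practice where minimum
module sizes of 15–30 keep centrality and enrichment meaningful; smaller
components — including the half-module fragments a single-measure network
carves out of a nonlinear module — carry too few paths for betweenness to
discriminate). Components are reported largest-first with deterministic
tie-breaks.

Each retained gene is scored W = D × B with D the raw incident-edge count
and B the betweenness centrality: the fraction of pairwise shortest paths
passing through the gene, computed and normalized *within its component*
by (n_c−1)(n_c−2)/2. Per-component normalization keeps B in [0, 1] and
comparable across modules; normalizing by the whole graph would deflate
every value in a multi-component network. Components of ≤ 2 nodes have
B = 0. Ranking is global across modules, descending W, ties broken by
higher degree then lexicographic gene id, so output is byte-reproducible.
The multiplicative combination means a gene needs both local connectivity
and a bridging position to rank highly; leaves (B = 0) always score 0.

## Integration and missing values

Cohorts are merged by gene intersection (order of the first input, or
sorted on request), sample concatenation in input order, and removal of
every gene with a missing value in any retained sample — the merged
matrix is complete by construction and the feature count drops below the
per-cohort gene count, which is the behaviour expected of multi-cohort
tumour integrations. Sample-id collisions are disambiguated by prefixing
the dataset label. Gene identifiers are matched as exact strings; symbol
or alias resolution is out of scope.

## Enrichment

One-sided hypergeometric over-representation per (module, gene set), sets
intersected with the background first (default background: all genes of
the integrated matrix, not only network nodes — the network is a
selection event and conditioning on it would bias p-values). BH FDR is
adjusted across the sets tested for one module; results sort by p-value.
Under a null of random modules the p < 0.05 rate is nominal within
binomial error once set and module sizes are large enough that the
discrete p-value support is fine near 0.05.

## Synthetic data generator

`generate_expression` emulates the structure the hybrid rule assumes:

- linear modules: one standard-normal latent factor per module; member
  g = sign_g · factor + N(0, noise_sd²), signs random, so absolute
  correlation is exercised. Population |r| between members is
  1/(1 + noise_sd²).
- nonlinear modules: latent u ~ Uniform(−1, 1); half the members follow
  u + noise, half u² + noise (or cos(πu), configurable). Cross-half pairs
  have population Pearson correlation exactly 0 by symmetry yet high MI —
  the cleanest case in which MI supplements correlation.
- background genes: independent N(0, 1).

Everything is reproducible bit-for-bit from the seed. Defaults for the
recovery benchmark used by the tests and the acceptance script: 300 genes
× 300 samples, three linear modules and one nonlinear module of 20 genes,
noise_sd 0.2, seed 42 — sizes at which every stage (including all-pairs
MI) runs in seconds on one CPU while the signal/background geometry of
the sorted curves is realistic enough to exercise knee selection.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial mean–variance coupling), batch effects, correlated backgrounds,
sample imbalance across cohorts, or gene-length/library-size artefacts.
Passing the recovery tests therefore demonstrates the pipeline's logic
(measure complementarity, thresholding, module extraction, scoring), not
robustness to those real-data phenomena.

## Numerical choices and degenerate inputs

- Zero-variance genes: correlations set to 0 (undefined otherwise),
  diagonal forced to 1, genes listed in `params["zero_variance_genes"]`
  and warned — never dropped silently.
- Symmetry is enforced to machine precision by averaging with the
  transpose after `corrcoef`.
- TSV outputs use 6 significant digits for human-facing tables and 17
  (`%.17g`, exact for doubles) for stage-chaining artifacts; re-reading
  uses round-trip float parsing so a network stage rerun from saved
  association matrices reproduces the single-shot run exactly.
- Empty networks (thresholds above every value) are valid: zero modules,
  empty score tables, clean exit.

## Known limitations

- Plug-in MI bias is not corrected; comparisons across different n or B
  are not meaningful without recalibration.
- Knee selection assumes a head-plunge-bulk geometry; on curves without a
  knee the quantile fallback is a blunt instrument and is clearly flagged.
- Connected components are a coarse module definition: one spurious
  inter-module edge merges two modules. The strict thresholds make this
  rare but the failure mode is abrupt.
- Betweenness is exact (Brandes) but O(V·E) per component; the intended
  scale is the retained subnetwork (hundreds of nodes), not the full gene
  set.
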