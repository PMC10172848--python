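# Methods

This note documents the models, conventions and numerical choices behind
`migrascape`, in the order data flows through the pipeline.

## Problem setting

Genetic migration in a region can be summarized as a *migration surface*: a
per-deme rate field on a lattice of local subpopulations, estimated from how
often pairs of individuals share identity-by-descent (IBD) genomic segments.
`migrascape` asks the downstream question: **which environmental and
cultural variables predict that surface?**  It prepares the IBD inputs the
effective-migration MCMC software expects, ingests that software's output,
assembles a per-deme table of landscape predictors, and regresses the log
migration rate on those predictors with a tuned random forest.

## IBD segments and time stratification

Segments are read from the 8-column tab-delimited output of hap-ibd.
Segments shorter than 2 cM are discarded (high false-discovery rate below
that length), and within-individual (homozygosity) segments are rejected at
parse time.  The default length bins are half-open intervals [2, 4), [4, 6)
and [6, inf) cM, which partition the retained range; the upstream literature
writes these as "2–4, 4–6, >6" without specifying boundary membership, and
the half-open convention is the only one that makes them a partition.

Under a large-population approximation, segments with lengths in [L1, L2]
have expected coalescent age

    T = (300/4) * (1/L1 + 1/L2)   generations,

giving 56.25, 31.25 and 12.50 generations for the default bins (the
reciprocal of an unbounded upper limit is zero).  The bins therefore act as
coarse time strata: each bin yields its own sharing matrix, migration
surface and regression.

Sharing matrices count segments per individual pair, summed over the four
haplotype pairings.  Counts (not total cM) are used because that is the
similarity statistic the migration-surface estimator consumes; exact
duplicate rows are retained but flagged by the parser.

## The deme lattice

Demes sit on an equilateral-triangle lattice with up to six neighbors,
constructed in a plate-carrée approximation (longitudes scaled by
cos(mean latitude)).  The row x column counts are chosen so their product is
as close as possible to the requested deme count while matching the box's
aspect ratio; a single step length is then fitted so the lattice sits inside
the box anchored at the top-left corner.  Every adjacency edge has exactly
the step length in construction coordinates; on the sphere, edge lengths
deviate by at most a few percent at regional scales through longitude
convergence.  Demes are numbered row-major from the top-left corner and a
habitability mask (any polygon set, e.g. a coastline) can switch demes off;
habitability is decided by center-in-polygon with boundaries counting as
inside.  Individuals are assigned to the nearest habitable deme center by
great-circle distance, ties broken to the lowest deme id for determinism.
All spherical distances use the haversine formula with radius 6371.0 km.

## Migration surfaces

The external estimator writes per-deme log10 migration rates (`mRates.txt`)
and deme coordinates in estimation order (`demes.txt`).  Both are read as
whitespace-separated numeric tokens with no header; a token count that is an
integer multiple of the deme count is treated as posterior draws and
averaged per deme.  Deme rows are matched to lattice demes by nearest
center and must fall within one lattice step of one.

Replicate runs are averaged on the **linear** scale (arithmetic mean of
10^m): migration rate is the quantity of interest and "averaging migration"
is read literally.  A geometric-mean option (mean of the log10 rates) is
available behind a flag.  The transform order — 10^m per replicate, then
average — is a documented choice; the alternative (average the logs first)
is the geometric option.

Dispersal distance uses sigma = step * sqrt(m) by default: sigma is a
root-mean-square per-generation displacement, and under diffusive movement
the displacement variance scales as rate x step^2, hence the square root.  A
linear variant (sigma = step * m) is provided because the scaling convention
of the upstream plotting code is not fully specified.

The regression response is the natural log of the linear rate, restricted to
habitable demes; migration rates are strongly right-skewed and the log makes
the response roughly symmetric.  The base only rescales the response and is
irrelevant to the forest's fit quality.

### Heuristic baseline surface

For development and testing without an MCMC run, `baseline_surface` computes
for each habitable deme a Gaussian-kernel-weighted average of pair sharing
counts, with weights in the great-circle distance between the deme center
and the pair's great-circle midpoint, and z-scores the result across demes.
It is explicitly labelled non-publication-grade in logs: it captures where
sharing is locally high, not migration rate per se, but it correlates
positively in rank with the true surface on synthetic data (a tested sanity
floor) and exercises every downstream stage.

## Predictors

* **Rasters** — single-band ESRI ASCII grids or geographic-CRS GeoTIFFs.
  Values are extracted at deme centers by nearest-pixel lookup (the
  convention of the common GIS point-extraction utilities); points outside
  the extent or on nodata become missing, and demes with any missing value
  are dropped with a logged count — never imputed, because imputation would
  distort importance rankings.
* **Kernel density** — an unnormalized Gaussian kernel density of the
  individuals' coordinates evaluated at deme centers, bandwidth 200 km in
  great-circle distance by default.  It enters as a predictor to absorb
  sampling-intensity artifacts (surface estimators are biased near sampling
  locations).  Normalization is irrelevant: tree ensembles are invariant to
  monotone rescaling of a single predictor.
* **Categorical occurrences** (e.g. language families) — k-LoCoH hulls: for
  each occurrence point, the convex hull of it and its k-1 nearest
  neighbors (k = 10 by default; the union of hulls is the occurrence
  region).  Demes are coded 1 inside or on the boundary of any hull, else 0.
  The k-LoCoH variant and k are package choices, recorded here because
  occurrence coding is sensitive to them.

Column order in the predictor table is deterministic (rasters in input
order, hulls, then kernel), making assembled tables byte-reproducible.

## The regression model

`MigrationForest` wraps a random-forest regression (scikit-learn trees) of
the per-deme response on the predictor table:

* **RSQ** — out-of-bag percent variance explained,
  100 * (1 - OOB MSE / var(y)), the classical "percent variance explained".
* **Importance** — out-of-bag permutation importance (mean decrease in
  accuracy): per tree, the MSE increase on that tree's OOB demes when one
  predictor's values are shuffled, averaged over trees.  "Excluding" a
  variable is read as permuting it, the convention of the classical forest
  packages, not refitting without it.
* **Tuning** — grid search over mtry in ceil(P/3) * {0.5, 1, 2} (clipped to
  [1, P]) and nodesize in {1, 5, 10, 20}, minimizing OOB MSE; ties break to
  the smaller mtry then smaller nodesize.  The grid is a package choice (the
  upstream tuner's grid is unspecified) and both axes are configurable.
* **Cross-validation** — seeded k-fold (default 10) over demes.  Per fold:
  r_train and r_test are Pearson correlations of observed vs predicted
  response on the training and held-out demes; RSQ is the training model's
  OOB estimate (it is reported alongside r_test rather than as a held-out
  R^2 — both views are available from the per-fold records).  k may be as
  large as n (leave-one-out); a warning is logged when k > n/2.
* **Kernel comparison** — the with/without-kernel contrast reuses identical
  fold assignments, and when mtry is unset it is pinned to a common value so
  the contrast is not confounded by the default ceil(P/3) changing with the
  column count.
* Defaults: 1000 trees, nodesize 5; every stochastic stage takes an explicit
  seed and identical seeds give bit-identical results.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the biology that produces it:

* **Covariates** — Gaussian-smoothed white noise (smoothing sd 8 px on an
  80 x 80 grid by default), standardized per layer; layers are mutually
  independent.
* **Surface** — log10 m = sum of beta_k * g_k(z_k) + noise over habitable
  demes, with links g in {linear, step threshold at zero (the standardized
  layer's mean), tanh saturation}, each standardized so the betas are
  comparable effect sizes.
  The nonlinear links exist to exercise the forest's advantage over linear
  models.  Given a target explainable variance v, the noise sd is set to
  sd(signal) * sqrt((1-v)/v); the *empirical* variance ratio
  var(signal)/var(signal+noise) is returned as the oracle an ideal
  regression could reach.  The combined field is rescaled to sd 0.5 on the
  log10 scale (rates spanning roughly a factor of 30 across the region).
* **Sampling** — each individual is, with probability `clustering` (default
  0.6), a Gaussian draw (sd = 2 lattice steps) around one of five seeded
  cluster centers, otherwise a uniformly chosen habitable deme center.
  This mimics the strongly uneven sampling of real cohorts.
* **IBD sharing** — edge conductances on the habitable lattice are the mean
  linear rate of the endpoint demes; the commute (resistance) distance from
  the graph Laplacian pseudoinverse, rescaled so the mean adjacent-deme
  distance equals the lattice step, gives an effective distance rho between
  any two individuals' demes.  Per pair and length bin, segment counts are
  Poisson with mean c_b * exp(-rho / s) (defaults: c = 3.0 / 1.5 / 0.8
  segments for the three bins at rho = 0 — a few shared segments for
  colocated pairs, decaying over s = 300 km, about three lattice steps at
  the default scale).  Segment lengths are uniform within the bin (the
  unbounded bin is capped at 16 cM) on a single toy chromosome with a
  uniform 1 cM/Mb map.

This is **not** a coalescent simulation: counts are conditionally
independent across pairs, there is no linkage, pedigree or shared ancestry
structure, and the Poisson-exponential decay is the simplest generative
form consistent with migration surfaces shaping IBD sharing.  Tests passing
on this generator show the *pipeline* recovers the structure it assumes;
they do not validate the assumptions against real genetic data.

## Experiment harnesses and problem sizes

`recovery_experiment` generates a dataset (default 400 demes, 20 layers, 3
causal effects with mixed links at explainable variance 0.45, 200 clustered
individuals), regresses the true surface's response on the assembled
predictor table (tune, fit), and reports RSQ, the oracle explainable
variance and the causal layers' importance ranks.  The true-surface path
isolates the regression stage; the baseline-surface path can be enabled to
exercise the IBD stages as well.

`kernel_effect_experiment` builds a response that is an equal mix of one
environmental layer and the standardized sampling density under strong
clustering (0.85), then runs paired 10-fold CV with and without the kernel
column (500 trees per fold, identical folds).  Excluding the kernel should
lower CV RSQ; the direction, not the magnitude, is the tested contract.

The test-suite fixtures use 60–100-deme lattices and 100–300-tree forests;
the two experiment harnesses run at the full 400-deme scale across 10 seeds
each.  These sizes were chosen so the whole suite completes comfortably on a
single CPU while keeping the recovery experiments at the deme scale the
method targets.

## Known limitations

* The effective-migration MCMC itself is out of scope; the package reads its
  outputs and offers only the labelled heuristic baseline in its place.
* The plate-carrée lattice construction is adequate at regional scales but
  not near the poles or for continental spans.
* The baseline surface conflates sampling intensity with migration; that is
  precisely the bias the kernel-density predictor exists to absorb, and the
  kernel contract test demonstrates the mechanism rather than removing it.
* LoCoH parameters and the tuning grid are package conventions where the
  field's usage varies; both are configurable and logged.
* The synthetic IBD model cannot test robustness to coalescent noise,
  linkage, or phasing error.
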