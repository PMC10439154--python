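# Methods

Models, assumptions, parameters and numerical choices behind `riverindic`.
Nothing in this document is an empirical claim beyond what the package
itself computes on its own synthetic data.

## Data model

A survey is three ordered longitudinal transects (left bank, center, right
bank) sampled source → mouth at shared station distances. Three tables:

- **abundance** — samples × ASV read counts;
- **taxonomy** — ASV × six ranks (Kingdom … Genus);
- **metadata** — per-sample transect, station, distance to mouth,
  environmental gradients, chlorophyll *a*, and an ordered `status_class`.

Loading validates shapes, non-negativity and index agreement, and orders
samples upstream → downstream within each transect; all downstream
machinery relies on that ordering. Missing numeric metadata can be imputed
by predictive mean matching: a linear model on complete covariates ranks
donors by predicted mean, and each missing entry receives the *observed*
value of one of the `k` nearest donors (seeded), so imputations always lie
in the observed support.

## Prevalence / variance screening

Per taxon (at any aggregation rank): prevalence = fraction of samples with
abundance > 0; CV = sample (n−1) standard deviation over mean of relative
abundances. Candidates are taxa on the prevalence–CV Pareto front, ranked
by the product of min–max-standardized prevalence and CV, with
lexicographic tie-breaking. Conventional candidate counts: 6 at phylum
level, 15 at genus level.

## Ordination

Hellinger transform (square root of relative abundance) before any
Euclidean-style treatment; Bray–Curtis dissimilarities between samples.
dbRDA = PCoA of the dissimilarity matrix (negative eigenvalues either
rejected, truncated, or fixed by the Lingoes additive correction) followed
by redundancy analysis of the retained coordinates on standardized
predictors; constrained eigenvalues come from the eigendecomposition of
the fitted sum-of-squares matrix. On Euclidean distances this reproduces
classical RDA exactly (tested to rel. err < 1e−8). The global permutation
test permutes rows of the predictor matrix, uses the pseudo-F statistic and
the unbiased estimator p = (b+1)/(m+1). Collinearity is removed before
selection by iteratively dropping the predictor with the largest VIF
(1/(1−R²), threshold 5). Forward selection admits, at each step, the
candidate with the largest gain in adjusted constrained proportion if its
permutation p-value clears α; only the α stopping rule is implemented.

## Threshold surfaces

Every unordered station pair contributes (g_lo, g_hi, Bray–Curtis d) with
the gradient values in canonical order, making the fitted surface
orientation-invariant. The surface is a boosted-tree regressor (500 trees,
depth 3, learning rate 0.05, subsample 0.8) scored by R² on a seeded 80/20
pair split. The spanning score S(c) is the mean predicted dissimilarity
over grid pairs straddling c by at least one band on each side; thresholds
are interior local maxima of dS/dc exceeding the baseline (average) rate
of change, and maximal runs with dS/dc at or below the baseline are
reported as homogeneous segments.

Two numerical guards: a held-out response whose variance is numerically
zero (ss_tot ≤ 1e−12·n) scores R² = 0 by contract rather than amplifying
float noise; and because the boosted model predicts in single precision,
S carries absolute noise of order 1e−7, so a ridge must exceed a noise
floor of 1e−5/step in dS/dc before it counts as a threshold.

## Spatio-temporal screening

Engineered features: for ASV a, window w, lag l, the value at site i of a
transect is the abundance at site i−l, centered and scaled over the w
sites ending there (sample sd; w = 1 means the raw lagged value). Shifts
never cross transect boundaries. Warm-up: sites whose lagged window is
incomplete use the truncated upstream part of the window (a single
available value standardizes to 0), and sites with no lagged site at all
carry the value of the earliest site that has one — so no engineered value
ever depends on a site downstream of its own. This invariant is tested
exhaustively and is deliberately stricter than interpolating from the
first complete window, which would leak downstream information.

Evaluation is a genuine downstream prediction: training = first 85% of
observations by distance from the source, held-out = the most downstream
15%. The boosted model is XGBoost (`tree_method=hist`, `max_bin=32`,
single-threaded, seeded; softmax for the status classes, squared error for
chlorophyll *a*); defaults 80 rounds, depth 3, learning rate 0.2.

One screening run: candidates are visited in a given order; each is
grid-searched over (w, l) — lags ascending, then windows, strict
improvement only, early exit at accuracy 1 — and accepted iff its best
held-out metric strictly exceeds the incumbent's (tolerance 1e−9). The
ensemble repeats this over many runs with permuted candidate order and
hyperparameters sampled per run (trees 30–120, depth 2–5, learning rate
0.05–0.3 log-uniform, subsample 0.6–1.0). Candidates default to a
random-forest prefilter (permutation importance on a real-vs-permuted
synthetic-class task, log-loss scored), optionally truncated to the
`max_candidates` most important — the candidate-list length is the main
cost driver of a large ensemble and is the intended runtime knob.

Retention: for classification, every model with 100% held-out accuracy;
for regression, the single best-R² model (ties broken by lowest seed).

## Redundancy networks

Retained models become a binary model × ASV presence table. Node filter:
nearest-rank percentile on occurrence counts (rank = max(1, ⌈p/100·n⌉),
ties at the cutoff included; default 95). Co-occurrence edges carry the
exact number of models in which two ASVs appear together; a co-exclusion
edge is an observed joint count of zero — a statement of informational
redundancy, not a significance test. The two graphs partition the ASV
pairs. Minimal models are the smallest accepted sets; an ASV occurring in
several distinct minimal sets is a hub. The taxonomy dendrogram uses the
rank-difference distance (number of ranks at which two lineages differ)
with average linkage.

## Synthetic generator

The generator's defaults are the reference study conditions: 60 stations ×
3 transects, shared strictly decreasing distances, smooth environmental
gradients with seeded noise, and a compositional community sampled
per-station from a multinomial (library size 50 000) over intensities:

- a log-scale AR(1) background (ρ = 0.6, innovation sd 0.2) per taxon,
  sharing a base level across transects, with 30 taxa additionally coupled
  to a common trend so the background has realistic covariance;
- planted indicator groups: a parent profile switching between a low and a
  high regime (ratio 20) at given river-length fractions, offset by a few
  stations per transect; clones are the parent times log-normal jitter
  (sd 0.05) — near-duplicates carrying the same information;
- noise taxa named `ASV_0001` … with randomized taxonomy over several
  phyla; clones share their parent's lineage.

The latent response is the weighted sum of z-scored *true* lagged
(window, lag) features of the group parents plus optional Gaussian noise
(default 0); the status class is its cut-point binning (defaults −1.05,
0.85 → three classes), and at zero noise the class is an exact function of
the true lagged features — the planted ground truth that screening is
expected to recover. Chlorophyll *a* follows the saprobity latent on a
log-scale with seeded noise.

Emulation scope: the generator reproduces the *structure* that the methods
exploit — ordered transects, lagged dependence, compositional sampling,
redundant clones, environmental gradients — not the taxonomic composition,
diversity, or absolute effect sizes of any real river. Real-data headline
values (e.g. threshold positions in mg L⁻¹ or surface R²) are not
reproducible from it and are never asserted.

## Scaled-down test designs

Test and example configurations shrink the problem (fewer stations, fewer
noise taxa, smaller libraries, shorter grids, fewer ensemble runs, explicit
candidate lists, truncated prefilter rankings) to fit interactive runtimes;
they change cost, not semantics. Two designs deserve explanation:

- **Lag recovery** is measured *conditionally*: the grid search must
  recover an indicator's planted lag with the other indicator group's true
  feature already in the design. At desk scale a single indicator alone
  barely beats chance on the three-class task, so the unconditional search
  carries no lag information to recover.
- **Clone co-exclusion** uses a single planted redundancy group whose
  regime switches all occur inside the training region, with one
  transect's class flipping exactly at the train/test boundary. The
  position-only baseline is then imperfect while either clone alone
  classifies the held-out block perfectly, so a greedy run stops after
  accepting its first clone and no retained model can contain both clones;
  the co-exclusion edge follows structurally. The surrounding ensemble
  (permuted candidate orders including decoy noise ASVs, sampled
  hyperparameters) is unchanged.

With `tree_method=hist` and `max_bin=32`, boosted trees place split cuts
at training-quantile bin edges; when many training samples share a bin, or
when a held-out value falls between a learned cut and the training class
boundary, a feature that separates the classes perfectly in value space
can still yield imperfect held-out accuracy. The scaled designs above keep
training sizes near the bin resolution so that split placement, not bin
mixing, determines the outcome.

## Limitations

- Forward selection implements only the α stopping rule (no adjusted-R²
  ceiling), which can admit more predictors than the two-criterion variant.
- Co-exclusion is a zero-count statement; with few retained models it can
  reflect sampling rather than true redundancy. Use large ensembles before
  interpreting edges.
- The ordered split evaluates a single downstream block; no rolling-origin
  evaluation is implemented.
- PMM imputation assumes an approximately linear mean structure among the
  numeric metadata variables.
- BIOM input is not supported; the three tables are TSV.
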