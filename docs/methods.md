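# Methods

This note records the statistical model behind `mprkit`, the design of the
synthetic data generator, the estimators and their conventions, and the
numerical choices a maintainer would want to know.

## Proxy measures

All probabilities are basket-frequency estimates. A *basket* is one till
receipt; an input lacking basket identifiers is grouped one-basket-per
(customer, store, date). A basket is *menstrual* if any line's product is
categorised "tampon" or "sanitary pad", *pain* if any line is "Pain Relief
Oral" or "Topical Pain Relief" (exact, case-insensitive category matching),
and *menstrual-pain* if both. For a basket universe of size n:

- P(M) = #menstrual / n, P(P) = #pain / n;
- P(P|M), P(P|¬M) are pain frequencies within the menstrual / non-menstrual
  partitions;
- MPR = P(P|M) / P(P|¬M).

The law of total probability, P(P) = P(P|M)·P(M) + P(P|¬M)·(1−P(M)), holds
as an exact algebraic identity on any single universe and is asserted in
tests at 1e−12. Undefined quantities (no menstrual baskets; zero
denominator) are returned as `None` (or NaN in tabular outputs), never as
sentinel values.

**Customer-set convention.** Customer sets are defined by basket content:
the menstrual (pain) set holds customers with ≥1 menstrual (pain) basket;
the menstrual-pain set holds customers with ≥1 basket carrying both flags,
and is a subset of both. Each probabilistic measure is computed over the
basket universe of its customer set: in particular the headline MPR and
the area-level menstrual-pain conditional are computed **within the
menstrual-pain customer set**, i.e. P(P|¬M) is that set's own background
pain-purchase rate. This is the reading under which the three calibration
anchors below are mutually consistent; the estimators themselves
(`compute_proxies`, `msoa_proxies`, `income_gradient`) are
customer-set-agnostic and accept any basket table.

## Synthetic data generator

The generator emulates a loyalty-card panel from a single retailer. Its
defaults are the study conditions the analysis is calibrated to; all
randomness derives from one seed through fixed named streams, so outputs
are bit-identical across runs.

**Shopping process.** Customers are assigned uniformly to MSOAs (each
containing 4–5 LSOA neighbourhoods and, by default, one store) and shop at
one home store. Ordinary trips arrive at `trip_rate_per_week` (default 1)
on uniform days over the two-year default period. Every basket carries one
everyday item; menstrual and pain items are added per the processes below.
One basket per (customer, date); same-day events merge.

**Cycles.** A `menstruating_fraction` (default 0.5) of customers carry a
menstrual cycle. Inter-onset gaps are drawn from a normal distribution
(mean 28 d, sd 3.8 d) truncated to the conventional physiological window
[21, 35] and rounded to whole days, so every true inter-onset gap lies in
the window by construction; the truncation is symmetric, so the mean stays
at 28. The default 0.5 menstruating share is a panel-composition choice:
the share observed in any real retailer's data reflects market share and
card usage, not biology, and 0.5 keeps per-area menstrual basket counts
informative at desk scale.

**Noise.** Each onset produces a menstrual basket with probability
1 − `purchase_miss_prob` (default 0.7); missed onsets create observed gaps
of two or more cycles, the long right tail of the unfiltered interval
distribution. With probability `stockup_prob` (default 0.05) per cycle, a
customer makes one extra menstrual purchase on a uniformly chosen
non-onset day of that cycle — roughly 1.3 stock-ups per customer over two
years. Stock-ups split one cycle gap into two shorter gaps; keeping the
rate at the per-cycle (not per-trip) level is what leaves the planted
28-day mode recoverable after the physiological filter, which is the
generator's purpose. Neither contraceptive cycle suppression nor
multi-retailer switching is modelled beyond the miss probability.

**Pain co-purchase and customer heterogeneity.** A `pain_prone_fraction`
(default 0.267) of menstruating customers co-purchase pain relief in
menstrual baskets: each of their menstrual baskets includes a pain item
with probability `p_pain_given_menstrual` (default 0.50) scaled by their
area's income decile (below). Non-prone customers' menstrual baskets never
include pain relief — they manage pain outside menstrual shopping — while
*everyone's* non-menstrual baskets include pain relief at the background
rate `p_pain_given_nonmenstrual` (default 0.1282). This heterogeneity is
essential: under a homogeneous mechanism, any customer with ~20 menstrual
baskets would almost surely have at least one menstrual-pain basket, and
the menstrual-pain customer fraction could not sit at a calibrated 26.7%.
The three anchors — fraction 0.267, within-set P(P|M) = 0.50, within-set
MPR = 0.50/0.1282 ≈ 3.9 — are then simultaneously recoverable.

**Income gradient.** MSOAs are ranked by latent weekly household income
and split into deciles (ties broken by position). The menstrual pain
probability of prone customers is multiplied by a decile scale, linear in
decile rank and **normalised to mean 1**:

```
scale(d) = ((1 − g) + g·(d − 1)/9) / (1 − g/2),   d = 1..10
```

so the top-vs-bottom relative contrast is exactly g (default 0.32) while
the population-mean conditional probability stays at the configured 0.50.
An un-normalised scale running from 1−g to 1 would silently drag the
population P(P|M) to 0.42 and the MPR to ≈3.3, making the gradient and the
MPR calibrations mutually inconsistent.

**Regions.** LSOA incomes are a mean-preserving 3% spread of their MSOA's
latent income, so averaging LSOAs recovers the latent value exactly and
the estimator's decile ranking matches the planted one. IMD score and
jobseeker claims fall with income, electricity spend rises, room occupancy
falls slightly, and population counts/age structure are independent noise
— realistic collinearity that the attribution stage must contend with.

**Catalogue.** Unit prices are log-normal per category; popularity weights
(used to sample which product fills a basket line) are tied to price
through a Gaussian copula with target correlation −0.80 for pain items and
−0.50 for menstrual items, so the realised price–frequency correlation is
stronger (more negative) for pain relief — customers are more
price-sensitive about analgesics than about menstrual products.

**What the generator does not emulate.** Real panels have household
card-sharing, purchases for others, basket-spanning co-purchases across
days and stores, seasonal and promotional dynamics, store catchments
crossing area boundaries, and within-area deprivation heterogeneity.
Passing recovery tests therefore shows the estimators are correct and
well-calibrated under the stated model, not that the proxies are unbiased
on real retail data.

## Periodicity analysis

Per customer with ≥2 menstrual baskets, day gaps between date-sorted
consecutive menstrual baskets are pooled across customers (a single pooled
summary, not a mean of per-customer summaries). The physiological filter
retains gaps in [21, 35], bounds inclusive; it is idempotent. Summaries
report n, integer mode (ties broken to the smallest value, for
determinism), arithmetic mean, population standard deviation, median, min
and max; an empty input yields an explicit empty summary. Same-day
menstrual baskets at different stores yield zero-day gaps and are kept in
the unfiltered summary.

## Regional analysis

LSOA features are averaged up to MSOAs with unweighted means. Baskets are
pooled across an MSOA's stores before computing proxies — pooling counts,
never averaging per-store probabilities, which preserves the
law-of-total-probability identity and weights stores by volume.
`study_region_table` assembles the per-area table the study design calls
for: transaction volume, P(M) and P(P) over all customers' baskets, and
P(P|M)/P(P|¬M)/MPR within the menstrual-pain customer set. Restricting the
conditional to its customer set also removes the between-area binomial
noise of the pain-prone share, which would otherwise dominate the decile
contrast at desk scale.

Feature–proxy association uses Pearson correlation with two-sided
p-values, pairwise-deleting areas with undefined values; cells with fewer
than 3 pairs or zero variance are flagged NaN. The income gradient is
(top-decile mean − bottom-decile mean) / top-decile mean of area-level
P(P|M), with deciles over area household income; the decile convention is
shared with the generator so the planted contrast is recoverable exactly
up to Monte-Carlo noise. "Lowest/highest income areas" as extreme deciles
is a definition choice — the grouping is exposed via `n_groups`.

## Classification and attribution

Areas are labelled High when the target proxy strictly exceeds the
unweighted mean over areas with a defined value. Features are min-max
scaled to [0, 1] inside the cross-validation pipeline (bounds fitted on
training folds only, held-out values clipped); the description of the
normalisation as both z-scoring and [0, 1]-ranged is contradictory, and
min-max was chosen as matching the stated range. Zero-range features are
dropped with a warning, and a raw ONS income column is dropped when weekly
household income is present (collinear).

Model families and grids (small, honest, desk-scale):

- logistic regression, C ∈ {0.01, 0.1, 1, 10};
- random forest, trees ∈ {100, 300} × depth ∈ {3, 6, none};
- SVM, kernel ∈ {linear, RBF} × C ∈ {0.1, 1, 10};
- multilayer perceptron, one or two hidden layers of {8, 16, 32} units,
  lbfgs solver with L2 penalty 1e−3 and no early stopping — at one or two
  hundred areas an early-stopping validation split is ~10 rows and halts
  training almost immediately, so full-batch lbfgs is the appropriate
  small-sample configuration.

Selection is by mean accuracy under stratified 10-fold CV (stratification
guards against single-class folds; a minority class smaller than the fold
count fails loudly). Training is refused below 50 labelled areas or with
degenerate labels.

Feature influence uses a sampling (permutation-chain) Shapley estimator on
the winning model's P(High) output: per Monte-Carlo sample, one random
feature permutation and one background row per evaluation point; walking
the permutation from background to evaluation values yields every
feature's marginal contribution from one chain of model calls. Defaults:
≤100 evaluation points, ≤100 background rows, 64 permutation samples. The
estimator satisfies efficiency (attributions sum to f(x) − E[f] up to
Monte-Carlo error), gives exactly zero to constant features, and on
additive models recovers the coefficient-magnitude ordering — all
asserted in tests. Rankings report mean |Shapley value| plus a signed
summary (the correlation between feature value and Shapley value:
positive means high values push toward High).

## Problem sizes and tolerances

Recovery checks run at sizes chosen so Monte-Carlo error is small against
each tolerance: the headline acceptance simulation uses 40,000 customers
across 150 MSOAs over two years (≈3.4 million baskets; ≈600,000 within the
menstrual-pain set; decile-gradient standard error ≈1 percentage point
against a ±3-point band; MPR standard error ≈0.03 against ±0.15). Module
tests use panels of 600–6,000 customers, with seed-replication tests (20
seeds) for the MPR median and the null income gradient. The end-to-end
pipeline at its 5,000-customer default completes in well under a minute
plus roughly a minute for classification.

## Known limitations

- The proxy is a lower bound on menstrual-pain prevalence: it misses
  sufferers who cannot afford or do not use OTC analgesics, buy them
  elsewhere or in separate trips, or manage pain non-pharmacologically;
  and it does not measure pain intensity.
- Basket co-occurrence is instrumental: pain items in a menstrual basket
  need not be for menstrual pain. The MPR's normalisation mitigates but
  cannot remove this.
- Area-level associations are ecological; no spatial autocorrelation
  adjustment is applied, and store catchments are assumed to coincide
  with their containing MSOA.
- Real-data correlation and accuracy values are properties of a private
  dataset and are not targets here; synthetic recovery demonstrates
  estimator correctness under the stated model only.
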