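# Methods

This note documents the statistical procedures implemented in `clpnet`,
the data-generating model behind its synthetic panels, the defaults that
matter, and what the test suite does and does not establish.

## The cross-lagged panel network model

Given two waves of $p$ symptom scores per subject, the cross-lagged panel
network (CLPN) is estimated by $p$ separate penalized regressions: for
each item $j$, the wave-2 score is regressed on **all** $p$ wave-1
scores,

$$ y^{(2)}_j = \sum_{i=1}^{p} a_{ij}\, y^{(1)}_i + \varepsilon_j, $$

with an L1 (LASSO) penalty on the coefficients. The matrix $A = (a_{ij})$
is the directed network: $a_{jj}$ is the autoregressive self-loop (a
symptom predicting itself across waves, controlling for everything else
at wave 1), and $a_{ij}$, $i \ne j$, is the cross-lagged edge $i \to j$.
Regularization makes $A$ exactly sparse, which is what gives "nonzero
edge" counts their meaning.

Choices that the estimator exposes, with their defaults:

* **Penalty selection** — per node, 10-fold cross-validation minimizing
  mean squared prediction error; the smallest penalty attaining the
  minimum is chosen on exact ties (`lambda_rule="min"`). The
  one-standard-error rule is deliberately not silently substituted: the
  CV-minimum is the default in the nodewise-regression network
  literature, and it is recorded in the results object.
* **Standardization** — predictors *and* outcomes are z-scored before
  fitting, so coefficients are comparable across nodes and between the
  autoregressive and cross-lagged classes; the scaling record is kept in
  `CLPNResults.standardization`.
* **Fold assignment** — each node draws its folds from a random stream
  keyed by (master seed, CRC-32 of the node name). Keying by *name*
  rather than position makes the whole fit equivariant under item
  reordering (permuting the input columns permutes $A$ conjugately),
  which the tests check exactly.
* **Penalty grid** — 100 log-spaced values per node from the smallest
  all-zeroing penalty down to $10^{-3}$ of it. The grid floor matters
  only for runtime: CV selection lands well above it on all data the
  package targets.
* **Solver** — an in-package Gram-matrix coordinate-descent path solver
  (numba-compiled) with warm starts along the grid and convergence
  tolerance $10^{-6}$ on the maximum coefficient update. It minimizes the
  same objective as glmnet/scikit-learn,
  $\frac{1}{2n}\lVert y - Xb\rVert^2 + \lambda \lVert b \rVert_1$, and the
  test suite pins it against scikit-learn's Lasso (agreement $\le
  10^{-6}$ at matched tolerances) and against the normal-equation OLS
  solution at zero penalty. It exists because the stability analyses
  refit the full network thousands of times; per-call overhead of the
  generic implementations dominates at that scale.

`fit()` with `penalty="none"` solves the unpenalized normal equations;
a float fixes one penalty for every node.

## Centrality and bookkeeping conventions

* **Expected influence (EI)** of a node: signed sum of its incident
  cross-lagged edges, incoming + outgoing each counted once; the
  self-loop is excluded. In-only and out-only variants are options.
* **Bridge expected influence (BEI)**: the same sum restricted to edges
  whose other endpoint belongs to the other disorder. For bridging, the
  two depression sub-communities (negative-mood and reverse-scored
  positive-affect items) collapse into one depression side.
* **Normalized BEI** is the z-score of BEI across the network's nodes
  (population SD); a node is a **bridge symptom** when its normalized BEI
  strictly exceeds 1 in *every* sample considered.
* **Block-wise global characteristics** follow the two-instrument
  bookkeeping of symptom-network reports: the entire network counts all
  $p^2$ ordered pairs including self-loops ($33^2 = 1089$); the PTSD
  block counts $15^2 = 225$ ordered pairs, the depression block
  $14^2 = 196$ (the 14 negative-mood items — the only reading consistent
  with the published counts; positive-affect items belong to the entire
  network but to neither within-block); the two between blocks count
  $15 \times 14 = 210$ ordered cross pairs each. Density = nonzero /
  estimated; global strength = $\sum |w|$; average weight = strength /
  estimated. Reported tables round to 2 decimals; full precision is kept
  internally.

## Accuracy and stability

* **Edge accuracy** — nonparametric bootstrap (default $B = 1000$;
  subjects resampled with replacement, one resample per replicate reused
  for every edge), percentile intervals at 95%. The penalty is
  re-selected inside each replicate by the same CV rule (freezing is an
  option). Percentile rather than BCa intervals: the convention of the
  bootstrap procedure this mirrors.
* **CS coefficient** — case-dropping bootstrap of a centrality index:
  for each drop proportion $q$ in a grid (default 0.05–0.75 by 0.05,
  $B = 250$ per proportion), subsample $\lceil (1-q)n \rceil$ subjects
  without replacement, recompute the index, and correlate with the
  full-sample index. CS is the largest $q$ whose correlation is
  $\ge 0.7$ in $\ge 95\%$ of draws (0 if none; if the full-sample index
  is constant the statistic is undefined and the maximum grid value is
  returned with a warning). CS $> 0.25$ is the usual minimum for
  interpretation, $> 0.5$ preferred.
* **Difference tests** — for node pairs (BEI) or edge pairs, the
  bootstrap distribution of the difference; significant when the
  two-sided percentile interval excludes zero. Uncorrected, as is
  conventional for these matrices; the output says so.

A calibration study in the acceptance suite checks the percentile
interval: for a true coefficient of 0.2 in a 6-node network at
$n = 1000$ on the *continuous latent scale*, the 95% interval covers the
truth in roughly 90% of runs. The latent scale is used because ordinal
discretization attenuates the regression estimand below the generating
coefficient, so "coverage of the generating value" is only well defined
before discretization; the mild undercoverage that remains is the known
shrinkage bias of bootstrapping a penalized estimator.

## Exploratory graph analysis

EGA estimates the number of latent dimensions by (1) fitting a Gaussian
graphical model to the item correlation matrix by graphical lasso along
100 log-spaced penalties, selecting the model minimizing the extended
BIC, $-2\,\ell + E \log n + 4 \gamma E \log p$ with $\gamma = 0.5$ and
$E$ the number of nonzero off-diagonal pairs; and (2) running 4-step
walktrap community detection on the absolute partial correlations.
Isolated nodes become singleton communities. bootEGA repeats the fit on
$B$ subject resamples, forms the element-wise median network, detects
communities on it, and reports per-item replication (how often an item
lands with its median-network community, after Hungarian label
matching). bootEGA applies only to cross-sectional matrices; passing a
directed network raises `TypeError`. Correlations are computed on
nonparanormal-transformed data (transform-then-Pearson), consistent with
the rest of the pipeline; the graphical-lasso convergence tolerance is
$10^{-3}$ (selection is edge-count driven and the EBIC comparison is
insensitive at that level; the EBIC itself is verified against a direct
log-determinant oracle).

## Preprocessing

* **Imputation** — default chained equations with predictive mean
  matching (5 donors, 10 cycles, per wave), deterministic given the
  seed; a per-item mode fill is available. Single imputation, not
  multiple: with the sub-2% missingness these panels carry, pooling
  would change nothing and single imputation keeps the pipeline
  deterministic. Observed cells are never altered.
* **Nonparanormal transform** — per column, average ranks through the
  empirical CDF winsorized at $\delta = 1/(4 n^{1/4} \sqrt{\pi \log
  n})$, then the standard-normal quantile, then rescaling to unit
  variance; applied to each wave separately. Rank-based, hence invariant
  to monotone recodings; Spearman correlations are preserved exactly
  whenever no rank falls in the winsorized tails (always the case for
  0–3 ordinal items whose tail categories carry more than $\delta$
  mass).
* **Normality screen** — per-item skewness and kurtosis with the
  conventional flags skewness > 2 or kurtosis > 7; kurtosis is on the
  Pearson scale (normal = 3), which is the scale the 2/7 rule of thumb
  was stated on.
* **Screening prevalence** — instrument totals (reverse items recoded
  $3 - x$) against the published cut-offs (PTSD scale $\ge 11$,
  depression scale $\ge 15$, inclusive); subjects missing any item on an
  instrument get a missing total and drop from the denominator. The
  default catalog is a truncation of both published instruments (15 of
  17 and 18 of 20 items), and the prevalence report flags that.

## The synthetic-data generator

The generator is the package's substitute for raw panel data and defines
the conditions under which every downstream claim is tested.

Latent model: wave-1 severities are multivariate normal with
exchangeable correlation 0.3 within each disorder and 0 between, except
that bridge items also correlate 0.15 across the boundary. Wave 2 is
$z^{(2)} = W^\top z^{(1)} + \varepsilon$ with residual SDs chosen to
make every wave-2 latent unit-variance. Both waves are discretized by
per-item increasing thresholds; the default thresholds put mass
(0.55, 0.25, 0.15, 0.05) on categories 0–3, the right-skewed endorsement
typical of community symptom data. Reverse-scored positive-affect items
are stored as $3 - $category, so the generator emits raw-scale data and
the ground truth on the raw scale is $DWD$ with $D = \mathrm{diag}(\pm
1)$ (`raw_weight_matrix()`). Missingness is MCAR per wave (default 1%,
the order of magnitude seen in school-administered panels).

Ground-truth weights: autoregressive loops $\mathcal N(0.19, 0.05)$
clipped to $[0, 0.95]$ — self-prediction dominating cross-prediction by
an order of magnitude is the robust finding of two-wave symptom panels.
Within-disorder cross-lagged edges appear with probability 0.35 and
weights $\mathcal N(0.02, 0.01)$ (the published within-block *nonzero*
densities of 0.45–0.65 make 0.35 a conservative latent density). Each
designated bridge item (default: the six dysphoria symptoms) carries 4
guaranteed outgoing and 3 incoming cross-disorder edges with weights
$U(0.11, 0.18)$, other endpoints load-balanced over the non-reverse
items of the other disorder, plus random extras at rate 0.04. Three
deliberate design features: (i) cross-disorder edges avoid
reverse-scored endpoints, because a raw-scale sign flip would cancel the
bridge's signed influence — empirically the strong dysphoria–depression
links run through negative-mood items; (ii) receiver load balancing
prevents any non-bridge item from accumulating bridge-level influence by
accident, so the designated bridge set is actually bridge-dominant *in
truth*; (iii) the guaranteed edges put some true weights above 0.15,
giving the sign-recovery study a non-empty target set.

What the generator does **not** emulate: attrition/dropout between
waves, measurement non-invariance across samples, MAR/MNAR missingness,
floor effects beyond the skewed thresholds, and any dependence of item
difficulty on covariates. Passing recovery tests therefore demonstrates
that the estimators work under a faithful linear-Gaussian-threshold
regime at these sample sizes — not that any specific empirical dataset
satisfies that regime.

## Replicability metrics

`compare_networks` reports (a) the Pearson correlation between the two
networks' cross-lagged edge vectors (all $p(p-1)$ ordered pairs;
self-loops excluded by default, includable), with Fisher 95% CI and $t$;
(b) the number of edges nonzero in both networks with equal sign,
together with that count divided by *each* network's nonzero count (the
two shares answer different questions and published reports have mixed
them up — both denominators are always emitted), plus a presence-only
count; (c) the Pearson correlation of BEI vectors; (d) the overlap of
the top-$k$ ($k = 3$) nodes by normalized BEI.

## Problem sizes used by the tests and the acceptance script

Recovery and discrimination studies run at $n = 2000$ subjects, 33
items, 20 (tests) or 8 (script) replicates; the null false-positive
study at $n = 2000$; EGA dimensionality at $n = 1000$ with blocks of 4
and 20 seeds; bootstrap coverage at $n = 1000$, $B = 250$, 40 (tests) or
24 (script) runs; the demonstration pipeline at $n = 600/400$ with
$B = 200$ edge-bootstrap replicates, $B = 40$ case-drop replicates per
proportion and $B = 50$ bootEGA replicates. These sizes were chosen so
each study estimates its rate with usable precision while the whole
suite stays comfortably runnable on a laptop; the full-scale defaults
($B = 1000$, 250 per proportion) remain the API defaults.

## Known limitations

* CV-minimum LASSO overselects under a global null: a few percent of
  truly-zero edges come back with tiny nonzero weights (almost never
  above 0.05). Edge *presence* near zero should be read jointly with the
  bootstrap intervals, as in the source methodology.
* Percentile bootstrap intervals inherit the penalty's shrinkage bias
  (~90% observed coverage at nominal 95% in the calibration study).
* The walktrap step count (4) and EBIC $\gamma$ (0.5) are the standard
  EGA configuration and are exposed but untested at other values.
* Estimated coefficients from discretized ordinal data are attenuated
  relative to the latent generating weights (by roughly a third at the
  default thresholds); sign and rank structure, which the analyses rest
  on, survive.
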