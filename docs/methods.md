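# Methods

`taskrt` analyzes person-by-item scores and response times (RTs) from an
untimed simulation-based assessment task: 11 items (seven selected-response
knowledge items, then a simulation item and three explanation items), each
scored 0/1, with per-item RTs in seconds and no missing cells. This note
records the models, the synthetic-data generator, the numerical choices, and
what the test suite does and does not establish.

## The joint model

Each person j carries two latent traits, ability θ_j and speed τ_j; each
item i carries difficulty b_i, time-intensity β_i (log seconds) and
time-discrimination α_i (> 0). Conditional on these, the score and the RT of
a cell are independent:

- **Scores (Rasch):** P(Y_ji = 1) = 1 / (1 + exp(−(θ_j − b_i))).
- **RTs (two-parameter lognormal):** log T_ji = β_i − τ_j + ε_ji with
  ε_ji ~ N(0, α_i⁻²). Larger τ means a systematically faster person; larger
  α means less RT dispersion on that item.

At the population level (θ_j, τ_j) ~ N₂(0, Σ_p) and (b_i, β_i) ~ N₂(μ_I, Σ_I),
with α_i treated as independent of (b_i, β_i). The quantities of scientific
interest are the correlations ρ_θτ = σ_θτ/(σ_θ σ_τ) (do more able people work
faster?) and ρ_bβ = σ_bβ/(σ_b σ_β) (are harder items more time-consuming?).

Priors: μ_b ~ N(0, 2), μ_β ~ N(4.5, 2) (variances; 4.5 log-seconds ≈ 90 s,
a weakly informative center for item-level times), Σ_p and Σ_I ~
inverse-Wishart(I₂, ν = 1), α_i ~ inverse-gamma(1, 1) on α itself. ν = 1 on a
2×2 matrix sits at the edge of propriety; the sampler warns at startup and a
config switch raises it to ν = 3 (the posterior is proper either way since
the data term adds J or I degrees of freedom).

### Sampler

A bespoke Gibbs-within-Metropolis scheme, chosen so every conditional that is
conjugate is sampled exactly:

- **Conjugate Gibbs:** τ_j and β_i (normal), (μ_b, μ_β) (bivariate normal),
  Σ_p and Σ_I (inverse-Wishart, drawn via a 2×2 Bartlett decomposition).
- **Adaptive random-walk Metropolis:** θ_j, b_i (Rasch likelihood is not
  conjugate) and log α_i. Per-coordinate step sizes adapt by Robbins-Monro
  toward 0.44 acceptance during burn-in only and are frozen afterwards, so
  the retained chain is a valid Markov chain. Post-burn-in acceptance rates
  outside (0.1, 0.6) trigger a warning.
- **Identification:** the scales of θ/b and τ/β are only jointly determined,
  so after every iteration the means of θ and τ are recentred to zero with
  compensating shifts of b and β. This leaves μ_b and μ_β estimable and makes
  the constraint (mean ability = mean speed = 0) hold exactly in every
  retained draw.

Reference schedule: 2 chains × 15,000 iterations, 5,000 burn-in, thinning 5
(2,000 retained draws per chain); per-chain seeds derive deterministically
from one master seed. Convergence is judged by the Gelman-Rubin potential
scale reduction factor (no chain splitting), computed for every reported
parameter; max PSR < 1.1 counts as converged. Point estimates are EAPs
(pooled posterior means) with posterior SDs and equal-tailed 95% credible
intervals; the Level-2 correlations are computed per draw from that draw's
covariance entries and then summarized, which keeps |ρ| ≤ 1 draw by draw.

The test suite runs a scaled schedule (2 × 5,000 iterations, 2,000 burn-in)
on the J = 445 preset, which passes the same PSR criterion and recovers the
generating b and β within ±0.3 for at least 9 of 11 items; the acceptance
script runs the full schedule (a few minutes on one CPU; the sampler is
fully vectorized over persons and items, ~1 ms per iteration at 445 × 11).

## Synthetic data

The generator draws from exactly the model above. The default ("study-like")
configuration reproduces the study conditions: J = 445, I = 11, the
published EAP item parameters as fixed generating truth, person covariance
(σ_θ², σ_θτ, σ_τ²) = (0.85, 0.04, 0.08) — implying ρ_θτ ≈ 0.15 — and person
covariates emulating the reported sample composition (63.6% male; median age
~24; ethnicity 75.5/12.8/6.1/5.6%; career plans 70.8/22.3/6.9%; motivation
answers ~60/35/5%) with effects on log task time of at most 0.08 in absolute
value, matching the finding that no covariate clearly predicted timing.
Under these defaults the median synthetic task time is ~4 minutes with
quartiles near 3.3/5.3 minutes, like the study's.

Planted structure, all optional and off by default:

- **Speed clusters** shift per-item log-RT means additively (preserving
  within-cluster lognormality) and may shift ability. The bundled
  three-cluster preset plants sizes 12/222/211 with pairwise log-RT gaps of
  1.4–2.9 and ability −1 for the small slow cluster. These gaps are chosen
  for *recoverability*: the common person-speed factor (sd ≈ 0.28 on the log
  scale) elongates the raw-seconds point cloud, and pairwise gaps below ~1
  are not separable by Euclidean/Ward clustering at these sizes. The planted
  preset therefore demonstrates detector correctness, not the (much weaker)
  separation of the real study's clusters.
- **Rapid guessers** replace a fraction of persons' cells with RT ~
  Uniform(1, 5) s and scores at the item's chance level (1/4 for 4-option
  single selection, 1/3 for the 2-of-3 multiple selection, 1/120 for the
  5-option ordering item, 0 for constructed response).
- **Covariates** enter as additive shifts on τ (equivalently multiplicative
  on time); nominal covariates are closed category sets.

What the generator does **not** emulate: within-person speed drift across
items, item-order/position effects, RT dependence beyond the single common
speed factor, polytomous or missing responses, and action-level process
data. Passing tests therefore show the pipeline recovers structure *of the
generator's kind*; they cannot certify behavior on data violating the
lognormal or fixed-speed assumptions.

## Timing distributions

Task times and item RTs are fit by maximum likelihood under lognormal,
gamma and Weibull families. The lognormal MLE is closed form (mean and
variance of the log times, divisor n); gamma and Weibull use scipy's
numerical MLEs with the origin fixed at zero. Families are ranked by the
two-sided Kolmogorov-Smirnov distance (log-likelihood reported as a
secondary criterion). The KS statistic uses both one-sided ECDF limits at
every sample point; the p-value comes from the asymptotic Kolmogorov
distribution with fitted parameters treated as known. That "plain" p-value
is conservative for fitted families; a parametric-bootstrap correction
(refitting per replicate) is available behind `ks_method="bootstrap"` but is
not the default. Constant samples are reported as degenerate rather than
fit. Display conventions truncate task-level plots at 150 s and item-level
conditional-accuracy grids at the item's 90th RT percentile; statistics
always use all data.

## Covariate regression

Log task time is regressed on person covariates by OLS. Nominal covariates
enter as whole blocks of indicator columns (reference = first declared
category), so the 8-predictor preset model carries 14 model degrees of
freedom. Reported statistics: RMSE = √(SSE/(n − p − 1)), R², and adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1), with p the encoded column count.
Stepwise selection is forward with partial-F entry tests (block-level
numerator df) at α = 0.05 and backward removal at the same level after each
entry; ties in entry p-values break by declared candidate order, making the
trace deterministic. Rank-deficient designs raise an error naming the
aliased columns. Information-criterion selection is deliberately out of
scope.

## RT-pattern clustering

Persons are clustered as I-dimensional raw-seconds RT vectors with Ward
linkage under the Ward.D2 height convention (two singletons merge at their
Euclidean distance); a log-RT option exists behind a flag. The cluster count
is selected at the elbow of the merge-height curve: with h_K the height at
which K clusters become K−1, K* maximizes the second difference
h_K − 2h_{K+1} + h_{K+2} over 2 ≤ K ≤ k_max−1 (ties toward smaller K). A
curve with no positive curvature returns the smallest admissible K with a
"no clear elbow" warning. The elbow rule is scale-covariant, so the height
convention does not affect K*. Labels are 1-based and ordered by cluster
size descending. Profiles report per-item mean RTs, task-time five-number
summaries, mean task score with a normal-approximation 95% CI (undefined
for singleton clusters, not NaN), per-item accuracy, and covariate
composition.

## Rapid-guessing detection

For each item the *conditional proportion correct* is the accuracy among
responses with RT ≤ t, evaluated at every observed RT (a binned variant
exists behind a flag). The per-item threshold is the largest time t*, capped
at 10 s, such that accuracy at or below t* is ≤ chance + margin (margin
0.1) and accuracy above t* is ≥ chance + 2·margin — an explicit,
deterministic replacement for visual inspection. Two guards prevent noise
dips from manufacturing thresholds: the 10 s cap (thresholds such
procedures find in practice are ~6–8 s, and the planted guessing range is
1–5 s), and a one-sided binomial test (α = 0.05) that the below-threshold
correct count is significantly below the solution-side criterion. Without
these guards the cumulative-accuracy path of a genuinely hard item (e.g.
a CR item with overall accuracy ~0.26 against chance 0) dips to chance by
luck in a substantial fraction of clean datasets; with them, measured
specificity on guesser-free data is 100/100 while planted guessers below
5 s are still recovered with thresholds in [4, 6] s. Cells with RT strictly
below their item's threshold are flagged; the dataset verdict is
"negligible" only when every item's flagged fraction is strictly below 2%.

## Problem sizes and determinism

Simulation-based tests use the study-scale J = 445 where the claim is about
study conditions, 10⁴–10⁵ draws for moment checks, and 20–100 replications
for rate assertions; the MCMC-based tests use the scaled 5,000-iteration
schedule, and a 20-replication single-chain study checks that the 95%
credible interval for ρ_θτ covers the generating value in ≥80% of refits.
Every random quantity in the package flows from an explicit seed
(`numpy.random.Generator` throughout; spawned child streams per stage), so
pipelines rerun byte-identically. All artifacts are JSON/CSV stamped with
the configuration hash and master seed.

## Known limitations

- The rapid-guessing rule's two margins, the 10 s cap and the significance
  level are conventions; datasets whose solution behavior is barely above
  chance will yield no threshold by construction.
- Raw-seconds Euclidean clustering is dominated by the most time-intensive
  items and by the common speed factor; weakly separated profiles (pairwise
  log gaps ≲ 1) are not recoverable at these sample sizes.
- The KS comparison treats fitted parameters as known unless the bootstrap
  flag is set, so its p-values are conservative.
- The joint model assumes one fixed speed per person; mixtures,
  item-position effects and 2PL/3PL response models are out of scope.
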