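# Methods

## Model

Each observation Y_gi (gene g, cell i) carries a latent phase Z_gi. In the
background phase the gene is not transcribed and the count follows a
cell-specific zero-inflated Poisson, ZIP(p0_i, lam_i): inflation mass p0_i
at zero mixed with Poisson(lam_i). In the active phase the count is
Poisson(theta_gi * S_gi) with a lognormal concentration
theta_gi ~ LN(mu_g, sigma2_g) and a technical distortion S_gi specific to
both the cell and the gene. The prior activation probability pi_g is
per-gene and constant across cells; a cell-dependent prior (e.g. tied to
detection rate) is a plausible alternative we did not adopt, because the
cell context already enters through the background parameters and the
factors themselves.

theta and S are jointly unidentified; we constrain the mean of S over
unmasked genes in the *reference cell* — the cell whose library size is the
median — to be 1. With an even number of cells the lower of the two middle
library sizes is used so the reference is always an actual cell; ties break
to the first cell in column order.

All internal logarithms are natural. Diagnostics that are conventionally
presented in log2 (the count-depth mean-expression filter) expose the base
as an option, defaulting to log2 with pseudo-count 1.

## Background estimation

If N background genes in a cell follow Poisson(lam), the frequency n_y of
count value y satisfies log n_y + log y! = (log N - lam) + y log lam, so a
line fitted to the points (y, w_y), w_y = log n_y + log y!, recovers lam
from its slope. Only y in 1..y_max (default 10) enters: higher counts are
increasingly produced by active-phase genes. Points are weighted by n_y
(Var(log n_y) ~ 1/n_y).

Active-phase leakage into the window only ever *adds* counts and its share
grows with y, so the uncontaminated region is a prefix of the bins. The fit
therefore first grows a window from the head of the distribution, admitting
each next bin unless its observed log frequency exceeds the current line's
prediction by more than 2.5 sampling standard errors, and then runs Tukey
bisquare IRLS (tuning constant 4.685, 20 iterations) inside the window,
with residuals standardized by sqrt(n_y) and the scale floored at its
theoretical unit value. The slope is initialized from the two
most-populated bins (the ratio estimator lam = 2 n_2 / n_1) rather than
from a global OLS line: with heavy contamination the OLS line starts in the
contaminated basin and reweighting cannot escape it, whereas the head bins
are essentially clean by construction. The plain frequency-weighted OLS
estimator is retained (`robust=False`) purely as a contrast.

Given lam-hat and the intercept, N-hat = exp(intercept + lam-hat) is the
implied Poisson-part population; the zero-inflation mass comes from the
excess of observed zeros over N-hat e^{-lam}, reconciled with the total
background population B = N-hat/(1 - p0) in one fixed-point pass and
clipped to [0, 0.999]. Cells whose window cannot support the regression
(fewer than two distinct count values in 1..y_max) are flagged and imputed
with the cohort median — downstream stages need parameters for every cell;
if no cell succeeds the run aborts.

## Mixture fit

The active-phase pmf is the Poisson-lognormal integral, evaluated by
**adaptive Gauss-Hermite quadrature** (default 25 nodes): the rule is
centered at the mode of the log-concave integrand (found by Newton) with
node spacing matched to its curvature. A fixed rule centered at the prior
mean cannot resolve the Poisson kernel, whose width shrinks as 1/sqrt(y);
the adaptive rule is accurate to ~1e-10 relative over the ranges that occur
in practice. For Y >= 100 the Poisson layer is negligible and the lognormal
density of log Y (with the 1/Y Jacobian) is used instead.

Initial phase indicators set Z = 1 exactly where Y exceeds the cell's ZIP
0.999 quantile. EM then alternates:

- E-step: Z_gi = pi_g f_act / (pi_g f_act + (1 - pi_g) f_bg).
- M-step: pi_g is the mean posterior (exact maximizer). (mu_g, sigma2_g)
  are updated from Z-weighted mean/variance of log Y over cells with
  Y >= 1 — zeros are excluded because log 0 is undefined and a zero carries
  negligible active responsibility under any realistic mu. Because this
  moment update is not the exact maximizer of the Poisson-lognormal
  likelihood, it is wrapped as a **generalized EM step**: the candidate is
  accepted per gene only if it does not decrease the expected complete-data
  active log-likelihood, otherwise the previous parameters are kept. This
  makes the monotonicity of the log-likelihood trace a theorem rather than
  an empirical observation; on separated data the candidate is essentially
  always accepted.

sigma2 is floored at 0.01 (log scale) to prevent degenerate spikes. Genes
with less than 3 effective active cells are flagged non-estimable (mu
missing, posterior forced to background) — at initialization and again
after the final E-step, never mid-run, so the recorded trace reflects one
consistent model. Convergence: max absolute change in mu and pi below 1e-4,
cap 100 iterations. The EM is deterministic given the data; the `seed`
argument exists only for API uniformity. A single pass with log S = 0 is
the standard procedure; an optional second pass (refit with the estimated
offsets) exists behind a flag and is off by default.

Note that in the first pass sigma2-hat absorbs whatever log-scale spread
the technical factors have, on top of the biological dispersion — this is
expected and does not disturb the factor estimation, which works on
residuals.

## Normalization factors

Residuals eps_gi = log Y_gi - mu-hat_g are formed on the active set:
Z-posterior above 0.99, Y >= 1, gene estimable. Per cell, a natural cubic
regression spline with df = 5 (knots at quantiles of the abscissae,
truncated-power natural basis) is fitted to eps against mu-hat_g by
bisquare IRLS (3 rounds) — robust because the residual scatter is heavy
tailed at low expression. Outside the fitted abscissa range the curve
extrapolates as a constant, preventing wild spline tails from inflating S
for extreme counts.

Two abscissae are deliberately in play: curves are *fitted* against
mu-hat_g (the bias is a function of expression level) but *evaluated*, by
default, at the observed log count (`mode="at_count"`); evaluation at
mu-hat_g (`mode="at_mu"`) is available. The two agree on constant curves
and differ only through curve slope times within-gene count spread.

**Censoring correction.** Conditioning on the active call censors the
lower tail of low-rate observations: a gene near its call cutoff
contributes only its larger counts, biasing its residuals upward — visibly
so in cells with small S, where the same gene sits closer to the cutoff.
After an initial curve fit, each residual is debiased by the
truncated-normal mean shift sqrt(v) phi(a)/(1 - Phi(a)), where the cutoff
is the smallest count the posterior would call active (computed from the
fitted mixture on a 0..60 grid) and v is the cell's robust residual
variance; the curves are then refit once. The Poisson log-concavity term
E[log Y] - log E[Y] ~ -1/(2Y) is deliberately *not* removed: it is a
count-level distortion that belongs in the factor.

Fallback ladder for data-poor cells: fewer than 50 active residuals -> a
constant curve at the median residual; fewer than 10 -> the pointwise
median of the other cells' curves. Such cells are flagged. Finally all
factors are shifted so the reference-cell constraint holds exactly (the
operation is idempotent); if the reference cell is fully masked, the
unmasked cell with library size nearest the median substitutes, with a
warning.

Adjusted counts divide only unmasked entries; masked (background) counts
pass through untouched, and a recommended filter lists genes active in at
least 3 cells. Offset mode returns the masked log S matrix itself.

## Diagnostics

All diagnostics are pure functions returning tidy tables. Count-depth
statistics regress log2(Y+1) on log2 L per gene (genes with mean
log2(Y+1) > 4, the "reliably detected" filter; base and threshold
configurable) and report the Pearson correlation between the gene's values
and L — Pearson, not Spearman, matching the linear framing of the
count-depth relationship. MA tables plot log Y - mu-hat against mu-hat with
phase labels. Conditional SD ratios compare the SD of log expression over
active cells (>= 3 required) between normalized and raw data, stratified
into four quartile bins of mean active log expression; quartile binning is
our convention, as is emitting both all-cell and active-only variants of
the two-group log fold change (natural log of value + 1). The ARI utility delegates to scikit-learn's
adjusted_rand_score; its correctness is cross-checked in the tests against
an independent brute-force pair-counting oracle. A CPM-style size-factor
normalizer is included only as the contrast baseline, and a
drop-k-cells-and-refit utility quantifies fold-change stability.

## Simulator

The generator draws directly from the model above with one PCG64 stream
and a frozen draw order (gene mu, sigma, pi; cell p0, lam; bias; then the
Z, active and background matrices as single full-matrix draws), so a
(config, seed) pair is bit-reproducible. Three bias models: none (S = 1),
cellwise (S_gi = s_i, log-uniform), and smooth
(log S_gi = t_i q(mu_g) with per-cell log-depth t_i and a fixed positive
quadratic q), the last giving deeper cells uniformly larger factors while
the count-depth slope varies with expression — the phenomenon the method
targets. Group layouts add a depth multiplier through s_i and optional
true fold changes on a leading block of genes. Library-size heterogeneity
emerges from the bias and background parameters; it is not set directly.

Canonical fixtures (seeds fixed in `FIXTURE_CONFIGS`): `pure_zip`
(20,000 genes, background only), `contaminated` (5% low-active genes
leaking into the count window), `well_separated` (500 x 100, EM recovery),
`cellwise_bias` (10,000 x 60 — gene counts at the scale of real non-UMI
transcriptomes, so per-cell curves rest on thousands of residuals),
`smooth_bias` (3,000 x 80 with 15% depth-free background-only genes),
`overnorm` (depth effect confined to high-expression genes),
`unbalanced_depth` (4x depth ratio, no DE), `dge_spike` (100 genes at a
true 2-fold change).

What the simulator does **not** emulate: gene length and GC biases,
doublets, ambient RNA, cell-cycle structure, overdispersion beyond the
lognormal, or UMI protocols. Passing tests therefore establish internal
consistency of the estimators under the model's own assumptions, not
performance on any real dataset.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| y_max | 10 | upper count of the background regression window |
| robust_iters | 20 | bisquare IRLS rounds in the background fit |
| n_nodes | 25 | adaptive Gauss-Hermite nodes |
| max_iter / tol | 100 / 1e-4 | EM cap and parameter-change tolerance |
| sigma2_floor | 0.01 | lower bound on active-phase log variance |
| min_active_mass | 3 | effective active cells for a gene to be estimable |
| threshold | 0.99 | posterior cutoff for the active call |
| df | 5 | spline degrees of freedom ("a few") |
| min_curve_points | 50 | residuals needed for a per-cell spline |
| min_cells_active | 3 | recommended downstream gene filter |

Degenerate inputs: all-zero matrices and fully-failing backgrounds raise;
single cells work (the cell is its own reference); constant genes get
missing correlations; df is reduced with a warning when points are scarce.

## Known limitations

- A df-5 spline fitted to ~10^3-10^4 noisy residuals has an irreducible
  sampling wiggle of a few hundredths (log scale); per-cell curves are
  near-constant on pure cell-wise data in the median but individual cells
  can show ranges up to ~0.07.
- When a nontrivial fraction of genes changes in one direction between
  groups, the per-cell curves absorb a small part of that signal (the
  shared limitation of all residual-based normalizations); a true log-2
  fold change is recovered at ~0.6 rather than 0.69 on the spiked fixture.
- Residual censoring is corrected to first order via a truncated-normal
  shift; the skewness of low-rate Poisson log counts is not modeled.
- The method targets non-UMI protocols; UMI data violate the amplification
  model and need different treatment.
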