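# Methods

## Model

`panelnet` estimates a panel graphical vector autoregression (panel
GVAR) for short multi-wave panels of continuous scores. For subject
*i*, wave *t* and a *P*-vector of variables,

    y_it  = mu + b_i + eta_it
    eta_it = B eta_{i,t-1} + zeta_it

* `mu` — grand means, constant over waves (a wave-specific-means option
  exists; constant means is the default because the model targets
  stable within-person dynamics, not trends).
* `b_i ~ MVN(0, Sigma_between)` — between-person random intercepts that
  absorb stable individual differences; `Sigma_between` is positive
  semidefinite and estimated saturated by default.
* `zeta_it ~ MVN(0, Sigma_zeta)` — within-person innovations,
  positive definite, saturated by default.
* `B` — the temporal network. Rows index the outcome ("to"), columns the
  predictor ("from"); `B[i, j]` is the lag-1 effect of variable *j* on
  variable *i* controlling for all other variables and for the
  between-person structure. Effects are constrained equal across waves
  (stationarity), and the spectral radius of `B` must stay below 1.

Under stationarity the within-person covariance solves the discrete
Lyapunov equation `Sigma_eta = B Sigma_eta B' + Sigma_zeta`, and the
stacked T-wave observation vector is multivariate normal with
block-Toeplitz covariance `Cov(y_s, y_t) = B^(s-t) Sigma_eta +
Sigma_between` (s ≥ t). With three waves and saturated nuisance
covariances the model is identified: the lag-1 and lag-2 blocks differ
by one application of `B`, which separates the within- and
between-person parts.

Reported coefficients are standardized by the stationary within-person
standard deviations, `b_std[i, j] = B[i, j] * sd_j / sd_i`.

## Estimation

Parameters are estimated by full-information maximum likelihood (FIML):
subjects are grouped by missingness pattern and each pattern contributes
the exact likelihood of its observed sub-vector through pattern
sufficient statistics, so complete data reduce to the closed form in the
sample mean and covariance. The two covariance components are
parameterized by their Cholesky factors, making the optimization
unconstrained while keeping them PSD; a large penalty value rejects
iterates whose temporal matrix leaves the stationary region
(spectral radius ≥ 0.995).

The objective (average negative log-likelihood per subject) carries a
fully analytic gradient: derivatives flow through the block-Toeplitz
structure, through the Lyapunov equation via its adjoint (a second
Lyapunov solve with transposed coefficients), and through the Cholesky
factors by the standard chain rule. The gradient is verified against
central finite differences in the test suite. Optimization uses
L-BFGS-B from a moment-based warm start (pooled lag-1 regression for
`B`, a within/between moment split for the covariances) with up to three
seeded jittered restarts; convergence requires a gradient max-norm below
1e-6 on the per-subject scale, and non-converged fits are returned
flagged, never silently.

Standard errors come from the inverse observed information at the
optimum, computed by central differences of the analytic gradient
(verified exact against value-based second differences); Wald p-values
are two-sided normal. Model χ² is `2(loglik_saturated − loglik_model)`
against the unstructured saturated model (closed form when data are
complete, an EM algorithm over missingness patterns otherwise); note
that even with every temporal entry free the panel GVAR is a restriction
of the saturated model (the wave-constant structure equates blocks), so
its χ² has positive degrees of freedom. The baseline model for
incremental indices frees one mean and one variance per variable × wave
and sets all covariances to zero. CFI, TLI and RMSEA use the standard
formulas with `N − 1` in the RMSEA denominator; a model with zero
degrees of freedom has CFI = TLI = 1 and RMSEA = 0 by convention. BIC is
`−2 loglik + k ln(N)` with `N` the number of subjects.

## Model search

Following common practice for these models, the search starts from the
full (saturated-temporal) model and alternates two moves until the
structure is stable, treating lower BIC as better:

1. **Prune** — fix to zero, in one batch, all free temporal entries with
   Wald p ≥ α (default 0.05) and refit; if the batch worsens the BIC,
   single least-significant edges are tried instead until one removal
   improves it.
2. **Expand** — rank the fixed-zero entries by a score-test
   modification index computed from the gradient and observed
   information at the current optimum, then confirm the top candidate by
   an actual one-edge-freed refit; the edge is added only when its
   likelihood-ratio p < α and the BIC improves.

The modification index is a *ranking* device only: at a
boundary-restricted optimum the observed-information Schur complement
underestimates the efficient-score variance in this model, inflating the
score statistic relative to χ²(1) (it remains monotone in the LR
statistic, empirical correlation ≈ 0.998). All accept/reject decisions
therefore rest on the likelihood-ratio refit and the BIC guard, both of
which are empirically calibrated in the test suite. Ties among
candidates break by row-major (to, from) position in declared variable
order, so the search is deterministic given the data. Every accepted
move strictly lowers the BIC, which guarantees termination; a revisited
structure (possible only through numerically tied BICs) stops the search
at the best BIC seen.

A consequence of the alternation is that retained borderline edges are
re-tested after every refit; under a null network this drives the
expected number of chance edges in the final model *below* the
single-test share α·P², which is why the null-calibration check brackets
the retained-edge count in a band centered on α·P² rather than pinning
it there.

## Centrality

Centralities follow the directed-strength convention on the
standardized temporal matrix with self-loops excluded: instrength and
outstrength sum absolute incoming/outgoing weights; bridge in/out-degree
restrict the sums to edges crossing between the internalizing and
externalizing communities. Variables assigned to neither community are
transparent to bridge centrality. Absolute weights are the default
(centralities are then non-negative); a `signed` option sums raw
coefficients instead.

## Multi-group estimation and invariance

Groups are fitted jointly; the joint likelihood is the sum of group
likelihoods. Equality constraints tie selected temporal entries to a
single shared value across groups via an index-mapped parameter vector;
without constraints the joint fit equals the separate per-group fits
(additivity), which is how the unconstrained reference is computed.
Equality is tested by Δχ² = 2(ll_unconstrained − ll_constrained) with
Δdf = (G − 1) × (number of constrained edges); the omnibus test
constrains the full P×P matrix of a saturated-temporal multigroup model
(Δdf = P² for two groups) rather than sparse searched masks, because
only the full matrix makes every single-edge constraint well defined.
Group-specific model searches run independently of the invariance
machinery. Subjects with missing group labels are excluded from the
multigroup analysis only.

## Robustness

* **Edge-inclusion bootstrap** — resample subjects with replacement,
  rerun the entire model search, and report the fraction of successful
  replicates containing each edge; inclusion above 50% counts as robust.
  Failed or non-converged replicates are logged and excluded from the
  denominator; a warning attaches when more than 5% fail.
* **Case-dropping subset bootstrap** — drop `floor(0.2 n)` subjects
  without replacement, refit the *fixed* final structure (no re-search),
  recompute centralities, and report 2.5/97.5 percentile bounds.

Both arms draw per-replicate substreams from the master seed
(`SeedSequence.spawn`), so results are bit-identical for a given seed
whether replicates run sequentially or in parallel.

## Synthetic data

The generator mirrors the fitted model exactly: intercepts from
`Sigma_between`, the within process initialized at its stationary
distribution (so every wave is marginally stationary and three waves
suffice), innovations from `Sigma_zeta`. The default scenario uses the
canonical eight CBCL syndrome scales with the 20 published standardized
temporal edges as `B_true`, unit innovation variances, between-person
variance 0.5 per variable and zero means; innovation and between-person
structures are diagonal by default because no published counterpart
exists for them — they are deliberately arbitrary and documented as
such. A two-group scenario flips the sign of three externalizing →
other-scale edges between groups (±0.034…0.095, the published
female/male contrast), giving invariance tests a true positive.

An optional T-score transform `clip(50 + 10 z, 50, 100)` reproduces the
bounded, positively skewed, leptokurtic look of normed syndrome scores,
including the mass point at the floor of 50. Parameter-recovery tests
use the uncensored Gaussian output, matching the estimator's
assumptions; censoring is a stress-test mode that mimics how real
T-scores violate them. A single `mcar` fraction deletes cells completely
at random; no other missingness mechanism is modelled. What passing
tests show is therefore internal consistency of estimator and generator
under Gaussian stationarity — not robustness to the skew, floor effects
or informative missingness of real questionnaire data.

## Simulation sizes and numerical choices

Calibration checks use simulation sizes chosen to keep a full test run
routine: parameter recovery uses 20 replicates of n = 2000 subjects at
P = 8; the null-search calibration 50 replicates; the published-network
recovery check aggregates 12 replicates at n = 4000 (testing the mean
F1 and the median of the per-replicate maximum standardized-edge error,
since single-replicate extremes of ~20 retained edges are dominated by
sampling noise at SE ≈ 0.019); invariance calibration uses a 2-variable
panel (the Δχ² null distribution does not depend on P) with 500 null and
100 power replicates; the bootstrap checks use a 4-variable strongly
autocorrelated panel with 100 replicates. Degenerate inputs are handled
explicitly: empty temporal structures are valid models; constant columns
flag undefined skewness rather than crashing; singular implied
covariances and non-stationary iterates are rejected with penalties
during optimization and hard errors at the API boundary.

## Limitations

* With two waves and fully saturated covariances the model is not
  identified (the stationary structure provides too few distinct
  moment blocks); three or more waves are assumed throughout.
* The estimator assumes multivariate normality; with censored
  (T-score-like) data the fitted coefficients are attenuated and no
  correction is attempted, matching standard practice for these models.
* Wald-based pruning and LR-based expansion are asymptotic; at a few
  hundred subjects with P = 8 the saturated start is close to the limit
  of what the data identify, and searches there should be read as
  exploratory.
* The case-drop bootstrap quantifies stability, not sampling
  uncertainty; its intervals need not cover the point estimate.
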