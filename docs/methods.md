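# Methods

## Error model and conventions

All metrics assume the working hypothesis of Gaussian prediction errors,
ε = y_pred − y_true ~ 𝒩(0, σ²), with the predicted uncertainty σ interpreted
as a standard deviation in property units.  The sign convention is fixed as
prediction minus truth; absolute errors are derived on demand and never
stored.  Uncertainties are standard deviations at every public boundary —
variances appear only inside the NLL and the distance-to-variance maps.
Rows with σ ≤ 0 are hard input errors rather than silently dropped, because
silent filtering would bias every downstream metric; rows with missing
values are rejected with their indices reported.  CSV I/O is deliberately
rigid (comma separator, header required, '.' decimal, no locale inference)
and uses round-trip float parsing so that save → load is bit-identical.

## Simulated references

The raw values of ρ_rank and the NLL depend mostly on the predicted
uncertainty *distribution*, not on whether the uncertainties are right.
The simulated reference replaces an absolute reading with a self-consistency
check: errors are resampled as εᵢ ~ 𝒩(0, σᵢ²) (the signed draws are shared
between both metric branches; the Spearman branch takes |ε| internally), the
metric is recomputed per replicate, and the mean and standard deviation over
replicates (default 1000) are reported as "mean (sd)".  The discrepancy
(observed − mean)/sd is reported as a z-distance without a pass/fail
verdict: no decision threshold is imposed, the number is a diagnostic.
A closed form backs the NLL branch, E[NLL] = ½(ln 2π + mean ln σᵢ² + 1),
and is exposed as `expected_nll`.

Spearman ranking uses average ranks for ties, the standard convention that
keeps the statistic in [−1, 1].  A fully tied uncertainty list carries no
ranking information; the simulated reference then correlates against input
order (which averages to ~0 over replicates, as exchangeability implies),
while the direct `spearman_rank` of a constant list is reported as an error
rather than a number.

## Calibration curve and miscalibration area

The curve construction: a uniform grid of expected fractions q (100 interior
points plus endpoints by default), thresholds z_q = Φ⁻¹((1+q)/2) so that
P(|Z| ≤ z_q) = q under the standard normal, observed fraction =
proportion of |Zᵢ| ≤ z_q (non-strict).  This reproduces the standard normal
anchors — tail fractions 0.045 beyond |Z| = 2 and 0.003 beyond |Z| = 3 — and
the area between curve and diagonal is integrated by the trapezoid rule on
the same grid.  The construction was reverse-engineered from those printed
anchor fractions and the "scan |Z| > x until x = 0" description; no more
detailed published recipe was available, so the grid density is exposed as a
parameter.  For Z = s·𝒩(0,1) the area has the closed form
∫₀^∞ 2φ(z)·|2Φ(z/s) − 2Φ(z)| dz, which the tests evaluate by quadrature as
an independent oracle (0.0704 for s = 1.25 and s = 0.8 alike).

## Bootstrap intervals

Var(Z) ≟ 1 and μ(Z) ≟ 0 use bias-corrected and accelerated (BCa) percentile
intervals, computed through `scipy.stats.bootstrap` with 1000 resamples and
level 0.95 by default.  Var uses the unbiased (n−1) estimator, which keeps
the target-1 comparison honest at small n.  Two degenerate regimes are
handled explicitly: an all-identical sample yields a zero-width interval at
the point estimate, and a collapsed BCa interval (which occurs for
lattice-valued or bounded statistics, where the bias correction diverges)
falls back to the plain percentile interval with a warning.  Reported
intervals are clamped to contain the point estimate.

## Error-based calibration

Equal-count binning with a default of 250 samples per bin; the bin count is
derived from the data size, never the reverse.  A final remainder of at
least half a bin is kept as its own bin, otherwise merged into the previous
one — the published figures never state how a non-divisible test set is
handled, so this is the package's own convention.  Ties in σ at bin
boundaries are broken by stable input order for reproducibility.  The OLS
fit of RMSE on RMV is unweighted (per-bin CIs are diagnostic, not fit
weights), and the identity line, not the fit, is the calibration reference.

## Re-calibration

Three linear families, all fitted on a validation set:

- `rmv_linear` (σ_cal = a_val·σ + b_val from the validation RMSE/RMV fit)
  makes no Gaussian assumption;
- `nll_linear` minimises the validation Gaussian NLL over a linear map *of
  σ*.  Acting on σ rather than σ² is a choice: it keeps the map in the same
  family as `rmv_linear` so the two methods are directly comparable (the σ²
  alternative would be a different two-parameter family);
- `distance_variance` maps mean k-NN latent distances (k = 10, Euclidean by
  default) to variances via V(d) = θ₀² + θ₁²·d, or the flexible
  V(d) = θ₀ + θ₁²·d whose negative-offset freedom requires the variance
  floor: V < 0 is clipped to 10⁻⁴.

The same 10⁻⁴ variance floor (σ floor 0.01) is applied to the output of
every linear map, not only the flexible one, because any affine map of σ can
go non-positive and every downstream metric requires σ > 0.

NLL minimisations use deterministic multi-start Nelder–Mead (moment-based
initial guesses — an OLS fit of ε² on d, or the RMSE/RMV scale ratio — plus
fixed perturbations) with tolerance 10⁻⁸; non-convergence is flagged on the
returned model, which still carries the best point found.  The optimisation
surface is two-dimensional and benign; multi-start guards against the
occasional flat direction when θ₁ ≈ 0.

## Synthetic scenarios

The generators are pure functions of their arguments including the seed.

- The σ-grid generator draws εᵢ ~ 𝒩(0, σᵢ²) with the generating σ recorded
  as the uncertainty, so the data are exactly calibrated by construction:
  Var(Z) → 1, A_mis → 0, and the error-based fit → (a=1, b=0, R²≈1) as the
  sample grows.  This single generator provides the null for every metric.
- The default grid runs 0.5 to 10 in steps of 0.01 (951 values).  The step
  and the highlighted 0.5–1.5 subrange are fixed by the toy construction;
  the end points 0.5 and 10 are this package's inference from the half-grid
  NLL values they reproduce (closed-form expectations 2.28 on [0.5, 5] and
  3.42 on (5, 10], against quoted single-realization values 2.33 and 3.39
  with single-realization sd ≈ 0.03).
- The scale-mismatch scenario multiplies errors by 1.25 where σ ≤ 5 and by
  0.8 above, leaving uncertainties unchanged.  Each half then has
  miscalibration area ≈ 0.07 while the pooled area nearly cancels — the
  canonical demonstration that A_mis is blind to compensating local
  miscalibration.  Samples exactly at the threshold take the low factor.
- The cubic toy draws x uniformly and y = x³ + ε with aleatoric noise sd 3;
  train range [−4, 4], with the [−6, 6] test range placing one third of the
  samples out of distribution.  No model is trained here — the module only
  generates data for users to plug their own estimator into.

What the generators do *not* emulate: non-Gaussian error tails, heteroscedastic
bias (μ(Z) ≠ 0 coupled to σ), correlated errors, and the coupling between a
model's accuracy and its uncertainty estimates that real ML models exhibit.
Passing the null suites therefore shows the metrics are correct under the
Gaussian working model, not that any particular UQ method is well calibrated
on real chemical data.

## Problem sizes and determinism

Default report settings: bin size 250, 1000 bootstrap/simulation replicates,
level 0.95.  A report is a pure function of (input data, config): one
top-level seed is streamed via `numpy.random.SeedSequence` to every
randomised sub-computation.  Test-suite simulations use 50–500 replicates
and sample sizes of 10²–10⁶ chosen so each distributional assertion has
comfortable Monte-Carlo margin (coverage checks use ≥400 replicates at
±0.03–0.035 around the nominal 0.95; moment-recovery checks assert within
3–4 standard errors).  The acceptance script averages 200–500 seeded
realizations per quantity.

## Known limitations

- All likelihood-based quantities assume Gaussian errors; with heavy-tailed
  errors A_mis and the NLL conflate miscalibration with distribution shape
  (the Var(Z)/μ(Z) tests are the distribution-free alternative).
- Re-calibration is linear only; a strongly nonlinear σ↔error relation needs
  a different family and will show as residual structure in the error-based
  plot after re-calibration.
- Equal-width or adaptive binning schemes and confidence curves are out of
  scope.
- The BCa percentile fallback slightly changes the interval's higher-order
  accuracy in the degenerate regime; the fallback is warned about and only
  triggers where BCa itself is undefined or collapsed.
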