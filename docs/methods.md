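# Methods

## The physical model

Weak, transient domain–peptide interactions — the SH3/proline-rich-motif
system is the motivating case — are poorly described by a single rigid
binding site. A short array peptide of length *N* offers *N − S + 1*
contiguous *S*-residue windows to a domain whose footprint covers *S*
residues, and a transiently bound domain shuttles between them. Treating each
window *σᵢ* as an independent docking site with its own free energy
*G_P(σᵢ)*, the configuration integral of the complex is the sum of per-site
integrals, giving the ensemble ("multiple-site", MS) free energy

    G = α − ln Σᵢ exp(−G_P(σᵢ))        (all energies in RT units)

so additional competitive sites can only lower the total energy (raise the
bound population). The conventional single-site (SS) picture scores one fixed
representative window *σ_r* with the same additive expansion and no ensemble
sum.

Per-window energies use a reference-sequence expansion truncated at single
residues:

    G_P(σ) = J₀ + Σₛ J[s, aₛ],   J[s, ref(s)] ≡ 0,

equivalently a linear function of an indicator encoding with one intercept
element plus 19 indicator slots per window position (the reference residue is
not counted). Higher-order (pairwise) terms are out of scope by design: their
parameter count is not supportable at ~1,000 observations per domain.

The observable is the pseudo-binding energy −ln(BLU) of a SPOT-array spot,
treated as the dimensionless free energy with additive error. The offset α
absorbs the imperfect affine mapping from light intensity to free energy.

## Identifiability conventions

* In the MS model, J₀ and α are exactly confounded
  (α − ln Σ exp(−J₀ − …) = α + J₀ − ln Σ exp(−…)), so `MSModel` fixes J₀ = 0
  and α carries the offset.
* The per-position reference residue is a parameterization convention, not a
  physical choice. The default policy is `most_frequent` (modal residue over
  training windows, ties alphabetical); `fixed_alanine` is provided for
  reproducibility experiments. `EnergyParams.reparameterized` converts a
  fitted table between conventions without changing any prediction, which is
  how recovery experiments compare fitted J tables with a ground truth
  expressed in a different convention.
* α enters additively. The alternative (a multiplicative scale on the
  log-sum-exp) was considered and rejected: the offset reading matches an
  affine intensity-to-energy calibration error, which is the stated role of
  the parameter.

## Fitting

**MS.** Nonlinear least squares on the residuals
G^SPOT − (α − ln Σ exp(−F·J)) with an analytic Jacobian (per-record softmax
weights times the window design matrix), solved by scipy's bounded
trust-region reflective method. J is box-bounded to ±20 RT — far outside any
plausible single-residue contribution — to keep rare features from diverging.
The objective is non-convex, so `n_restarts` independent starts are run and
the lowest-SSE solution kept: restart 0 starts from J = 0 (deterministic and
typically sufficient on clean data), later restarts from
J ~ Uniform(−`init_spread`, +`init_spread`) with `init_spread` = 1 RT.
α starts at the mean observed pseudo-energy. Columns of the window design
never observed in training are excluded from optimization and fixed at J = 0,
so predictions on unseen residues fall back to the reference energy and
repeated fits are bit-identical. Tolerances (`convergence_tol`, default
1e−10, applied as ftol/xtol/gtol) and `max_iterations` are configurable;
log-sum-exp is always computed with max-shift stabilization.

**SS.** Ordinary least squares of the pseudo-energies on the site-*r*
encoding, solved by a rank-revealing (SVD-based) decomposition; unobserved
columns are dropped and restored as zeros. No regularization by default; an
optional ridge penalty on J (never the intercept) is available for
ill-conditioned small designs.

## Evaluation protocol

Records are permuted by a seed and dealt round-robin into k folds (k = 10;
1,000 records give ten folds of 100). MS cross-validation is two-pass: pass 1
fits every training set with free α and the median of the k α values is
selected; pass 2 refits each training set with α fixed at that median, then
scores the held-out fold. The error metric is the normalized RMSE — RMS
prediction error divided by the test fold's sample standard deviation (ddof
= 1, a recorded choice: the mean predictor then scores √((n−1)/n), not
exactly 1). SS cross-validation additionally scans every candidate site
offset r ∈ {0 … N_min − S} (N_min = shortest peptide, so every record carries
the site) and keeps the offset with minimal mean normalized RMSE, ties to the
smaller r.

Window scans run the matching cross-validation per S; for the MS model the
full-length window is excluded from best-S selection when smaller sizes are
available (at S = N the ensemble degenerates to a single site). Ties break
toward the smaller S (parsimony). `compare_models` pairs the best-S fold
errors of the two scans on identical folds and reports the per-fold percent
decrease 100·(RMSE_SS − RMSE_MS)/RMSE_SS, its mean and its sd. Computing the
ratio per fold and then averaging (rather than the ratio of averages) is a
recorded choice; the difference is second order.

## Localization (MLP)

The maximum local population of a peptide is the largest Boltzmann occupancy
among its windows, L_max = exp(−G_P(σ_min)) / Σᵢ exp(−G_P(σᵢ)) ∈ (0, 1]. α
cancels algebraically and does not enter. L_max = 1 means fully localized
binding; two near-equal strong sites give ≈ 0.5; n equal sites give 1/n.
Reports are sorted by predicted ensemble energy; TSV output rounds
occupancies to 6 decimals (JSON keeps full precision). Interpretation bands
(e.g. "localized above 0.7") are descriptive annotations, never algorithmic
thresholds.

## The synthetic-data generator

`simulate` emulates the structure of one domain's array: by default 1,000
peptides, a 50/50 mix of 13- and 14-mers, residues i.i.d. uniform over the
20 canonical amino acids (an optional motif pattern such as `PxxP` can be
embedded at a uniform random offset; an optional residue-frequency table
supports proline-enriched compositions), a fresh ground-truth model with
J ~ N(0, 1) RT over an alanine reference, α_true = 5 RT (placing ensemble
energies in a plausible small-negative range), and Gaussian noise of sd
0.1 RT added on the energy scale — hence log-normal intensity noise, matching
the additive-error fitting model. Intensities are back-computed as exp(−E),
so the −ln(BLU) invariant holds exactly.

What the generator does *not* emulate: spot-density, purity and washing
artifacts of real membranes (beyond the single additive noise term),
proteome-derived sequence composition, replicate spots, and the real BLU
dynamic range (not published). Passing recovery tests therefore demonstrate
correctness of the estimator under the stated noise model, not performance
on real arrays.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen so the data/parameter ratio matches the canonical
setting (1,000 observations for ~115 free parameters, ratio ≈ 9):

* Parameter recovery runs at the canonical scale (n = 1000, true S = 6).
* Cross-validation unit tests use 200–300 length-8 peptides with true S = 3
  (ratio ≈ 4–5). At very small n (150) the noiseless CV error is dominated by
  finite-sample generalization (~0.06 normalized RMSE), not optimizer error.
* The MS-vs-SS direction runs use 300 length-10 peptides, true S = 4, scans
  over S ∈ {3, 4, 5}, 10 folds, 2 restarts; the sign of the percent decrease
  is the quantity of interest and is insensitive to these sizes.

## Numerical and degenerate-input choices

* Log-sum-exp: max-subtraction everywhere; documented relative tolerance
  1e−12.
* Peptides shorter than the window (or the SS site span) are skipped with a
  logged warning, not fatal — real arrays mix 13- and 14-mers.
* Non-canonical residues (B, J, O, U, X, Z) are rejected with an error naming
  the offending character and position; no silent imputation. FASTA tiles
  containing them are skipped with a warning.
* Fits require ≥ 2 distinct sequences (MS) or ≥ 2 records (SS); constant
  observed vectors make the normalized RMSE undefined and raise.
* TSV numerics carry 12 significant digits; a write→read cycle is accurate to
  ~1e−11 relative and idempotent thereafter. Model JSON round-trips are
  lossless to full float precision.

## Known limitations

* The MS objective is non-convex; restarts mitigate but cannot guarantee the
  global optimum. On single-site-generated data the landscape is noticeably
  harder (the MS parameterization has no exact representation of a
  site-specific function) and fits take many more iterations.
* With free α and near-complete off-reference designs, α trades off against
  per-position J levels along a nearly flat direction; predictions are
  unaffected, but fitted α values from small folds scatter — which is exactly
  why the evaluation protocol fixes α at the fold median before scoring.
* No uncertainty quantification on J (no posterior, no bootstrap); the
  cross-validated error is the only generalization diagnostic.
* Structure-based energy evaluation and consensus derivation from selection
  experiments are out of scope.
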