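# Methods

## Model

A community of `N` species with abundances `x_i` evolves under replicator
dynamics on the simplex:

    dx_i/dt = x_i (f_i - phi),      phi = sum_j x_j f_j,
    f_i = -x_i + sum_j A_ij x_j + sum_{jk} B_ijk x_j x_k
          + sum_{jkl} C_ijkl x_j x_k x_l.

The `-x_i` term encodes self-limitation of an inherently stable community;
`A`, `B`, `C` are random pairwise, three-way and four-way interaction
tensors; subtracting the abundance-weighted mean growth rate `phi` keeps the
total abundance fixed at 1, modelling a community whose total biomass is set
externally (nutrients, space).  Three- and four-way terms model one or two
species modulating the interaction between two others — e.g. degradation of
an antibiotic that mediates a pairwise inhibition, or behavioural
(trait-mediated) effects.

Interaction strengths are **variances**: `A = sqrt(alpha) * A~` where `A~`
has standardized entries (mean 0, variance 1 on the nonzero support), and
likewise `beta`, `gamma` for `B`, `C`.  Only this reading reproduces the
single-order stability conditions `alpha < 1/N`, `beta < 1`, `gamma < N`
and the measured threshold scalings; the strength-as-standard-deviation
alternative predicts half-slopes, which the simulations reject.

### Index conventions for the high-order tensors

The baseline tensors exclude the focal species from its own high-order
terms: `B_ijk` is nonzero only for `j, k != i` (repeats `j == k` allowed),
and similarly for `C`.  A high-order interaction is by definition a
modulation of the focal species' pairwise interactions *by other species*;
self-modulation terms are not part of that mechanism.  This choice matters
only at small `N` (at `N = 4`, over half of an unrestricted four-way
variance budget would sit in self-involving terms) and is what makes the
measured threshold scaling exponents match the analytic ones at desk scale;
`exclude_focal=False` restores fully unrestricted sums.  Two further
structural variants are exposed for robustness work: `exclude_diagonal`
(all indices pairwise distinct) and `strict_order` (only `j > k (> l)`
kept).  Both were evaluated while calibrating the baseline and rejected:
their per-species term counts are so small at `N <= 8` that the four-way
threshold-versus-`N` curve becomes U-shaped (measured slope ~ -0.1 instead
of ~ +0.9), so they serve as robustness switches, not as the baseline.
Non-Gaussian entry distributions (uniform on `[-sqrt(3), sqrt(3)]`,
standardized Laplace) are available; the stability theory depends only on
the variance.

A Lotka-Volterra variant (`dx_i/dt = x_i f_i`, no normalization) is
included as a labelled reconstruction — its published form is not available
to us — and is kept out of all quantitative reproduction targets.

## Integration and the persistence criterion

Simulations start from the uniform state `x_i = 1/N` and use adaptive
Runge-Kutta 4(5) (`scipy.integrate.RK45`) with relative tolerance `1e-3`
and absolute tolerance `1e-6` (the classic ode45 defaults).  Every
`chunk = 10` time units, with elapsed time `T`, the species-distribution
entropy `H = -sum x_i log x_i` is evaluated on a dense grid (spacing 0.1,
taken from the integrator interpolant so extrema do not depend on adaptive
step placement).  The run is declared *persistent* when

    min H over [0.9 T, T] / min H over [0.7 T, T]   and
    max H over [0.9 T, T] / max H over [0.7 T, T]

both lie within `entropy_tolerance` of 1; this accepts fixed points and
bounded oscillations alike.  The first check happens at `T = 100` so the
three-tenths window spans several chunks.  Runs that never pass are stopped
at `t_max = 1e4` with status `timeout`.  Diverging trajectories (possible
once abundances overshoot the simplex under strong interactions) are
status `failed`, warned about, and excluded from feasibility tallies;
measured failure rates near thresholds are 0-2%, so this choice does not
move thresholds materially.

**Choice of `entropy_tolerance` (default `1e-3`).**  The window test has no
convergence limit as the tolerance shrinks — extinctions are asymptotic, so
the tolerance (like `t_max`) encodes how long one waits.  At `1e-2` the
criterion routinely declares persistence while slow extinctions are still
in progress, which visibly flattens the threshold scaling (pairwise
exponent -0.66 instead of ~ -1.1); at `1e-3` and `1e-4` the measured
exponents are stable to within their fit errors (pairwise -1.08 vs -1.26,
three-way -0.10 vs +0.08, four-way +0.87 vs ~ +0.9 at reduced scale).
`1e-3` is the default; the cost roughly doubles at `1e-4`.

**Feasibility.**  A community is feasible when every final abundance
exceeds `1e-5 / N` (tiny negative values are zeroed only at
classification).  The conservative variant additionally requires
persistence, counting timeouts as infeasible; it feeds the lower error
bars of threshold estimates, while the main estimate classifies timeouts
by their final abundances.

## Thresholds

Feasibility probabilities are estimated on a *fixed collection* of `R`
seeded communities (common random numbers), making infeasibility monotone
in strength in practice.  The critical strength of an order is the first
strength at which the infeasible fraction reaches 5% of the collection,
with the 2% and 10% crossings as the bracket.  The search is a geometric
coarse scan (factor 1.3) from an analytic starting guess, followed by
bisection in log-strength to 5% relative width.  Replicate evaluation stops
as soon as a quantile comparison is decided; because replicates are
independently seeded and visited in fixed order, results are identical to
exhaustive evaluation.  The two-dimensional `(alpha, gamma)` boundary is
traced along radial rays `alpha = 0.001 * 1.2^(r cos theta)`,
`gamma = 0.05 * 1.3^(r sin theta)`, increasing `r` in steps of 0.5 until
the 5% quantile is crossed and bisecting in `r`; the ray increment and
refinement rule are implementation choices.

## Stability theory

Linearizing `f` around a state folds the high-order terms into an
effective pairwise matrix

    A_eff_ij = A_ij + sum_k (B_ijk + B_ikj) x_k
               + sum_{kl} (C_ijkl + C_ikjl + C_iklj) x_k x_l.

Near a coexistence fixed point `x_i ~ 1/N`, the entries of the random part
of `A_eff` are sums of independent coefficients, so variances add; by
Girko's circular law the eigenvalues fill a disc whose squared radius
defines the stability margin

    margin = N alpha + beta + gamma / N   (strictly ordered convention),

stable iff `margin < 1` (the boundary counts as unstable).  With
unrestricted or modulation-only index sums the two high-order terms carry
constant combinatorial factors (2 and 3 asymptotically) that leave the
scaling with `N` untouched; `girko_margin` exposes both conventions, and
`thresholds.margin_factor` gives the exact finite-`N` counts per
structural variant.  The same margin, viewed as the quadratic
`alpha N^2 - (1 - beta) N + gamma < 0`, yields lower and upper bounds on
the number of species (computed with the cancellation-free quadratic
formula); they close at `N* = sqrt(gamma / alpha)` when the discriminant
`(1 - beta)^2 - 4 alpha gamma` vanishes.  The exact replicator Jacobian
additionally carries normalization derivatives; these are implemented
exactly in `dynamics.jacobian`, so the quality of neglecting them is a
testable statement (the leading-eigenvalue signs of the exact and
approximate Jacobians agree on >= 95% of weak-interaction fixed points)
rather than an assumption.

## Experiments and problem sizes

The scaling experiment measures critical strengths per order on
`N in {4, 6, 8, 12, 16, 24}` with `R = 100` communities per `N` (one fixed
collection per `N`, shared across orders) and fits ordinary least squares
to `log10(threshold)` versus `log10(N)`; the slope's standard error is the
OLS standard error.  This reduced, desk-scale protocol runs in a few
minutes on one CPU; `R = 300` with a denser grid (the full protocol) is
available behind `--full-scale`.  Measured exponents at reduced scale are
about -1.1 (pairwise), -0.1 (three-way) and +0.9 (four-way): interactions
of every order destabilize, but diversity *raises* the tolerance to
four-way interactions while lowering it to pairwise ones.

The diversity-curve experiment evaluates the feasible fraction versus `N`
at fixed `(alpha, gamma)` (with `beta = 0`, `R = 50` per point) for three
regimes, each over the diversity range where its shape expresses itself.
The regime strengths and grids were fixed by a pilot calibration against
precisely measured (`R = 150`) single-order and mixed curves:

* pairwise-dominated `(0.1, 0.1)` on `N in {4, 6, 8, 12, 24}` — feasibility
  falls from ~0.75 to 0 (diversity bounded from above);
* four-way dominated `(5e-4, 5.0)` on `N in {12, 20, 30, 42}` — feasibility
  rises from ~0.27 to ~0.9 (bounded from below);
* mixed `(0.0075, 2.0)` on `N in {4, 6, 8, 12, 16, 24, 36}` — an interior
  plateau near 0.74 against ends near 0.65 and 0.37 (both addition and
  removal of species destabilize).

Two desk-scale effects shaped these choices.  First, below `N ~ 10`
four-way-only feasibility saturates around 0.3-0.6 regardless of strength:
a species has too few independent tensor entries for the Gaussian
variance picture, and strong quartic terms create alternative persistent
states (often bounded oscillations).  The four-way-dominated rise is
therefore examined from `N = 12` upward, and the mixed case uses a
moderate `gamma` below the saturation regime.  Second, combining pairwise
and four-way disorder is distinctly more destabilizing in the mid-`N`
range than independent variance addition predicts, which rules out deep
interior peaks from strong-`gamma` mixtures; the mixed regime instead
pairs a sub-saturation `gamma` with a pairwise strength that only bites
at the top of the range.

The bounds diagram is purely analytic: the diversity bounds along a fixed
ratio line `gamma = 1e3 alpha` (or with `beta = gamma`), closing at
`N* = sqrt(1e3) ~ 31.6` where `4 alpha gamma = (1 - beta)^2`.

## What the synthetic ensembles do and do not capture

All inputs are internally generated random tensors: i.i.d. standardized
entries, full connectance by default, no trophic structure, no
reciprocity correlations, no degree heterogeneity, and no demographic
noise, migration or explicit resources.  Passing tests therefore
demonstrate properties of the *random-interaction null model* — the
diversity-stability inversion with interaction order, and the resulting
diversity bounds — not predictions for any structured empirical food web.
Determinism is exact for fixed seeds on one platform; per-replicate
seeding makes every experiment row regenerable independently of the rest
of its grid.

## Known limitations

- The entropy-ratio persistence test assumes non-negative entropy terms;
  for the Lotka-Volterra variant (total abundance not conserved) the
  criterion is applied unchanged and is less principled.
- Thresholds inherit a weak dependence on `entropy_tolerance` and `t_max`
  (how long one waits for slow extinctions); the defaults are documented
  above and exposed.
- At `N <= 4`, high-order feasibility statistics are dominated by
  small-sample effects of the few independent tensor entries; analytic
  margins are poor guides there.
- Spectral sampling at `N = 200` uses dense eigendecomposition; no sparse
  or very-large-`N` path is provided.
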