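# Methods

## Model and assumptions

The package models a price-volume agreement as first-order exponential decay
of the per-patient price over the cumulative number of treated patients:

    PRICE(Npt) = fPRICE · exp(−k · Npt)

The form is borrowed from one-compartment pharmacokinetics with patients in
place of time; its single substantive assumption is that each additional
treated patient reduces log-price by a constant amount. The model is
deliberately one-factor: clinical benefit, cost-effectiveness at full price
and other negotiation drivers are not modelled, and the x-axis is cumulative
patients, not calendar time — there is no discounting or inflation.

The decay is summarised as the **price-halving population**,
PHP = c / k, with c = 0.693 by default. The 3-decimal constant (rather than
exact ln 2) is the convention used in the worked national examples the
fixtures reproduce, and matters for parity with their quoted PHPs at the
whole-patient level; exact ln 2 is available everywhere via
`half_life_const` (the CLI's `--half-life-const ln2`). All intermediate
arithmetic is full double precision — reproducing the quoted PHPs requires
the *unrounded* decay constant, since 4-decimal rounding of the logs already
shifts PHP by several patients.

## Fitting

- **Two points** determine the model exactly:
  k = (ln p₁ − ln p₂)/(n₂ − n₁). The first observation usually sits at
  n = 0 (the full price is public even when the agreement is confidential),
  in which case fPRICE = p₁; otherwise fPRICE is back-extrapolated.
  Rising prices are rejected — a price-volume agreement is non-increasing by
  construction. Equal prices yield k = 0 and an infinite PHP sentinel rather
  than an error: a flat price is a legitimate no-discount agreement.
- **More than two points** fit by ordinary least squares of ln(price) on
  volume (the model is linear there), optionally with the intercept pinned at
  a known full price (one-parameter constrained fit). With exactly two points
  OLS coincides with the exact fit. A negative fitted k (price rising, which
  noise can produce) is returned flagged via `rising_price`, never clamped —
  the caller decides. OLS fits carry the residual standard error of the
  log-price regression; no confidence intervals are reported for two-point
  fits (they are undefined).

Volumes are accepted as real numbers, not integers only: observed volumes may
be prorated (e.g. vials divided by vials per course). Money is real-valued
EUR throughout; rounding to whole euros/patients happens only in the
human-readable reports (the JSON output always carries full precision). The
arithmetic is currency-agnostic; EUR is a label.

## Expenditure

Total expenditure over n treated patients is the area under the price-volume
curve, computed two ways and cross-checked:

- analytic: fPRICE·(1 − e^{−kn})/k (fPRICE·n when k = 0);
- composite trapezoidal rule with uniform step and an exact final partial
  panel. The integrand is convex, so the trapezoid estimate bounds the
  analytic value from above with error O(step²). The CLI's default step is
  max(1 patient, n/100 000) and every report states the step actually used,
  so a default change can never silently move reported numbers.

The average cost per patient is total/n, algebraically identical to
(fPRICE − PRICE_last)/(k·n) with PRICE_last the modelled price at n; both
forms are implemented and asserted equal to 1e−12 relative. The candidate
populations anchoring the fixtures' quoted averages are 20 000 (ranibizumab)
and 60 000 (sofosbuvir) — the volumes of their second observations.

NWBI (nationwide budget impact) is the undiscounted worst case
fPRICE × totPT, kept deliberately distinct from the decay-adjusted total.

**Inverse problem.** Given fPRICE, totPT and a budget cap below the
undiscounted spend, the required decay constant solves
total(k) = cap. total(k) is strictly decreasing in k, so the root is unique;
it is found with SciPy's Brent method on the bracket [0, k_hi] with
k_hi = ln(fPRICE/0.01) (decay so fast the price reaches one cent within one
patient), doubled in the pathological case that bracket is insufficient.
Brent on a guaranteed bracket retains bisection's unconditional convergence
while converging faster; the solution satisfies |total − cap|/cap < 1e−10. A
cap at or above the undiscounted spend returns the flat model (k = 0, the
no-discount case).

**Tier schedule.** Real agreements are stepped, not continuous. Each volume
band [lo, hi) receives the volume-averaged model price over the band (band
AUC / band width), which conserves the continuous model's expenditure over
every whole band exactly.

## Nomogram

Each settled agreement contributes a reference point
(NWBI, 100 · PHP / totPT). Queries interpolate the percentage linearly in
**log10(NWBI)**: NWBI spans orders of magnitude (hundreds of millions to
tens of billions of euros), so raw-linear interpolation would let the larger
reference dominate everything below it. This axis choice is a package design
decision and is recorded in the nomogram's interpolation field so files are
self-describing.

Outside the reference range the nearest endpoint's percentage is returned
with an explicit `extrapolated` flag — never silently — since a two-point
reference set supports no extrapolation claim at all. Flat-price agreements
(infinite PHP) carry no decay information and are excluded from construction
with a warning. The shipped reference nomogram is *reconstructed*: the two
fixtures' candidate populations come from public reporting, not from the
confidential agreements, so its predictions are indicative.

## Synthetic data

The generator draws volumes evenly spaced (optionally uniform-random) on
[0, n_max] and perturbs the model price multiplicatively:
price_i = PRICE(n_i) · exp(ε_i), ε_i ~ N(0, σ²). Log-normal noise is the
default because it is exactly Gaussian on the scale the OLS fit works on and
keeps prices strictly positive; additive EUR noise is available as an option.
Volumes are noise-free — the payer counts patients exactly. Identical spec
and seed yield an identical dataset.

Default conditions for recovery experiments: 50 points on [0, 50 000]
patients, σ = 0.05 (≈5% price noise — the scale of the approximation already
present in publicly reported agreement figures). Under these conditions the
suite verifies median relative error of the recovered k below 5% over 200
replicate seeds, estimator bias below 1% of k, and spread shrinking with
more points. What passing shows: the fitting pipeline is correct and
well-behaved under the stated noise model. What it does not show: real
agreements need not decay exponentially, real price observations are few,
rounded and possibly systematically (not independently) wrong, and volumes
themselves may be estimates — none of which the generator emulates.

## Numerical choices and degenerate inputs

- Exact two-point fits and the closed forms are evaluated directly in double
  precision; paper-parity tests use ±1 EUR / nearest patient, the quoted
  figures' own presentation rounding.
- k = 0 is an ordinary value everywhere (flat price): PHP is an infinite
  sentinel, expenditure degenerates to fPRICE·n, tiers to fPRICE.
- Duplicate volumes, fewer than two points, non-positive prices, non-positive
  populations and non-ascending band edges raise typed errors
  (`DegenerateInputError`, `DomainError`, `MonotonicityError`).
- In OLS, exactly constant prices short-circuit to k = 0 so that float noise
  in the regression cannot produce a spurious minuscule decay.

## Problem sizes

Everything here is desk-scale: two-point fits, closed-form integrals, a
one-dimensional root find and OLS on tens of points. The largest computation
in the test suite is the 200-replicate recovery experiment (200 OLS fits of
50 points); the full suite runs in a few seconds.

## Known limitations

- One factor only: the NWBI→PHP relationship is clearly multi-factorial and
  a two-point nomogram cannot capture that; predictions are starting points
  for negotiation, not answers.
- Calibrated to one national market's worked examples; other jurisdictions
  need their own reference agreements.
- No rebate/payback mechanics (capitation, payment-by-result) and no
  alternative decay shapes — those are different agreement classes.
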