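# pvagree — price-volume agreement modelling

Price-volume agreements let a national payer afford a high-cost drug with a
large eligible population: the per-patient price falls, by contract, as the
cumulative number of treated patients rises. `pvagree` is a small library and
command-line tool for payers, HTA analysts and health economists that puts a
quantitative model behind such agreements.

## The model

The price decay is first-order exponential in the cumulative number of
treated patients, exactly as drug concentration decays in time in elementary
pharmacokinetics:

```
PRICE(Npt) = fPRICE · exp(−k · Npt)
```

- `Npt` — cumulative number of treated patients (the x-axis),
- `fPRICE` — full price per patient at `Npt = 0` (public even when the rest
  of the agreement is confidential),
- `k` — first-order decay constant (patients⁻¹).

The characteristic scale of the decay is the **price-halving population**,
`PHP = 0.693 / k`: the number of patients over which the price halves (the
model's "half-life" in patients; exact `ln 2` is available via
configuration). Because the model is linear in log-price, two observed
(patients, price) pairs determine it exactly, and larger datasets fit by
ordinary least squares on `ln PRICE`.

From a fitted model the package computes:

- **total expenditure** over `n` patients — the area under the price-volume
  curve, in closed form `fPRICE·(1 − e^{−kn})/k` or by the trapezoidal rule;
- **average cost per patient** — total divided by `n`, equivalently
  `(fPRICE − PRICE_last)/(k·n)`;
- **NWBI**, the nationwide budget impact `fPRICE · totPT` (full price times
  the whole candidate population — the undiscounted worst case);
- the **inverse problem**: the decay constant a payer must impose so that
  total expenditure over the candidate population meets a budget cap;
- a **tiered schedule**: flat per-band prices that conserve the continuous
  model's expenditure band by band;
- a **nomogram** relating NWBI to PHP as a percentage of `totPT` across
  settled agreements, to suggest a PHP for a new drug from its NWBI.

Two reconstructed national agreements ship as fixtures: ranibizumab in
macular degeneration ((0, 9 050), (20 000, 6 500) EUR) and sofosbuvir in
hepatitis C ((0, 37 500), (60 000, 4 000) EUR).

## Worked example

```sh
$ pvagree fit --pair 0 9050 --pair 20000 6500
fitted model on 2 points
  full price fPRICE : 9,050 EUR
  decay constant k  : 1.65481e-05 patients^-1
  PHP (c=0.693) : 41,878 patients
```

The price of ranibizumab halves roughly every 41 878 treated patients. The
budget report for the shipped agreement (same fit, candidate population
20 000):

```sh
$ pvagree expenditure src/pvagree/data/ranibizumab_agreement.json
agreement report: ranibizumab
  NWBI (full price x totPT)  : 181,000,000 EUR
  decay constant k           : 1.65481e-05 patients^-1
  PHP (c=0.693)        : 41,878 patients
  total expenditure (analytic): 154,095,970 EUR over 20,000 patients
  total expenditure (trapezoid, step=1): 154,095,970 EUR
  average cost per patient   : 7,705 EUR
```

Treating 20 000 patients under the decaying price costs 154.1 M EUR rather
than the undiscounted 181 M EUR — an average of 7 705 EUR per patient against
the 9 050 EUR full price. The sofosbuvir agreement gives k ≈ 3.73 × 10⁻⁵,
PHP ≈ 18 579 patients and an average cost of ≈ 14 968 EUR over 60 000
patients. Add `--json` before the subcommand for full-precision
machine-readable output; `pvagree nomogram --builtin --f-price … --tot-pt …`
suggests a PHP for a new drug from the two-point reference nomogram.

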