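# npkfis

Mamdani fuzzy inference for interpreting soil NPK tests.

Soil laboratories report nitrogen, phosphorus and potassium concentrations
in parts per million; deciding what those numbers *mean* — how fertile the
soil currently is, and how much of each nutrient to apply — is the hard
part for a farmer. `npkfis` encodes that interpretation as a fuzzy expert
system: each measured nutrient is partitioned into LOW / ADEQUATE / HIGH /
EXCESSIVE triangular fuzzy sets on its ppm universe (N 0–100, P 0–150,
K 0–1500), a 64-rule base derived from standard fertility-management
postulates maps every combination of input levels to required-N/P/K and
soil-fertility consequents, and Mamdani inference

- fires each rule at strength `w = min_i μ_{A_i}(x_i)` (AND = min),
- clips the rule's consequent set at `w` (implication = min),
- aggregates clipped sets pointwise by max, and
- defuzzifies by the centroid `x* = ∫ x μ(x) dx / ∫ μ(x) dx` on a discrete
  grid,

yielding a soil-fertility percentage and required N/P/K values on a 0–100
recommendation scale, each tagged with its winning linguistic label. A
`NIL` consequent (e.g. required nitrogen when soil nitrogen is excessive)
contributes nothing; if every firing rule is NIL for an output the crisp
value is 0 ("nothing required").

The package also ships a plain-text rule DSL (audit or override the
generated 64 rules), a synthetic labelled-panel generator for testing, and
the classifier metrics TPR = TP/P, TNR = TN/N and false-alarm rate
(= major deviations / total) with a seeded 70/30 holdout protocol.

## Worked example

```sh
$ npkfis forecast --n 30.55 --p 30.05 --k 200.05
soil fertility :  86.00 %  (HIGH)
required N     :  50.00    (AVERAGE)
required P     :  50.00    (AVERAGE)
required K     :  46.67    (AVERAGE)
```

These readings sit exactly at the ADEQUATE prototypes of all three
nutrients, so the single rule `IF N is A AND P is A AND K is A` fires at
full strength: fertility is the centroid of the entire HIGH fertility set
(86 %), and each recommendation is the centroid of its full AVERAGE set —
a moderate maintenance dressing of everything.

A low-nitrogen, potassium-rich soil shows blended rules at work:

```sh
$ npkfis forecast --n 12 --p 55 --k 900 --explain
soil fertility :  32.58 %  (LOW)
required N     :  73.04    (HIGH)
required P     :  34.75    (AVERAGE)
required K     :  17.78    (LOW)
firing trace:
  [0.376] IF N=L, P=A, K=H THEN R.N=H, R.P=M, R.K=L, S.F=L
  [0.600] IF N=L, P=H, K=E THEN R.N=H, R.P=L, R.K=L, S.F=L
  ...
```

Eight rules fire; nitrogen deficiency dominates, so fertility is LOW and a
HIGH nitrogen dressing is recommended while potassium needs only a LOW
top-up (never zero — crops need potassium to use the nitrogen).

Batch and evaluation workflows:

```sh
npkfis fixtures --count 500 --seed 7 --mode uniform --out panel.csv
npkfis batch --in panel.csv --out forecasts.csv
npkfis evaluate --in panel.csv --seed 1 --report report.json
npkfis rules --export rules.txt && npkfis rules --validate rules.txt
```

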