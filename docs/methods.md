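# Methods

## Model

`npkfis` is a Mamdani fuzzy inference system with three inputs (measured
soil N, P, K in ppm) and four outputs (required N, P, K and soil fertility
on a 0–100 scale, fertility explicitly a percentage). The operator set is
the canonical Mamdani/MATLAB default: AND = min, implication = min
(clipping), aggregation = max, defuzzification = centroid on a discrete
grid. Inference is deterministic: identical inputs at a fixed grid
resolution give bit-identical outputs.

### Linguistic variables

Input universes and level intervals follow standard soil-test
interpretation charts:

| variable | domain (ppm) | LOW | ADEQUATE | HIGH | EXCESSIVE |
|---|---|---|---|---|---|
| N | 0–100 | −1–20 | 20.1–41 | 41.1–70 | 70.1–100 |
| P | 0–150 | −1–20 | 20.1–40 | 40.1–100 | 100.1–150 |
| K | 0–1500 | 0–150 | 150.1–250 | 250.1–800 | 800.1–1500 |

Outputs (0–100 scale): required N and P split LOW 0–30 / AVERAGE 30–70 /
HIGH 70–100; required K LOW 0–20 / AVERAGE 20–70 / HIGH 70–100; soil
fertility LOW 0–40 / AVERAGE 40–80 / HIGH 80–100. A printed lower bound of
−1 is a chart convention for "below detection"; domains start at 0 because
a concentration cannot be negative, but each level's prototype is still the
midpoint of its *printed* interval (so N-LOW peaks at 9.5 ppm).

### Membership construction

The charts give disjoint crisp intervals; triangles placed exactly on those
intervals would leave near-zero dead zones at the boundaries (e.g. 20.05
ppm N) where no rule fires and the centroid is undefined. Each level's
triangle therefore peaks at its printed-interval midpoint with feet
stretched to the neighbouring peaks, and the first/last levels are
shouldered (membership saturates toward the domain edge). This is standard
Mamdani practice and makes every variable a Ruspini partition: degrees sum
to 1 everywhere, at most two adjacent levels are active, and every printed
midpoint remains a pure prototype of its level. The exact overlap used by
the original MATLAB tooling this design mirrors is not recoverable; the
Ruspini construction is this package's choice. Out-of-domain readings are
clipped to the domain edge with a logged warning rather than rejected.

### Rule base

The 64 rules are the full Cartesian product of the 4 input levels over the
3 nutrients. Consequents are generated, not hand-listed, from the minimal
deterministic scheme consistent with the five fertility-management
postulates (high phosphorus ⇒ limit phosphorus application; low phosphorus
⇒ satisfy immediate crop needs; potassium is needed to use nitrogen; some
potassium is always applied to cover crop removal; soil fixes its own
nitrogen when nitrogen is high):

- per-nutrient inverse dose-response: LOW→HIGH, ADEQUATE→AVERAGE,
  HIGH→LOW, EXCESSIVE→NIL — except potassium, whose EXCESSIVE consequent is
  LOW, never NIL;
- soil fertility = the minimum per-nutrient adequacy, where adequacy is
  LOW for a deficient nutrient, AVERAGE for an excessive one and HIGH
  otherwise (the worst nutrient caps fertility; excess is penalised but
  not as severely as deficiency).

The generated base is also serialised to the packaged `rules_default.txt`
so users can audit or override it through the text DSL. Rules are
AND-connected; OR is parsed but rejected by the system validator.

`NIL` means "this rule contributes nothing to that output", not "a zero
fuzzy set". When *every* firing rule is NIL for an output — e.g. required
nitrogen once measured nitrogen is unambiguously EXCESSIVE (above ≈85 ppm
the HIGH set's support ends) — the aggregate is empty and the crisp value
is defined as the output-domain floor, 0, labelled LOW: nothing required.
A genuinely empty aggregate caused by an incomplete custom rule base
raises `NoRuleFiredError` instead of silently inventing a midpoint.

## Tunable parameters

- **Grid resolution** (`resolution`, default 1001 points per output
  domain): discrete-centroid error on a 0–100 domain is well below 0.1
  units at this setting (measured max shift vs a 100001-point grid:
  ~3×10⁻⁴) at millisecond cost per forecast.
- **Train fraction** (`train_frac`, default 0.70) and split seed for the
  holdout protocol. The system has no trainable parameters, so the train
  split triggers a structural audit (partition, completeness, postulates)
  and metrics are reported on the held-out 30% — the conventional split is
  honoured for comparability, not because anything is fitted.
- **Deviation predicate** for the false-alarm rate: by default *any*
  fertility-class mismatch is a "major deviation", which makes
  accuracy + false-alarm = 1 on any panel; a stricter predicate (e.g. only
  two-class jumps) can be passed to `evaluate`.
- **Panel spec** (`count`, `seed`, `mode`, `sigma`): sampling modes are
  uniform-over-domain, stratified (≥1 sample per each of the 64 level
  cells) and prototype-jitter (cell midpoints + Gaussian noise of `sigma`
  ppm, clipped to the domain).

## What the synthetic panels do and do not show

Panels are labelled by the same crisp semantics the rule base encodes:
each nutrient is classified against its printed interval (boundaries
belong to the lower band, the last band closed) and the fertility label is
the minimum per-nutrient adequacy. This is the only self-consistent oracle
available without annotated field samples. Passing tests therefore
demonstrate that the fuzzy pipeline is faithful to its own crisp
semantics — exact recovery on noiseless prototypes, graceful degradation
under jitter (measured accuracy 1.00 / 0.98 / 0.90 at σ = 0 / 2 / 10 ppm
on 500-sample panels), ~86% agreement on uniform panels whose mass sits
near band boundaries — not that the system predicts real soil fertility.
Real soil chemistry (correlated nutrients, spatial structure, measurement
error) is deliberately not emulated, and published field accuracies are
not reproduction targets here.

## Numerical choices and degenerate inputs

- Centroid uses trapezoidal weighting on an evenly spaced grid; results
  are clamped to the output domain against float round-off.
- Fuzzification clips to the domain (logged); non-finite readings raise.
- Label ties at a crisp value are broken toward the lower level; in
  practice ties only occur at exact crossover points.
- Interval tables are validated: ordered, non-overlapping, covering the
  domain; a gap of up to 0.5 between consecutive printed bounds (the
  "20 / 20.1" chart convention) is treated as an abutting boundary.
- A single-interval variable degenerates to membership 1 everywhere.

## Known limitations

- **Requirement sweeps are not globally monotone.** With min-implication
  and centroid defuzzification, clipping a *shouldered* consequent set at
  falling rule strength widens its plateau and drifts its centroid toward
  the plateau's centre. Sweeping measured N upward with P and K held
  adequate, required-N falls from ~82 to ~17.8 but then *rises* toward ~25
  across the HIGH→EXCESSIVE flank before dropping to 0 where all rules go
  NIL; required-K shows a similar ~6-unit hump between the HIGH and
  EXCESSIVE prototypes (largest single sweep step: +0.15). This is an
  inherent artifact of the canonical Mamdani operator set with shouldered
  Ruspini partitions, not an implementation defect; monotonicity does hold
  across the level prototypes, and the acceptance suite measures the
  violation rather than hiding it. Product implication (scaling) would
  remove the drift but departs from the min-clipping contract this package
  implements.
- The crisp value at the all-NIL threshold is discontinuous by
  construction (centroid limit ~25 vs the defined floor 0); the trace and
  `nil_defaults` make the regime explicit.
- Whether the 0–100 required-potassium scale is ppm or an index is
  ambiguous in the source charts given potassium's 0–1500 ppm input
  universe; values are reported as-is on 0–100.
- Sugeno/TSK inference, non-triangular membership families, rule
  weighting/learning and crop-specific recommendations are out of scope.
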