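# psakit — Personal Support Algorithm toolkit

Home- and community-care programs allocate *personal support* (paid help
with activities of daily living) largely by individual clinical judgment,
with no standard way to classify need. The Personal Support Algorithm (PSA)
addresses this: a decision-tree case-mix classification that sorts patients
assessed with standardised interRAI-style home-care instruments into six
ordered need groups (Group 1 further split into 1A/1B/1C), each with a
characteristic distribution of weekly billed personal-support hours, so
that per-group percentile bands can guide — without dictating — allocation
decisions.

`psakit` is a complete toolkit for this framework, aimed at health-services
researchers and care-coordination analysts:

- **Scales** — ADL Short (0–16), ADL Hierarchy (0–6), Cognitive Performance
  Scale (0–6), IADL Difficulty (0–6), and the Self-Reliance Index, computed
  from raw assessment item codes.
- **Classifier** — a fully table-driven tree (JSON `TreeSpec`, bundled
  reference tree) mapping a record to one of the eight display labels.
- **Derivation engine** — recursive partitioning of weekly hours with
  one-way ANOVA F-tests (variance reduction), Bonferroni adjustment over
  all candidate partitions at a node, depth/leaf-size constraints, forced
  variables for interactive growth, and dynamic-programming collapse of
  leaves into ordered groups. Exposed both functionally and as a
  scikit-learn estimator (`HoursTreeRegressor`).
- **Hours pipeline** — weekly billed hours from service logs
  (12-week post-assessment window, span-adjusted), assessment-reported
  estimates, and the published derivation/guideline cohort filters with
  auditable exclusion ledgers.
- **Validation & guidelines** — explained variance (R² of hours on group
  indicators), model coefficient of variation, highest/lowest group-mean
  ratio, per-group statistics, 20/35/50/65/80th-percentile allocation
  bands with typical/occasional/exceptional zoning, and the statutory
  120 h / 90 h 30-day-period validator.
- **Synthetic cohorts** — a seeded generator calibrated to the published
  group shares and per-group hours distributions, producing assessments,
  billing logs and truth files so the whole pipeline is testable without
  access to the (undeposited) provincial data.

The model at the core: each patient is predicted by their group mean
$\bar y_g$, and a grouping is judged by
$R^2 = 1 - \mathrm{SSE}/\mathrm{SST}$,
$\mathrm{CV} = 100\cdot\mathrm{RMSE}/\bar y$, and the ratio
$\max_g \bar y_g / \min_g \bar y_g$. Splits during derivation maximise the
one-way ANOVA F statistic with adjusted p-value $\min(1, m\,p)$, where $m$
counts every admissible candidate partition evaluated at the node.
See `docs/methods.md` for the full account.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from psakit import (SimConfig, generate_cohort, classify_cohort,
                    billed_hours_frame, model_fit, group_stats, build_guidelines,
                    allocation_zone)
from psakit.evaluation import stats_frame

bundle = generate_cohort(SimConfig(n=5000, seed=42))          # synthetic cohort
assignments, dist, _ = classify_cohort(bundle.records)        # PSA groups
hours = billed_hours_frame(bundle.billing,
                           bundle.truth[["person_id", "assessment_date"]])
cohort = assignments.merge(hours, on="person_id")

fit = model_fit(cohort["top_level"], cohort["weekly_billed_hours"])
print(f"explained variance: {fit.explained_variance:.3f}")
print(f"coefficient of variation: {fit.coefficient_of_variation:.1f}")
print(f"group 6 / group 1 mean ratio: {fit.group_ratio:.1f}")
print(stats_frame(group_stats(cohort, "top_level", "weekly_billed_hours"))
      .round(2).to_string(index=False))

bands = build_guidelines(cohort, "top_level", "weekly_billed_hours")
print("zone for 4 h/week in group 3:", allocation_zone("3", 4.0, bands))
```

Output:

```
explained variance: 0.342
coefficient of variation: 97.2
group 6 / group 1 mean ratio: 36.4
group    n  percent  mean   sd  median   q1    q3   cv
    1  311     6.22  0.37 1.11    0.00 0.00  0.00 2.97
    2 2336    46.72  2.45 2.47    1.66 1.00  3.00 1.01
    3 1378    27.56  4.73 4.16    3.55 1.77  6.52 0.88
    4  378     7.56  6.97 5.87    5.55 2.45  9.54 0.84
    5  322     6.44  8.64 7.08    7.01 4.17 10.81 0.82
    6  275     5.50 13.56 8.50   11.70 7.74 16.28 0.63
zone for 4 h/week in group 3: typical
```

Reading it: the classifier recovers the planted group structure (shares
~6/46/28/8/6/6 %), per-group hour distributions match their calibration
targets (e.g. Group 3 mean ≈ 4.8, Group 6 median ≈ 12), group means rise
strictly with need, the grouping explains ~34 % of hours variance on this
cohort, and a 4 h/week proposal for a Group 3 patient falls inside the
35th–65th-percentile "typical" band.

The same pipeline is available from the shell:

```bash
psa --seed 11 simulate --n 1000 --out-dir fixtures/
psa classify --assessments fixtures/assessments.csv --out groups.csv
psa hours --assessments fixtures/assessments.csv --billing fixtures/billing.csv --out hours.csv
psa evaluate --hours hours.csv --groups groups.csv --out fit.json
```

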