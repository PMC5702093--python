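# Methods

`psakit` implements the Personal Support Algorithm (PSA), a case-mix
classification that groups home- and community-care patients by their need
for personal support services (paid help with activities of daily living),
together with the machinery around it: the clinical scales it reads, the
tree-derivation method that produced it, the billed-hours dependent
variable, the validation metrics, percentile allocation guidelines, and a
calibrated synthetic-cohort generator. This note records the model, the
parameter choices, and the places where the design was genuinely open.

## Clinical scales

All scales are pure functions of one assessment record. Item coding follows
the home-care convention: ADL self-performance 0 (independent) – 6 (total
dependence), with 8 meaning "activity did not occur"; decision making 0–4;
IADL difficulty 0–2. Code 8 is treated as maximal dependence everywhere (a
conservative need estimate); the recode tables live in
`src/psakit/data/*.csv` so they can be corrected without code changes.

- **Self-Reliance Index (SRI)**: impaired iff decision making ≥ 1 ("any
  difficulty") or any of bathing, personal hygiene, dressing lower body,
  walking indoors/outdoors, or locomotion is ≥ 2 ("supervision or any
  physical help"). The source instrument is ambiguous about whether
  "walking (or wheeling)" is one item or three; the data model carries
  walking indoors, walking outdoors, and locomotion separately and the SRI
  reads all three.
- **ADL Short scale (0–16)**: sum of personal hygiene, toilet use,
  locomotion and eating after recoding 0–6/8 onto 0–4
  (0,1,2,3 identity; 4,5,6,8 → 4).
- **ADL Hierarchy (0–6)**: a reconstruction of the published early-loss /
  late-loss hierarchy over the same four items. Items are categorised
  0 (codes 0–1), 1 (2–3), 2 (4–5), 3 (6/8); eating is the late-loss anchor:
  category 3 in eating gives level 6 when every other item is at least
  extensive (category ≥ 2), else 5; category 2 in eating gives 4; otherwise
  the level is the maximum item category (0–3). This satisfies the
  published banding (0 = independent) and is monotone in every item, which
  the test suite verifies exhaustively over the full 4-item code space.
- **CPS (0–6)**: the standard Cognitive Performance Scale structure adapted
  to the 0–4 decision-making coding: severely impaired decision making
  (code 4) gives 5, or 6 with total dependence in eating; otherwise the
  count of impairments (decision ≥ 1, memory problem, making self
  understood ≥ 1) gives 0/1, and with ≥ 2 impairments the severe count
  (decision ≥ 2, understood ≥ 2) gives 2–4.
- **IADL Difficulty (0–6)**: sum of the three 0–2 difficulty codes.

Missing items are governed by a policy: `reject` (default) raises a named
error; `impute_independent` fills the independent code.

## The classifier

The classifier is entirely table-driven: a `TreeSpec` is an ordered tree
with integer cut points (split semantics `v < cut` left, `v ≥ cut` right)
and terminal nodes carrying one of eight display labels
(1A, 1B, 1C, 2, 3, 4, 5, 6; higher = greater need; sublevels exist only in
Group 1). The bundled reference tree encodes the published narrative: root
on the SRI; IADL difficulty separates 1A/1B/1C; the ADL Short scale
stratifies impaired patients into low (≤ 2), moderate (3–9) and high (≥ 10)
impairment; dressing upper body plus decision-making difficulty or great
IADL difficulty differentiate the low branch; cognitive impairment
(CPS ≥ 3), unstable health, and weekly bladder incontinence the moderate
branch; and late-loss ADL (eating ≥ 2) with weekly bowel incontinence, or
communication difficulty (making self understood ≥ 2) with caregiver
distress, identify Group 6 at the top. The exact cut points were never
published; the defaults above follow the printed scale bands and are data,
not code. Sublevel ordering fixes 1A = lowest IADL difficulty. The
communication item is taken to be "making self understood" (the instrument
also has an understanding-others item; this choice is flagged in the tree
metadata).

Totality and cardinality are checked by an exhaustive sweep: the cut points
partition each variable's declared range into equivalence classes the tree
cannot distinguish, so enumerating one representative per class (the class
lower bounds) covers the entire discretised input domain exactly. The same
sweep verifies an ordering property: raising any single tree variable never
lowers the top-level group.

## Tree derivation engine

`grow_tree` / `HoursTreeRegressor` re-implement the derivation method:
recursive partitioning of a continuous target with one-way ANOVA F-tests
(variance reduction) as the splitting criterion, binary splits preferred
and contiguous multi-way splits optional (default up to 3-way), a depth cap
(default 6 levels), a minimum terminal size (default 100), and Bonferroni
adjustment at every split. The multiplicity `m` is the total number of
admissible partitions evaluated at the node **across all candidate
variables** — with a per-variable correction the chance of a false split at
a pure-noise node with five candidate variables would be ≈ 1−(1−α)⁵ ≈ 23 %,
defeating the point of the correction; the node-level total keeps it ≤ α,
which the acceptance suite verifies by simulation (500 null cohorts).
Candidates are ranked by raw p (equivalently adjusted p, since `m` is
shared at a node), then larger F — necessary because p-values underflow to
0 for strong splits — then binary before multi-way, smaller cuts, and
variable name, making growth fully deterministic; the `random_seed`
parameter is reserved for future stochastic tie-breaking and currently
unused. Rows missing the candidate variable are excluded from that
variable's evaluation (no surrogate splits). Interactive growth is
supported through a forced root variable and per-node path overrides.

Terminal nodes are collapsed into k ordered groups by sorting leaves by
mean and solving the weighted 1-D k-grouping that minimises within-group
sum of squares by dynamic programming — a reproducible stand-in for the
original manual merge of "similar averages"; k is supplied by the analyst.
Group means are strictly increasing by construction; an exact tie forced
apart by too large a k is an error rather than a silent violation. The
derivation/validation split is a seeded random 70/30 partition.

## Hours construction and cohort filters

Weekly billed hours: personal-support services in the half-open 12-week
window (assessment date excluded, day 84 included), total hours divided by
the first-to-last-visit span in days and multiplied by 7. The span is
floored at one day for single-visit patients (the formula is otherwise
undefined there) and such records are flagged. The assessment-reported
estimate is (aide + homemaking minutes)/60 over the 7-day lookback.

Derivation-path exclusions run structural rules first (assessed in
hospital; case-management/placement-only; under 21 days of active service —
"active service" keys on all services, since zero personal-support hours
are a legitimate Group 1 outcome) and then drop patients above the 99th
percentile of weekly billed hours computed on the remaining cohort. The
derived cut-off is reported in the ledger and can be passed back in, under
which the filter set is idempotent (recomputing the percentile on an
already-trimmed cohort would trim again by construction). The
guideline path instead drops congregate settings, waitlisted patients with
no service, and Groups 3–6 with no service, and keeps the heaviest users.
Exclusions use first-match accounting so ledger totals reconcile exactly.

## Validation metrics and guidelines

Explained variance is 1 − SSE/SST with group means as predictions (the R²
of hours on group indicators). The published "coefficient of variation" has
no printed formula; it is reconstructed here as 100 × within-group RMSE /
grand mean, the conventional relative-closeness measure in this literature,
and clearly labelled a reconstruction. Discriminatory ability is the ratio
of the highest to the lowest group mean; note that computing it from the
printed (rounded) group means gives 28.0 while the published value from
unrounded data is 32.1 — a rounding artefact, not a formula difference, and
the package does not force agreement. Quantiles everywhere are linear
interpolation of the empirical CDF ("type 7"), fixed for reproducibility;
group SDs use ddof = 1.

Guideline bands are per-group 20/35/50/65/80th percentiles (45/55 also
computed for the narrow-band configuration). Zones partition the
non-negative axis with inclusive boundaries: typical within [p35, p65],
occasional within [p20, p80] outside that, exceptional beyond. The
statutory validator enforces the 120 h (first 30-day period) and 90 h
(subsequent periods) ceilings inclusively, with named exemptions
suppressing but logging the flag.

## Synthetic cohorts

The generator's defaults are the published study conditions: group shares
6.4/45.5/28.2/7.6/6.6/5.7 %, and per-group weekly-hours models calibrated
to the published table. Two calibration modes exist because the printed
means and quartiles are not jointly attainable by one two-parameter family:
quantile mode (log-normal, median exact, σ a least-squares fit to both
quartiles on the log scale) for Groups 2 and 6, and moment mode (gamma,
mean and SD exact) for Groups 3–5. Group 6's printed quartiles
(12.0, 6.3–14.8) are too log-asymmetric for any log-normal to reproduce
both within 10 %, so the fit warns — by contract — while the median stays
exact. Group 1 (median and quartiles all zero) is zero-inflated: 80 %
structural zeros plus a log-normal positive part with mean 2.0, giving an
overall mean 0.4 and SD ≈ 1.42, matching the printed 0.4 ± 1.4. The Group 1
sublevel split (30/40/30) is a fixed convention; it is not printed
anywhere.

Records are generated by inverting the classifier: a leaf with the
requested label is chosen, the root-to-leaf path yields per-variable
intervals, scale-level constraints are pushed down to item codes (sum
decompositions for the ADL Short and IADL scales, recipe inversion for the
CPS), and the draw is verified by an actual classification round trip, with
rejection and resampling on the rare misses. Non-classifier fields follow
published marginal prevalences only (e.g. 53.5 % weekly bladder
incontinence, 49.3 % unstable conditions, mean age 78 ± 14.2); no attempt
is made to reproduce the unknown joint distribution, so passing tests
demonstrate correctness of the *machinery*, not realism of item
correlations.

The billing log encodes each planted weekly amount as weekly visits on
days 7–84 (span 77 days = 11 weeks) in quarter-hour quanta, with first and
last visits guaranteed non-empty so the span is preserved; planted hours
are snapped to this representable grid (max adjustment 0.25/11 ≈ 0.011
h/week, truth files record the snapped value), so the hours pipeline
recovers the planted value exactly rather than approximately. Generated
cohorts represent the *post-exclusion* analytic population (the published
group table is computed after exclusions), so hospital/placement flags are
all zero and active service spans the full window; the filter rules are
exercised on constructed toy cohorts instead.

## Problem sizes and numerics

The test suite uses the sizes at which each claim is statistically
decidable at desk scale: exhaustive sweeps for the discrete domains
(classifier ~9 × 10³ equivalence-class combinations, scales 9⁴ item
combinations), n = 10,000 for the share round trip (3-binomial-SE band),
n = 50,000 for hours-calibration recovery, 500 replicates for type-I
control, and 100 seeded runs for planted-split recovery. Floating-point
ties in the F ranking are broken deterministically as described; ANOVA on
zero-variance targets is defined as F = 0, p = 1, and a zero within-group
variance with non-zero between-group variance as F = ∞, p = 0.

## Known limitations

- The exact published 25-leaf tree is not recoverable from its narrative;
  the reference tree is a faithful-but-declared reconstruction with
  configurable cut points (18 leaves covering every described branch).
  Real-data headline figures (explained variance 30.8 %, ratio 32.1) are
  properties of the undeposited provincial cohorts and are deliberately
  not test targets.
- The ADL Hierarchy and CPS are reconstructions of cited-but-unreproduced
  instrument definitions; their recode tables are shipped as data for easy
  correction.
- The interactive derivation sessions behind the published tree
  (~20 candidate structures) cannot be replayed; the engine supports the
  mechanism (forced variables, per-node overrides), not the history.
- `model_cv` is a documented reconstruction; other definitions of the
  published coefficient of variation would rescale Table-4-style outputs.
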