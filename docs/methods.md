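# Methods

## Data model and definitions

The raw unit is an **invoice entry**: one billed item (drug, consumable,
or examination) for one animal on one date, carrying practice and patient
identifiers, species, breed, sex, birth/death dates, and free-text
anamnesis/diagnosis. All entries of one animal on one calendar date form a
**consultation**, the analysis unit. Any application *or* delivery of an
antibiotic counts as treatment; the same substance both injected during
the visit and dispensed to the owner counts **once** in the consultation's
substance set, while per-class usage shares are computed over
**applications** — every antibiotic invoice row — because that is the
natural denominator for "which classes are being used".

Episode definitions, all in whole calendar days:

- **initial treatment** — a treated consultation with no treatment of the
  same animal at offsets 1–30 before it (the 30-day washout blocks initial
  status at offset 30, not 31);
- **follow-up treatment** — a treated consultation at offsets 1–7 after
  another treatment (day 7 counts, day 8 does not); gaps of 8–30 days are
  neither initial nor follow-up;
- **substance change** — a follow-up whose single substance differs from
  the single substance of the nearest preceding treatment; consultations
  with ≥2 substances are excluded from change eligibility. In chains
  (day 0 → 5 → 9) each consultation's follow-up status is relative to its
  nearest preceding treatment, while `days_since_initial` tracks back to
  the chain's initial consultation. Two change shares are reported, since
  "share of cases" admits two denominators: change events / eligible
  follow-up pairs, and change events / single-substance initial
  treatments. Consultations near the end of the study window still count
  as index visits; no censoring correction is applied.

Cohort eligibility: dogs and cats, years 2018–2022 (inclusive), practices
with ≥100 distinct eligible patients ("fewer than 100" excludes 99 and
keeps exactly 100). Patients are counted after the species and year
filters by default — chosen for internal consistency with the analysis
cohort — and a flag (`count_patients_within_years=False`) switches to
counting before year filtering, since either reading is defensible.

Body weight is never recorded in invoice data, so dogs receive their
breed's mean weight (packaged breed table), 20 kg when the breed is
missing or unknown, and cats a flat 5 kg. Any breed string containing
"Mischling" (case-insensitive substring) marks a crossbreed. Age is
(consultation date − birth date)/365.25; consultations with missing birth
dates are excluded from age models only.

## Indication mapping

Anamnesis and diagnosis text are concatenated, lower-cased, umlaut-folded
(ä→ae, ö→oe, ü→ue, ß→ss), stripped of punctuation, and scanned with a
single word-boundary alternation regex over the lexicon; multi-word
keywords match as phrases and take precedence over their component words
at the same position. Each keyword maps to exactly one of **twenty**
categories. Fifteen labels follow the published grouping
(diagnostics/therapy, dermatology, orthopedics, digestive system,
respiratory system, otology, ophthalmology, urogenital tract, emergency,
trauma, intoxication, endocrinology, routine, systemic, unclear); the
remaining five (cardiology, neurology, dentistry, oncology, infectious
disease) are package-defined placeholders completing the set, as no
published enumeration of all twenty exists. When several categories match,
the highest hit count wins and ties break by a fixed priority list that
prefers specific organ-system categories over generic ones — the original
resolution rule is not published, so this deterministic rule is the
package's own, configurable choice. The packaged lexicon (~190 entries) is
format-compatible with, but far smaller than, the proprietary >25,000-term
list used in production settings; coverage numbers on real data would
differ accordingly.

## Statistics

**Odds ratios.** Cross-product estimate with the Woolf (logit) interval
`exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, z = 1.959964 at α = 0.05, and a
two-sided Wald p-value. For a single binary predictor this coincides with
simple logistic regression (verified against a statsmodels logit fit to
four significant figures on random tables). A zero cell raises an error
pointing at the optional Haldane–Anscombe continuity correction (+0.5 to
every cell), which is off by default. Under a null simulation the 95 %
interval covers OR = 1 in ~95 % of replicates (asserted at 93–97 % over
1,000 seeded replicates). Rounding (OR and CI to 2 decimals, percentages
to 1) happens only at the presentation layer.

One caveat on the published reference tables used as fixed inputs in the
acceptance checks: one within-indication row (skin × dermatology) prints
an OR of 0.98 while its own counts imply 1.12, and one percentage cell
prints 20.8 where its counts give 20.73 → 20.7. Both are internal
inconsistencies of the source tables, irreconcilable from the printed
numbers, and are excluded from the corresponding checks.

**Prevalence curves.** Logistic GLM on a natural cubic regression spline
basis (patsy `cr`, df = 4 by default) in age or breed-mean weight, knots
at predictor quantiles (the basis default, since only basis and df are
prescribed). The returned object is a prediction table over a grid
(2nd–98th percentile by default) with a pointwise 95 % band from the delta
method on the linear predictor; coefficients are deliberately not part of
the interface. Fits with fewer than 10 events or non-events, diverged
coefficients (|β| > 50, a separation symptom), or optimizer failure raise
an explicit fit error.

## The synthetic-record generator

`GeneratorConfig` defaults encode the study conditions the pipeline
is meant to recover: years 2018–2022, a 58 % dog caseload, per-species
treatment prevalence 12.9 % (dogs) / 22.5 % (cats), an 11.5 %
multi-substance share (2/3/4 substances in proportions 94.5/5.2/0.3 %),
per-species follow-up rates 23.1 % / 38.7 % at day offsets 1–7 with
geometrically decreasing weights (ratio 0.65 — early returns dominate),
a 13 % substance-change rate among single-substance pairs, 43.3 % of
consultations carrying lexicon keywords in their free text, and 4.4 % of
treated consultations using a human-registered product (95 % of that mass
on local eye/ear preparations, gentamicin-dominated). The substance mix
puts two thirds of mass on aminopenicillins (amoxicillin with and without
clavulanic acid as distinct substances) and exactly 12.5 % on HPCIA
classes. The indication mix concentrates on diagnostics/therapy,
dermatology, digestive and orthopedic categories. Where the emulated
conditions fix no value (consultation rate 1.1 index visits per
patient-year, untreated-return probability 0.18 at offsets 1–14 skewed
late, 2 % death fraction, 24 % crossbreeds, 17 % missing breed), values
were chosen once as realistic for first-line small-animal practice.

Design points worth knowing:

- **Prevalence is exact by construction.** Spawned follow-up visits are
  always treated and untreated returns never are, which would distort the
  share of all consultations that are treated; the generator therefore
  solves the index-visit treatment probability
  p\* = p(1+g) / ((1+f)(1−p) + p(1+g)) (f = follow-up, g = untreated-return
  probability) so the realized overall share equals the configured
  per-species prevalence in expectation.
- **Application rows are iid draws from the substance mix.** Duplicate
  draws are kept as repeat rows (inject + dispense), so the
  per-application class distribution equals the configured mix exactly;
  weighted sampling without replacement would systematically over-
  represent low-mass classes. Human-product substitution and
  change-target resampling perturb the application mix slightly (the human
  mix is 20 % ofloxacin, a fluoroquinolone); checks of the mix parameter
  itself therefore switch those two features off.
- **Between-practice variation** is a multiplicative Gamma random effect
  on prevalence with mean 1 (CV 0.35 by default, clipped at 0.95) — mean-
  preserving, so parameter recovery stays well-posed, while producing the
  wide per-practice spread seen in real data. Tests that assert recovery
  within binomial standard errors set the dispersion to zero, because a
  binomial bound presupposes independent sampling and the cluster variance
  otherwise dominates at any cohort size.
- **One scheduled return per index visit.** Each treated index visit
  spawns at most one treated follow-up. A consequence is that the
  initial-treatment share is ≈ 1/(1+f) (~80 % dogs, ~71 % cats) — real
  cohorts with longer re-treatment chains show lower initial shares, and
  no single-return process can match an arbitrary (initial share,
  follow-up rate) pair simultaneously. The follow-up rate, not the initial
  share, is the calibrated quantity.
- Free text is keyword + noise-token bags, not grammatical German —
  sufficient for lexicon matching, useless for NLP beyond it. Noise tokens
  are chosen never to match the packaged lexicon.
- Optional `predisposition_effects` apply exact odds multipliers to the
  indication assignment and/or treatment probability of breeds carrying a
  predisposition flag, so odds-ratio recovery tests have a known truth.
- Deaths truncate a patient's visits; a patient whose visits would all
  fall after the sampled death date keeps their visits and loses the death
  date instead, so every patient has ≥1 consultation.
- `prevalence_cohort` generates minimal (predictor, treated) cohorts with
  an arbitrary truth function for spline testing; the packaged test truths
  use smooth softplus ramps at 50 kg / 10 years because a df = 4 natural
  spline cannot represent a hard hinge without local bias.

What passing the synthetic tests does **not** show: performance on real
free text (the lexicon is tiny and the text synthetic), realistic
per-practice case-mix differences, treatment-duration or dosing
information (absent from invoice data), and clinic-type effects — none of
which the generator emulates.

## Numerical and testing choices

Probability-vector validation uses a 1e-9 sum tolerance. All randomness
flows through a single `numpy` Generator seeded from the config, making
identical config + seed byte-identical. Episode labelling is verified
against a quadratic all-pairs oracle, consultation grouping against a
nested-loop oracle. Recovery tests use 3 binomial standard errors at
cohort sizes of roughly 50,000 consultations (acceptance) and 12,000
(unit tests). Spline-coverage checks average the pointwise-covered grid
fraction over five replicate cohorts of n = 8,000, since a single
replicate's covered fraction under a 95 % pointwise band fluctuates around
its 0.95 expectation with correlated misses. The null-coverage simulation
uses two binomials of size 200 at outcome probability 0.3 per replicate.

## Known limitations

- The drug dictionary and breed table are packaged fixtures covering the
  substances and breeds relevant here, not registry mirrors; production
  use requires a full dictionary in the same format.
- Indication assignment quality is bounded by the lexicon; the max-count
  plus priority tie-break is a heuristic, and real free text would need a
  far larger lexicon or a learned classifier.
- No multivariable adjustment, random effects, or multiple-testing
  correction — the analyses are deliberately simple per-table statistics.
- Calendar-day arithmetic ignores time of day; two visits on one date are
  one consultation by definition, so same-day substance changes are
  invisible.
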