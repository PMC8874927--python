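# Methods

## The procedure

`matcvrisk` replays a retrospective maternal cohort encounter by
encounter. The pipeline has six substantive stages; every stage reads
and writes plain CSV tables so each is independently re-runnable and the
whole chain is byte-reproducible for a fixed seed.

1. **Cohort extraction.** The base cohort is every patient with a
   documented delivery procedure inside the delivery window (default
   2017-01-01 … 2020-12-31, inclusive). Encounter diagnosis codes (a
   configurable prefix list, default `Z34`/`O80`) identify the
   patients' prenatal and delivery visits, restricted to dates on or
   before the delivery. Three exclusions follow: visits registered in
   excluded years (historical uploads register in 1900), visits of
   communication types (portal message, phone call) carrying no
   clinical events, and encounters at which the patient is outside
   18–35 years. Each exclusion is a pure per-visit predicate, so the
   result is provably order-independent. Age is completed years at the
   encounter with both boundaries inclusive (18 and 35 qualify) — the
   boundary semantics are this package's choice, since "18–35" alone
   does not fix them. Visits with a missing or malformed date of birth
   go to a review list rather than being silently dropped.

2. **De-identification.** Zip codes are generalized to
   urban/rural/suburban through a lookup table and then discarded;
   unknown zips classify as "unknown" with a logged warning. Every
   datetime is split into a clock time (kept for within-day sequencing)
   and a calendar-day offset from the patient's *index visit* — defined
   as the earliest visit *surviving extraction*, not the earliest raw
   visit, so that year-1900 artifacts cannot corrupt the origin.
   Offsets of records predating the index (imported history) are
   permitted to be negative. Date of birth is replaced by age-at-index
   in completed years, which the static age factor needs. Person and
   visit ids are replaced by SHA-256 over `salt‖id`, hex-truncated to
   16 characters with collision detection (the hash construction and
   truncation length are implementation choices; only "keyed one-way
   with a recoverable master key" is essential). The master key is
   written to a separate directory, never alongside the analysis
   export, and can be withheld entirely. Events whose type is a
   free-text/comment/date entry field are stripped.

3. **Harmonization.** Every record receives a three-level
   classification (CATEGORY, SUB_CATEGORY, CLINICAL_CAT) from an
   ordered, editable rule list — first match wins, and unmatched
   records go to a review queue rather than being dropped, because
   event hierarchies are site-customized and always need manual
   review. Result values sharing the single value field are normalized:
   weights in lb convert to kg (× 0.45359237, rounded to 0.01 kg, so an
   lb→kg→lb round trip is within 0.02 lb); canonical units pass
   through; unknown units flag the record and bar it from risk
   evaluation. Duplicate observations (same person, visit, label,
   value, day, time) collapse to one row. The final schema (Person,
   Visit, Event, Diagnosis, FamilyHX, Race) keeps both pseudonymous ids
   on every visit-grain table; FamilyHX and Race are person-grain. A
   field-level data catalog is regenerated at every assembly.

4. **Risk engine.** Described in the README. Two choices deserve
   notice. Static findings count toward the 4-or-more rule — the rule
   speaks of *total* risk factors, and a prepregnancy condition is no
   less a factor at an encounter than a symptom; this is revisitable in
   config. Variable findings do not carry forward between encounters:
   the engine evaluates data collected at each visit. (A carry-forward
   window for sparsely recorded symptoms would be the natural extension
   but is deliberately not implemented: it changes onset semantics.)
   Symptom-coded tachypnea and the
   respiratory-rate threshold are distinct factor ids, and duplicate
   factor ids within an encounter count once (most severe level wins),
   so nothing is double-counted. The age ≥ 40 factor stays in the
   catalog even though the default extraction window (18–35) means it
   can never fire on study-like data.

5. **Baseline mode (off by default).** The engine can establish
   per-patient baselines — the median of the first k = 3 observations
   per quantity — and shift numeric thresholds by the deviation of that
   baseline from the population-norm midpoint. On retrospective
   extracts with little pre-pregnancy history this is unreliable, so
   the default is off and raw catalog thresholds apply; when on, a
   baseline outside the shipped accepted ranges flags the patient out
   of any calibration set. Both the shift formula and the norm ranges
   are this package's interpretation and are labeled non-authoritative.

6. **Delta evaluation and reporting.** `delta = reference − onset` in
   days; the default onset anchor is the earliest standard-or-higher
   day (a `--level red_flag` option restricts to red-flag onsets, since
   either anchoring is defensible). The reference day is the first
   diagnosis matching the target-condition code prefixes or a
   configured intervention marker; "intervention" has no canonical
   definition, so it is an explicit marker list. Patients with an
   onset but no reference are reported separately as "detected, never
   diagnosed" — candidate false positives or genuinely missed cases.
   The overview report formats percentages by rounding half-up to two
   decimals and trimming trailing zeros. This rule reproduces 15 of the
   17 count/percentage pairs in the published cohort overview this
   report imitates; the remaining two cells of that table are
   internally inconsistent with any single rounding rule (their exact
   values are 45.836 % printed as 45.83 and 1.45500 % printed as 1.45,
   while other cells in the same table are rounded half-up), so the
   formatter's own output is the documented behavior.

## The synthetic-data generator

The generator emulates the *structure* of a visit-centric maternal EHR
extract, not its physiology. Per patient it draws a cohort category —
delivered-on-first-visit (probability 0.4583), single prenatal visit
(0.3544), or a normal trajectory of ~2–8 prenatal visits uniformly
spread over a fixed 280-day gestation ending at a delivery inside the
window — one mutually exclusive draw per patient so each planted
fraction is an exact Bernoulli proportion, recoverable within binomial
error. Category fractions and the static-risk prevalences (BMI ≥ 35:
8.64 %, African American race: 25.28 %, substance use: 10.7 %) follow
the published cohort structure this generator emulates; prevalences
that structure does not state (diabetes 3 %, hypertension 5 %,
chemotherapy 0.5 %, labor-complication history 2 %, heart-disease
history 1 %) and the visit-count mean (8) are the package's own
defaults, chosen once as plausible for a prenatal population and not
estimates of any real cohort.

A fraction of patients (default 0.20 with a variable risk trajectory,
of whom 0.0529 of all patients reach the red-flag band) get one vital
sign planted to cross its standard threshold at a chosen visit and,
for red-flag patients, the red-flag threshold at a later visit. Values
are drawn from bands strictly below the threshold before the crossing
visit and at/above it from then on, with additive noise (default SD
0.5) clipped to the band — so the crossing day is unambiguous at any
permitted noise level, which is what makes exact onset and lead-time
recovery a meaningful test. A provider diagnosis from the
target-condition codes is planted at the first visit at least L days
after the crossing (L uniform on 7–42 days). Patients wholly outside
the 18–35 age range (6 %), year-1900 upload visits and
communication-only visits (10 % of base visits, all carrying an
encounter code but no clinical events) exercise the filters; occasional
free-text comment events embedding the patient's name exercise
stripping. The ground-truth table records, per patient, the planted
statics, crossing days, the *expected engine onsets* (computed by an
independent re-statement of the counting rule, since a patient with
three statics plus one exceedance legitimately red-flags at the
crossing), the diagnosis day and the expected delta.

What the generator does **not** emulate — correlated vitals, real ICD
coding practice, visit-frequency patterns, missingness — bounds what
passing tests show: they verify the pipeline's logic exactly under
known structure, not its behavior on real clinical data.

Single-visit patients' delivery encounters are recorded without an
encounter code (only the procedure), mirroring coding variation; their
delivery is therefore invisible to the visit extract, which is exactly
what makes them single-visit and non-evaluable downstream.

## Numerical and degenerate-input choices

* All thresholds inclusive; ties in (day, time) keep stable input
  order; unordered timelines are sorted internally.
* Percentages use decimal (not binary-float) arithmetic before
  rounding.
* Duplicate pseudonyms are a hard error naming the colliding inputs;
   16 hex characters give a collision probability ~10⁻¹¹ at 10⁵ ids.
* Empty inputs return empty outputs (summaries, reports) rather than
  raising, except where a stage dependency is genuinely missing.
* Problem sizes: the shared test fixture runs the full pipeline at 500
  patients (noise-free) and the acceptance script does the same; unit
  tests use hand-built records or 200-patient cohorts. These sizes make
  every proportion testable within 3-SD binomial bounds while keeping
  the suite fast.

## Known limitations

* The rule core is deterministic by design; no learned weighting,
  training loop, or outcome prediction is attempted, and the engine
  emits risk levels, not diagnoses.
* Delivery and prenatal code lists are placeholders matching the
  generator, not clinically authoritative sets; sites must supply
  their own.
* De-identification is structural (field removal, generalization,
  offsets, keyed pseudonyms); no formal k-anonymity or
  differential-privacy guarantee is made.
* Free-text is excluded throughout; factors that realistically need
  note parsing ("asthma unresponsive to therapy", "new or worsening
  headache") require explicit coded items here.
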