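# Methods

## The audit model

`trialaudit` operationalizes a meta-research audit of randomized controlled
trials as a deterministic rules engine over structured extraction records.
The engine deliberately contains **no text inference**: every judgment that
requires reading prose (whether a registered outcome is "too imprecise",
whether two differently worded labels denote the same outcome, whether an
outcome is an efficacy or a safety outcome) is an annotator-supplied field
or override. Given the same records and overrides, every verdict is
reproducible bit-for-bit.

### Completeness scoring

The checklist is a modified CONSORT-based peer-review tool of eleven items
(6a, 8a, 9, 11/11a/11b, 13a, 13b, 17a, 19, 23), each decomposed into
sub-items answered yes / no / NA, where NA means *non-assessable* (the
sub-item does not apply — e.g. the analysis time point of a survival
analysis), never missing data. One three-case rule is applied at every
level after excluding NA/not-applicable entries from the denominator:

- all remaining answers yes → **complete**;
- all remaining answers no → **not reported**;
- otherwise → **partial**.

The same rule blends per-outcome ratings into the multi-primary-outcome
item 6a verdict, and per-item ratings into the overall trial rating. Two
consequences worth stating: an unblinded trial (items 11a/11b skipped, not
applicable) can still be overall complete, and a trial with several primary
outcomes is complete on item 6a only if every outcome is completely
described. When the article does not clearly name its primary outcome, the
outcome assessed under item 6a is imputed in fixed preference order:
primary-objective outcome → sample-size-calculation outcome → first
registered primary → first outcome listed in the article.

The 13a/13b participant-flow ratings are also blended into one combined
participant-flow indicator for reporting, and the presence of a flow chart
is a separate descriptive field, not a scored sub-item.

### Selective reporting

*Retrospective registration* is registration strictly after the trial start
date. Dates carry their natural precision (`YYYY-MM` or `YYYY-MM-DD`) and
compare at the coarser precision of the pair, so no day is ever fabricated
for month-precision registry exports; ties are not retrospective.

*Switch classification* compares the registered primary outcomes (the
**original** registry entries; **current** entries only when no original
ones exist) with the article's primaries. Matching is exact on normalized
variable labels (trimmed, case-folded, whitespace-collapsed), extended only
by explicit annotator overrides — no fuzzy matching, for reproducibility.
Each matched pair records which fields changed (time frame, analysis
metric, or an override-flagged definition change). With A = any unmatched
outcome on either side and D = any changed pair, the category is
no-switch / add-remove / definition / combination; article without a clear
primary → non-assessable, imprecise registration → its own category, both
taking precedence over the flags (imprecise trials are excluded from
switching by design).

### Favorability

Significance of a published result is p < 0.05 for superiority designs and
the pre-set margin criterion for equivalence/non-inferiority designs;
*unclear* when neither is available or no summary measure is reported. The
outcomes **involved** in a switch are the introduced article primaries, the
omitted/demoted registered primaries, and the changed matched pairs;
retained unchanged primaries are not involved and do not gate
assessability (the source rule's wording is ambiguous here; this is the
narrower reading and none of the worked rule examples depend on it). If any
involved outcome is unclear the verdict is non-assessable — never
"does not favor" by default. Otherwise the trial favors significance if
**any** of three triggers fires: (a) introduced efficacy primary
significant; (b) omitted-or-demoted efficacy primary non-significant
(omission and demotion to secondary are treated identically); (c)
introduced safety primary non-significant. Result direction
(supports/refutes) is recorded but does not enter the verdict — the rule
keys only on significance status and the efficacy/safety type. A trial with
several discrepancies gets one verdict; one positive trigger suffices.

### Aggregation

Every indicator declares its denominator in one table-driven registry: all
trials, blinded trials, protocol-available trials, sharing-willing trials,
switch trials, or assessable switch trials. Percentages are integers with
ties rounded up — `percent(6, 16) = 38` — computed exactly in integer
arithmetic as `(200·count + d) // (2·d)`; JSON output retains the exact
fraction. Counts are additive over cohort concatenation and categorical
blocks sum to their denominators, both of which are tested.

## The synthetic-cohort generator

The generator is **label-first**: it samples each trial's latent verdicts
from configurable prevalences, then materializes raw fields (answer
vectors, outcome lists, p-values, dates) that the rules engine maps back to
exactly those verdicts. Round-trip equality — pipeline verdict = latent
label for 100 % of records — is therefore an exact test, not a statistical
one, and is asserted across seeds.

The shipped `PAPER_PREVALENCES` emulates an audited cohort of 101
colorectal-cancer RCTs using exact count fractions (5/101 overall complete,
74/101 item-6a complete, 47/47/7 blinded/unblinded/unclear, 25/25/51
sharing willing/not/none, 49/101 retrospective, 16/23 switches assessable,
6/16 favoring, ...). One published inconsistency is resolved by
construction: the four switch blocks print as 12 + 3 + 66 + 23 = 104 > 101,
so the no-switch mass is set to 63/101 to restore the partition while
keeping the three blocks that carry their own within-block percentages.

Several labels are logically entangled; they are sampled jointly so the
configured marginals are preserved:

- **Overall completeness first.** Independent item draws at the published
  item marginals would make an all-complete trial vanishingly rare
  (~10⁻³), far below the published 5 %. So overall completeness is drawn
  first (5/101); a complete trial forces all items complete, and other
  trials draw item ratings from the complementary conditional
  distributions, e.g. P(item complete | not overall complete) =
  (p_item − p_C)/(1 − p_C). A rejection step resamples the rare
  (~10⁻²–10⁻³) accidental all-complete draws in the not-complete branch;
  the marginal distortion this introduces is below 10⁻³ and ignored.
- **Unclear article primary ⇔ switch non-assessable ⇔ item 6a ≤ partial**
  (its first sub-item, "primary outcome clearly identified", is answered
  no). The switch block is drawn before the item ratings and the 6a
  conditional distribution is adjusted so both published marginals (12/101
  non-assessable, 74/101 6a-complete) hold simultaneously.
- **Favorability.** Under the stated triggers a definition-only switch can
  never *favor* (nothing is introduced or removed), so among assessable
  switch trials the favor probability is reweighted to
  (6/16)/(1 − 5/23) ≈ 0.479 within the eligible subtypes, preserving the
  6/16 marginal among all assessable switch trials. The triggering rule for
  a favoring trial is drawn as a/b/c with weights 0.4/0.4/0.2 (an
  unreported detail; any choice satisfying the category constraints works)
  and the materializer realizes exactly that trigger.
- Blinding-procedure completeness is sampled only for blinded trials
  (32/47 complete, the remainder partial — the partial/not-reported split
  among incompletely reported blinded trials is not published, so all are
  materialized partial).

Dates are drawn with day precision and converted to month precision with
probability 0.15 per date; retrospective offsets are ≥ 40 days so the
verdict is stable under month-granularity comparison. Outcome labels are
synthetic tokens ("outcome-1", "safety-outcome"); the generator makes no
attempt at realistic clinical wording, and transparency flags are sampled
independently across blocks (real cohorts likely correlate, e.g. protocol
access with data-sharing willingness). Passing tests on synthetic cohorts
therefore demonstrate the correctness of the rules engine and the
aggregation — not the realism of any text-matching step, which real
extractions exercise through the override mechanism instead.

## Problem sizes and numerical choices

- Prevalence-recovery runs use 500 cohorts of n = 101 (50 500 trials), a
  size at which the binomial standard error of a mean prevalence is ≈ 0.2
  percentage points; recovery is asserted within 3 standard errors.
- The significance threshold is strict: p = 0.05 classifies as
  non-significant. Simulated p-values avoid the boundary (uniform on
  [0.001, 0.049] / [0.06, 0.95]).
- Generated p-values, positions of missing sub-items, and date offsets come
  from a single seeded PCG64 stream per cohort; no global random state is
  touched, and identical seeds reproduce cohorts field-for-field.
- Degenerate generator configurations (e.g. a prevalence vector leaving no
  mass for a not-fully-complete trial) raise a validation or an
  infeasible-combination error rather than looping.

## Known limitations

- The engine audits registry-vs-article discrepancies only; protocols and
  statistical analysis plans are transparency indicators, not comparison
  sources.
- Outcome matching is exact-after-normalization plus overrides; genuinely
  free-text deposits need the override list (or a column mapping that
  canonicalizes labels) before classification.
- No inter-rater machinery: records encode a single annotator's judgments.
- Cohort summaries report counts and percentages only — no confidence
  intervals or hypothesis tests, matching the audit convention they mirror.
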