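# Methods

This note records the modelling assumptions, parameter defaults and
design choices behind `rcdrecur`, and what the test suite does and does
not demonstrate.

## Conventions

Dates are whole calendar days and all intervals are half-open
`[start, end)`. Fixed day counts make every boundary testable: "three
months" = 91 days, "one year" = 365 days, and the date-agreement bins
use 182 days (<6 months) and 365 days (6–12 months). Codes are
normalised by stripping dots and whitespace and upper-casing, and code
sets match by prefix ("C50.4" and "C504" are the same code; "C78"
matches every C78.x). These conventions absorb the dialect differences
between hospital-episode and registry coding.

## Outcome taxonomy and priority

Seven outcome categories form a total priority order used to resolve
same-date collisions. The default order is distant recurrence >
locoregional recurrence > recurrence of unknown type > contralateral
breast cancer > breast-cancer death > non-breast malignancy >
non-breast-cancer death. Only the first constraint (distant over
locoregional) is clinically forced — a same-day liver metastasis and
ipsilateral recurrence is recorded as distant; the rest orders outcomes
by informativeness and is configurable, with the constraint enforced at
construction.

## Code lists

The default code sets follow standard ICD semantics: breast primary
{C50, 174}, regional-node secondary {C77}, distant secondary {C78,
C79}, ignored non-melanoma skin {C44, 173}; any other invasive
malignancy-chapter code (C00–C97, 140–208) is a non-breast malignancy.
OPCS-4 defaults: breast resection {B27, B28}, reconstruction/oncoplastic
{B29, B30, B31}. The palliative-care marker {Z51.5} backs the
unknown-type rule. All sets are configuration data, not code, and
overlaps between configured sets are rejected at load time rather than
at classification time.

## Cohort selection

A woman enters the training population if her first IBC registration
falls in the accrual window and no exclusion applies, checked in a fixed
order (prior IBC; prior other-site invasive cancer, NMSC never
excluding; synchronous opposite-breast IBC; synchronous other-site
primary), with "synchronous" meaning an offset of at most 91 days
including the boundary day. Only the first matching reason is recorded,
mirroring one-reason-per-exclusion reporting. Selection is
order-independent and monotone: removing a non-index registration can
never turn an included woman into an excluded one (property-tested).

## Engine rules and tunables

* `primary_treatment_window_days` (default **270**): events inside this
  window after diagnosis (for procedures, after the first breast
  resection) are primary treatment, not recurrence evidence. Secondary
  malignancy codes inside the window are metastases present at
  diagnosis, and are never recurrences. The true clinical pathway length
  is not published; 270 days covers surgery + adjuvant chemotherapy +
  radiotherapy for a typical early-stage pathway and is configurable.
* Therapy rules are deliberately eager: palliative-intent systemic
  therapy, a chemotherapy block starting more than the treatment window
  after the adjuvant block (blocks split at >90-day gaps), palliative
  radiotherapy to a non-breast site, and repeat breast radiotherapy
  beyond one year each raise candidates; the filters then remove the
  known false-positive patterns.
* Infusion filter (defaults `min_count=4`, gaps in `[21, 200]` days):
  brackets an intravenous bisphosphonate protocol — monthly infusions
  moving to 3–6-monthly over five years. Only *single-day* attendances
  chain into a series; a multi-day admission (attribute
  `duration_days > 1`) can never be part of one, which keeps genuine
  palliative chemotherapy admissions out of the filter's reach. The
  metastasis override uses distant-secondary codes only.
* Reconstruction filter: surgical locoregional/contralateral candidates
  are dropped when the procedure carries a reconstruction code or has no
  malignancy code within ±91 days.
* Unknown-type rule: a palliative-care code after the treatment window
  with no site-specific secondary code within ±14 days yields
  recurrence-of-unknown-type. The category's true trigger rules are not
  published; this conservative stand-in produces the category without
  stealing events from the typed rules.
* Imaging records are corroborating evidence only; they never create
  candidates on their own.
* Death maps by underlying cause: breast codes (and distant-secondary
  codes) to breast-cancer death, everything else to other-cause death.

All filters only remove candidates (`|output| ≤ |input|`), the pipeline
is deterministic and independent of input record order, and both
properties are asserted in tests.

## Validation semantics

Each side (gold, RCD) resolves to a first-event status per outcome
definition: scanning date-sorted events, ignored types are skipped and
the first qualifying or censoring type decides. The default definitions:
distant recurrence qualifies {distant}, censors {both deaths, non-breast
malignancy}, ignores the other recurrence types (an earlier locoregional
event does not block a later distant one); locoregional as analysed is
"before any distant", so distant censors; any-recurrence pools the four
recurrence types. With a landmark, an event or censoring strictly before
the landmark removes the woman from the analysis period ("censored
before"); an event exactly at the landmark counts inside.

Within-window performance treats matched pairs more than
`match_window_days` (default 182) apart as missed for sensitivity and
NPV without adding them to the false-positive cell, so specificity is
invariant to the match window — also property-tested.

Confidence intervals on the accuracy proportions are Wald normal
approximations without continuity correction, clipped to [0, 100]; this
choice is pinned by reproducing a published interval exactly
((93.8, 97.3) for 518/542). Zero denominators report "undefined", never
0. Report rounding is one decimal, half away from zero. Kaplan–Meier
estimation uses `lifelines.KaplanMeierFitter` (Greenwood-variance-based
intervals with lifelines' log(−log) transform; delayed entry for
landmark analyses); an eight-woman hand-computed product-limit worksheet
and the no-censoring = empirical-CDF identity are the independent
oracles.

## Synthetic cohort generator

The generator emulates the statistical structure the validation assumes,
not any real dataset.

* **Hazards**: latent event times per outcome are piecewise exponential
  with knots at 5 and 10 years, solved in closed form so the latent
  cumulative risk hits the published trial-side values: distant
  19.5%/32.1%, locoregional 4.2%/5.7%, contralateral 0.9%/2.8% at 5/10
  years. Since the latent times are mutually independent, Kaplan–Meier
  on the truth with death as censoring recovers these targets
  (parameter-recovery is tested at n=4000–5000 within 1.5 points).
* **Onset delay**: no recurrence before 0.75 years. An adjuvant-treated
  early-stage cohort has essentially no recurrences during primary
  treatment, and the delay keeps every generated recurrence cleanly
  outside the engine's primary-treatment window so that generator truth
  is an exact oracle.
* **Death**: breast-cancer death follows distant recurrence after an
  exponential delay (mean 1.8 years); other-cause death has risks
  3.1%/3.4% at 5/10 years. These were fitted numerically so that
  breast-cancer mortality ≈ 13.4%/26.6% and all-cause mortality
  ≈ 15.0%/29.8% at 5/10 years. A single-exponential delay cannot hit
  both mortality horizons exactly; the residual misfit is ≲0.5 points.
* **Follow-up**: 19 clinic visits over five years (quarterly to four
  years, then six-monthly) and five annual visits to ten years. The gold
  standard records all true events up to death or ten years; analysis
  windows run from randomisation to last visit + 91 days. The index
  diagnosis date is taken equal to the randomisation date (the emulated
  trial enrolled women shortly after diagnosis), which makes
  "first year after diagnosis" and "first year after randomisation"
  coincide.
* **Intervention arm** (probability 0.5): single-day infusion
  attendances coded identically to chemotherapy — 6 doses q28d, 8 q92d,
  5 q183d from day 37 — stopping at five years, death, or 120 days
  before a distant recurrence (treatment stops on clinical suspicion of
  progression, which precedes the coded metastasis record; the margin
  also keeps the infusion series and the metastasis code from
  overlapping within the filter's ±91-day guard).
* **Noise knobs** (all default 0 — the baseline emulates faithful
  coding): per-event miss probability; coding date lag, discretised
  gamma with configurable mean and sd 30 days (motivated by the
  concentration of real date agreement under 6 months), applied as one
  lag per clinical episode so co-occurring evidence stays coherent;
  unknown-type degradation (a recurrence coded only as palliative care);
  first-year reconstruction surgery (days 285–364, either side);
  spurious stray metastasis codes.
* **Randomness**: one root seed; woman *i* draws from substream
  `(seed, i)`, so results are byte-reproducible and earlier women are
  unchanged when `n_women` grows.

What passing tests therefore show: the engine's logic is exactly
faithful to its rules, the metrics layer reproduces published statistics
from published counts, and detection degrades monotonically under the
modelled noise. What they do not show: performance on real NHS data —
the generator does not model coding-practice heterogeneity across
hospitals, calendar drift in code usage, visit-date jitter, or
arm-specific ascertainment differences, and the published supplementary
rule constants (exact code lists, priority table, include/censor/ignore
table) are replaced here by documented configurable defaults.

## Degenerate inputs and numerical details

Unparseable site codes never exclude a woman and never create
candidates; they are logged and treated as non-malignant. Events dated
after death are discarded at load with a warning. A history with no
primary surgery anchors the procedure rules at the index date (logged).
Malformed CSV rows are logged and skipped; a file with more than 1%
malformed rows aborts the run. Kaplan–Meier risks at horizons beyond the
last follow-up are reported as undefined rather than extrapolated.

## Problem sizes

The test suite exercises cohorts of 200–2000 women (round trips, filter
behaviour, noise monotonicity) and 4000–5000 for Kaplan–Meier parameter
recovery; the acceptance script uses 2000 for the round trip and 5000
for the risk curves. At these sizes simulation plus engine plus
validation complete in seconds on one CPU, and Monte-Carlo error on a
~20–30% cumulative risk is about 0.6–1.3 percentage points, within the
1.5-point recovery tolerance asserted.
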