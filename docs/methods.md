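# Methods

## Setting and objects

The package models the validation of an administrative hospital-claims
system against a reference-standard census of obstetric hospitalizations.
Two claims tables exist: a *reduced* table with one row per admission
authorization (AIH) — identifiers, demographics, admission/discharge dates,
a billing reason, a primary procedure, an ICU stay-days counter
(`UTI_MES_TO`-style) and up to 14 diagnosis fields — and a *professional
services* table with one row per billed act, joined by AIH number. The
reference standard has one row per true hospitalization with hospital type,
the six linkage attributes, the reason for admission, the discharge type
and 11 binary severe-morbidity indicators.

## Episode-of-care construction

A stay may be billed as several AIHs: each non-final AIH is closed with the
*continuing inpatient stay* billing reason (token "2") and a successor is
opened. Two AIHs chain when they share the person key (CNES, date of
birth), the predecessor carries the continuing token, and
`0 ≤ successor.admission − predecessor.discharge ≤ 1 day`. Chaining is
transitive; an episode is a maximal chain.

The published rule leaves ties open, so the builder fixes them
deterministically: records are processed in (admission date, AIH number)
order; each continuing AIH claims the earliest eligible successor not
already claimed; each AIH succeeds at most one predecessor. Consequences:

- the output is invariant to input row order;
- overlapping stays (negative gap) never chain and raise a data-quality
  counter;
- a missing date of birth disables chaining for that record (no usable
  person key);
- a final AIH still carrying the continuing token marks the episode
  `unresolved_continuation`, and its discharge type is *continuing
  inpatient stay*.

The greedy rule is not guaranteed to maximize the number of chained pairs
in pathological overlapping-window configurations; the test suite instead
verifies, by exhaustive enumeration over all order-respecting partitions
of every small person-key group, that the output is always a *maximal*
partition (no two chains could still be concatenated) and equals the unique
maximal partition whenever only one exists.

## The codebook

All operational definitions live in a versioned YAML document
(`src/sihvalid/data/box1_default.yaml`): the obstetric code sets, the four
reason-for-hospitalization rules, the billing-token → discharge-category
map, and the 11 criteria (severe pre-eclampsia O141; eclampsia O150–O159 or
procedure 03.03.10.002-8; HELLP O142; abruptio placentae O450/O458/O459;
post-partum/post-abortion hemorrhage, 15 fourth-character codes; uterine
rupture O710/O711; ectopic pregnancy O000–O009 or 04.11.02.004-8;
hysterectomy O822 or five procedures; laparotomy 04.07.04.016-1; blood
transfusion Z513 or nine procedures; ICU = stay-days > 0 or five
procedures). ICD patterns of 1–3 characters match as prefixes,
4-character patterns exactly; `"A to B"` entries expand to prefix ranges at
load. Procedures are 10-digit codes matched exactly. Loading validates
completeness (all 11 criteria, every billing token mapped exactly once) and
fails loudly otherwise; the loaded object serializes back to an equivalent
document.

Two deliberate readings of ambiguous source material are encoded in the
default document: the delivery row's "032 to 036" is read as O32–O36 (032
is not an ICD-10 code), and the pregnancy-complication row's "any ICD from
another group, as long as the procedure is not a delivery procedure" is
read as *primary code in none of the four reason categories' sets* — the
narrower reading would make the puerperium category unreachable by
diagnosis. The diagnosis-field list is configuration, because real extracts
differ by layout version.

## Classification

- **Obstetric stay**: any chapter-O code in any configured diagnosis field
  of any AIH in the episode, or an obstetric primary procedure — regardless
  of the AIH's position. Professional acts are *not* consulted here,
  matching the staged selection (acts are joined after obstetric
  selection); a toggle could relax this but the staged order is the
  default.
- **Reason**: evaluated on the first AIH only, precedence abortion →
  delivery → pregnancy complication → puerperium complication → catch-all
  (pregnancy complication) → other; a delivery procedure always classifies
  as delivery even when the primary diagnosis is a complication code;
  `missing` when the first AIH has neither primary diagnosis nor procedure.
- **Discharge**: the last AIH's billing reason through the codebook map;
  unknown tokens are an error, not a silent residual.
- **Criterion flags**: once per episode, evidence channels kept separate
  (ICD / primary procedure / professional act / ICU stay-days) so the
  report can reproduce a per-channel count breakdown. The flag is the union
  of its channels; adding an AIH can only turn flags on, never off.

## Linkage

Exact multi-pass matching on (CNES, dob, admission, discharge, race,
postcode): pass 1 all six; pass 2 drops postcode; pass 3 drops postcode and
race; pass 4 additionally allows discharge to differ by ≤ 1 day (split
billing shifts it). Matched records leave the pool; within a pass, any key
block with more than one candidate on either side is left unmatched and
counted, and missing values never satisfy equality. The published account
names the keys but not the pass structure or tie policy; the ordered
relaxation with conservative tie handling is this package's design, chosen
for auditability, and the pass list is configuration. The result is
provably one-to-one, and adding looser passes can only add pairs.

## Metrics

Coverage is `100·n_claims/n_reference` per hospital and per stratum
(public / private / total), rounded half away from zero to one decimal;
≥ 90 % is adequate, > 110 % flags over-recording. The reason-distribution
comparison first drops hospitals whose share of reference stays without a
recorded reason exceeds 10 % (strictly).

Validity is computed on linked pairs whose *reference* stay has at least
one morbidity indicator, per criterion and stratum: sens, spec,
LR+ = sens/(1−spec) (infinite sentinel, printed "–", when there are no
false positives), LR− = (1−sens)/spec (undefined when spec = 0).
Interpretation bands are assigned on the LR *as computed*, before display
rounding — assigning them after rounding would misband values such as an
LR− of 0.098 (strong) that prints as 0.10. The published band edges leave
gaps (9.9→10, 0.20→0.21, 0.50→0.51); the implementation closes them with
half-open intervals at 10/5/2/1 and 0.1/0.205/0.505/1. Percentages round
half away from zero (banker's rounding would disagree with several printed
values). No confidence intervals are produced, matching the analysis being
reproduced.

## Synthetic-data generator

`SimConfig` defaults encode the study conditions: 50 public and 28 private
hospitals, a 30-day admission window per hospital, women aged 10–49,
reason mix ≈ (delivery .725, abortion .088, pregnancy complication .165,
puerperium .022), discharge mix ≈ (routine .971, administrative .013,
death .001, transfer .015), per-condition prevalence of order 0.1–3 % and
per-condition, per-hospital-type recording sensitivities and false-positive
rates taken from the validation study's point estimates (e.g. severe
pre-eclampsia 0.393 public / 0.337 private; ectopic pregnancy 0.935/0.902;
HELLP 0, which the study observed as complete absence of coding).
Under-capture 14.5 % in private hospitals and over-capture 0.2 % in public
hospitals reproduce the coverage pattern (85.5 % / 100.2 %). Episode
splitting defaults to 2 % of captured stays (the split share is not
published; multi-AIH stays are a recognised but minority billing pattern),
and key corruption defaults to postcode 5 % / race 3 %.

Mechanics worth knowing when interpreting test results:

- A recorded condition is written through **one** evidence channel chosen
  uniformly among those its criterion offers, so estimated sensitivity
  converges to `record_sens` exactly; with `independent_channels=True`
  every channel flips independently and the expectation becomes the union
  `1 − Π(1 − p)`. Transfusion evidence is routed only through professional
  acts and ICU through stay-days or acts, mirroring where those procedures
  are observed in real claims; criterion diagnosis codes are placed
  uniformly over the non-primary diagnosis fields so the reason
  classification stays driven by the reason-consistent primary code
  (`concentrate_field` can instead pin a criterion to, say, the
  notification field to stress the classifier).
- Person keys (CNES, dob) are drawn unique within a hospital by default so
  the generator's pairing is exact ground truth; `p_person_collision`
  deliberately reintroduces shared birth dates to measure the collision
  risk the person-key design accepts.
- Spurious claims episodes (over-capture) and non-eligible noise rows
  (type-5 AIHs, men, out-of-age women, non-obstetric stays) exercise the
  selection stages without touching ground truth.
- Everything derives from one `numpy` generator seeded by `config.seed`;
  identical configurations give byte-identical tables.

What the generator does **not** emulate: real coding practice is not
independent across conditions or records (e.g. a hospital that under-codes
one diagnosis likely under-codes others), lengths of stay are a simple
shifted-Poisson, there are no neonatal records, no tariffs, and date
corruption is stylised. Passing the recovery tests therefore shows the
pipeline's estimators are unbiased under the stated error model, not that
real claims meet that model.

## Problem sizes and numerical choices

The bundled analyses and acceptance checks run at 78 hospitals × 100
episodes (≈ 7,800 stays) for the default-noise run and 50 × 100 for the
uniform-rate recovery run — large enough that binomial three-standard-error
bands are a few percentage points for the common criteria, small enough
that the whole suite runs in seconds. Recovery assertions use 3 binomial
SEs at the realised denominators. Ambiguity, quarantine and orphan counts
are always surfaced rather than silently resolved; degenerate inputs
(empty reference, zero reference positives or negatives, unknown billing
tokens, zero-count coverage denominators) raise descriptive errors.

## Known limitations

- The greedy successor rule is a documented choice where the published
  algorithm is silent; alternative resolutions of simultaneous open
  continuing-stay AIHs would produce different (rare) chains.
- The person-key design cannot separate two patients with the same birth
  date in the same hospital; the generator measures but the pipeline cannot
  repair this.
- The linkage pass structure is a reconstruction; the published match rate
  per pass is unknown, so only aggregate behaviour can be compared.
- Validity denominators follow the linked-morbidity design, so claims-side
  false positives among *non-morbid* women never enter specificity; that
  matches the design being reproduced but understates false-positive rates
  relative to an all-stays denominator.
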