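# Methods

This note records the model behind each pipeline stage, the defaults and why
they are what they are, and the places where the design was genuinely open.

## Registry model

A trial record carries only the fields the landscape analysis uses: an
`NCT########` identifier, study type, phase (with the combined I/II and
II/III designations as first-class bins, never split into two memberships),
recruitment status, two exclusion flags (pancreatic neuroendocrine tumor
focus; non-therapeutic purpose), disease stage, line of therapy, an endpoint
class, and one or more intervention arms. Lines of therapy beyond the second
are collapsed into a single `second_or_later` token; landscape censuses do
not distinguish further.

Every intervention arm has a leaf code in the therapeutic-category taxonomy
(drug → small molecule / monoclonal antibody / other pharmacologic;
conventional → PDAC combination-or-delivery / FDA-approved-other-cancer /
radiation; gene therapy; cellular therapy; nutraceutical; technique/
procedure; pain/quality-of-life). An arm is *systemic* exactly when its
category is not radiation, procedure, or pain/QoL. Systemic arms carry
exactly one leaf code in the mechanism taxonomy (immune with five
subclasses, adoptive cell further split into T-cell and other; DNA/cell
cycle; cell signaling with six pathway subclasses; metabolism; angiogenesis;
hormone receptors; apoptosis; symptom-targeting with three subclasses;
metastasis/invasion; unknown). Agents with several plausible mechanisms are
annotated with the single best-characterized one — the single-mechanism rule
is a validation invariant, not a multi-label option.

Category, mechanism, and novelty annotations are expert-curated *inputs*.
The package validates them against the shipped taxonomies and never
classifies free text; that boundary is what makes the census deterministic.

Cross-field invariants (systemic ⟺ mechanism present, non-empty arms,
novelty group only on late-phase records) are reported as violation lists by
`validate_record` rather than raised, so a whole snapshot can be audited in
one pass; enum tokens, by contrast, are hard-rejected at read time.

## Curation

The default filter spec admits interventional studies in phases I–III with
status recruiting, active-not-recruiting, or enrolling-by-invitation, and
excludes NET-focused and non-therapeutic records. When a record fails
several rules, the exclusion is attributed to the first failing rule in the
fixed order *status → study type → phase → NET → non-therapeutic*; the
published funnel reports only the NET and non-therapeutic counts, so the
order is a package convention chosen to make reports deterministic. The
report enforces `input − Σ excluded = output` at construction.

## Census tables

Each table is a complete partition at the leaf level; parent rows (localized
stage; drug and conventional categories; immune, adoptive-cell,
cell-signaling, and symptom mechanism classes) are sums of their children
and are emitted in taxonomy file order, which is the published display
order. Facets are bound to their natural denominators (trial facets to the
curated trial count, categories to the expanded intervention count,
mechanisms to the systemic subset); asking for any other combination is a
usage error rather than a silent re-base.

Rendering: the default is independent half-up rounding (ties away from zero
— no published cell actually exercises a tie) with the `< 1%` floor for
exact values in (0, 1). Largest-remainder apportionment is opt-in per table
because published tables mix conventions: the phase distribution only sums
to 100 under largest remainder (its 32/430 cell prints 8, where half-up
gives 7), while the mechanism table's top level matches plain half-up.  In
hierarchical largest-remainder mode each child block is constrained to its
parent's rendered value (the immune subclasses at 0.5-granularity then sum
to the parent's 37). Two published mechanism cells (45/515 → 9%, 14/515 →
3%) are inconsistent with independent nearest-0.5 rounding but consistent
with the parent-constrained scheme; the source never states its procedure,
so both behaviors are provided and neither is claimed as the original one.
Ties in fractional remainder are broken by row order (stable and
deterministic); the published tables contain no such tie.

## Impact Score

The rubric is shipped as a versioned CSV of (criterion, level, points) and
summed per trial; totals lie in [−7, 18] with 18 attained only by the unique
all-best active assignment. Numerical conventions, fixed where the printed
rubric is silent:

- `>` thresholds are strict: a 6.0-month improvement is a 1–6-month
  improvement; a 30% susceptible fraction is in the 5–30% band.
- The 1–6-month and 5–30% bands are closed on both ends; negative survival
  deltas are allowed and score 0.
- An unreported survival delta scores 0 (the lowest bin) — absent evidence
  earns no credit.
- Status has the two printed levels only (active 0, terminated-and-published
  −5); anything else must be mapped upstream.
- Susceptible fractions must lie in (0, 1]; 0 would mean the therapy applies
  to no tumor and is rejected.

Assignments may carry the raw quantity (months of PFS/OS improvement,
susceptible fraction), the level token, or both; raw values are binned at
scoring time and a stored level that disagrees with its raw value is an
error, not a silent preference. Novelty-level selection itself (the
definitions behind the four novelty tiers) is an input annotation: the
published footnote definitions are not machine-checkable. Retrospectively
scored landmark trials go through the same engine with no special casing.

Ranking is by descending total; ties share a dense rank and are ordered by
registry ID so output files are byte-stable.

## Synthetic snapshots

The generator emulates a one-day registry snapshot as *quota sampling*: each
facet's label list is built to exact configured counts and shuffled with the
seeded generator, and the per-facet lists are zipped. Tabulating a generated
snapshot therefore reproduces the quotas exactly for every seed — census
tests are exact, not statistical. The joint structure across facets is
deliberately independent (no stage×line correlation is modeled) because only
marginals are published; conclusions about joint distributions should not be
drawn from synthetic data.

Defaults are the published study conditions: 430 relevant trials with phase
quotas {134, 94, 165, 5, 32}, stage quotas {265; 60, 19, 46, 10; 30}, line
quotas {163, 168, 99}; 590 intervention arms over the category quotas
{163, 120, 27, 84, 50, 54, 23, 33, 15, 9, 12}; mechanism quotas over the 515
systemic arms matching the published mechanism table; novelty quotas
{14, 13, 7, 3} over the 37 late-phase trials; 41 NET and 10 non-therapeutic
decoys for a 481-record input. Two defaults are package choices because the
source is silent: the status split of the 430 records (301/99/30 across the
three admitted statuses — every record passes the status filter regardless)
and the arm-count allocation (arms in {1, 2, 3}; one arm each, extra arms to
the lexicographically first trials, giving a deterministic 590 from 430).
Registry IDs are sequential within a seed-offset block, which guarantees
uniqueness without coupling to the RNG stream.

Generated rubric assignments draw each criterion level from a configurable
categorical distribution and then draw any raw delta/fraction uniformly
inside the chosen level's bin (about half of lowest-bin survival deltas are
left unreported, as interim reports often omit them). The default level
distributions were fixed by convolving the criterion point distributions
exactly and requiring every total in the published score range [0, 15] to
carry at least ~1% mass (P(total ≥ 15) ≈ 0.017, P(total ≤ 0) ≈ 0.024), so a
10,000-draw sample attains the full published range with near certainty
while mid-range totals remain the most common.

## What the fixtures do and do not anchor

The packaged 37-trial compendium and its criterion assignments reproduce the
published identifiers, score totals, group totals (14/13/7/3 with the 3/2/9
novelty sub-split), and the four quoted raw survival deltas. Everything else
in those files — per-trial novelty-group membership, which five trials are
phase II/III, stage/line/status annotations, and the non-headline criterion
breakdowns — is a plausibility reconstruction (the official per-trial
breakdowns were published only as supplementary material that is not
available) and is flagged by the `_reconstructed` filename suffix. Tests
assert only the anchored totals. One taxonomy wrinkle: the category taxonomy
has no "device" node, so the three device trials in the compendium are
carried as procedures and consequently drop their mechanism annotation
(procedures are non-systemic); no anchored total depends on this.

The historical approval timeline table is shipped as static reference data
with a loader and no computation.

## Problem sizes and limitations

All computations are count/score arithmetic over ≤ 600 records; the full
test suite (including the 5,832-assignment brute-force rubric enumeration
with exhaustive single-level perturbations, the 10,000-draw score-range
sample, and 1,000-assignment rank-oracle comparison) runs in a few seconds
on one CPU. Known limitations: no live registry client (fixture- and
generator-driven only), no NLP classification, no modeling of accrual dates
or enrollment sizes, no cross-registry deduplication, and synthetic joint
structure is independence-by-shuffle as noted above.
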