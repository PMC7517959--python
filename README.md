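# trialscape

Tools for analyzing the clinical-trial landscape of pancreatic ductal
adenocarcinoma (PDAC): curation of a registry snapshot, census tabulation of
trials and interventions under controlled taxonomies, and an additive
Impact Score rubric for ranking late-phase trials.

PDAC drug development is unusually slow — standard care is still multi-agent
chemotherapy — so a recurring meta-research question is: *what is actually in
the pipeline, and which late-phase trials could move the needle?*  This
package answers that question reproducibly for registry-style snapshots. Its
intended users are trial meta-researchers and oncology analysts who have a
curated snapshot (or want a synthetic one at realistic scale) and need the
counts, percentages, and rankings to come out the same way every time.

## What it computes

**Curation.** A snapshot of registry records (a documented JSON dialect or a
flat one-row-per-arm CSV) is filtered by recruitment status, study type, and
phase, and pancreatic neuroendocrine tumor (NET) and non-therapeutic trials
are excluded. The funnel report attributes each exclusion to the first
failing rule in a fixed order, so `input − excluded = output` always holds.
Multi-arm trials are expanded into per-intervention records for
intervention-level analyses.

**Census.** Landscape tables count trials by phase, disease stage, and line
of therapy, and interventions by therapeutic category and — for the
systemically delivered subset — by mechanism of action, using two-level
controlled taxonomies. Two percentage-rendering conventions are provided,
because published tables mix them:

- *half-up*: each cell rounds independently to the nearest multiple of the
  granularity (1 or 0.5), with exact values in (0, 1) rendered `< 1%`;
- *largest remainder*: cells are floored to the granularity and the leftover
  steps are handed out by descending fractional remainder, so a block sums
  exactly to its target (100 for a top level, the parent's rendered value for
  a child block).

**Impact Score.** Each late-phase trial is scored on eight criteria —
novelty in PDAC (0–5), promise in other cancers (−2…+2), allocation design
(−1…+1), progression-free and overall survival improvement in months
(0–2 each, with raw deltas binned at strict `> 6` / closed `1–6` / `< 1`
thresholds), the expected susceptible fraction of tumors (1–3), desired
impact (0–3), and trial status (0 or −5 if terminated and published) — and
the criterion points are summed, giving totals in [−7, 18]. Trials are
ranked by descending total with dense, ID-tie-broken ranks.

**Synthetic snapshots.** A seeded generator emits registry snapshots whose
marginals are exact quotas (not multinomial draws), with decoy NET and
non-therapeutic records so the curation funnel is exercised end to end. The
defaults reproduce the landscape's study conditions: 481 records in, 430
relevant trials, 590 intervention arms, 515 systemic interventions, 37
late-phase trials.

## Worked example

```bash
trialscape generate --seed 3 --out work/gen
trialscape curate --in work/gen/registry.json --out work/cur
trialscape aggregate --in work/cur/curated.json --facet stage --denominator trials --out work/tables
```

The curate step logs the funnel to standard error:

```
INFO trialscape: curation: 481 records in
INFO trialscape: curation: excluded 41 by rule 'net'
INFO trialscape: curation: excluded 10 by rule 'non_therapeutic'
INFO trialscape: curation: 430 records out
```

and `work/tables/stage_table.md` starts:

```
| Stage (n = 430)     | n   | %   |
| ------------------- | --- | --- |
| Advanced/Metastatic | 265 | 62% |
| Localized           | 135 | 31% |
|   Resectable        | 60  | 14% |
```

i.e. 265 of the 430 curated trials (61.6%, rendered 62%) enroll
advanced/metastatic patients, and the four localized sub-stages roll up into
a 135-trial parent row. Scoring the packaged 37-trial late-phase compendium:

```bash
python - <<'PY'
from trialscape import load_phase3_assignments, score_assignment, rank_trials
ranked = rank_trials([score_assignment(a) for a in load_phase3_assignments()])
for s in ranked[:3]:
    print(s.rank, s.registry_id, s.total)
PY
```

prints

```
1 NCT03377491 15
2 NCT03504423 13
3 NCT03126435 11
```

— the tumor-treating-fields trial tops the ranking at 15/18 points (novel
mechanism +5, phase III success elsewhere +2, non-randomized −1, PFS +4.6
months +1, OS +8.2 months +2, broadly applicable +3, directly treats the
cancer +3, active 0), followed by the mitochondrial-metabolism inhibitor
trial at 13/18.

The packaged compendium and per-trial criterion assignments are
reconstructions consistent with the published group and score totals (their
filenames carry a `_reconstructed` suffix); see `docs/methods.md` for what is
anchored and what is not.

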