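"""Landscape census tables and percentage rendering.

Census tables count trials or interventions along one facet (phase, disease
stage, line of therapy, therapeutic category, or mechanism of action) under
the facet's natural denominator: the curated trial count for trial-level
facets, the expanded intervention count for categories, and the systemic
subset for mechanisms.  Hierarchical facets emit parent rows (whose counts
are the sums of their children) alongside leaf rows, in taxonomy file order.

Two rendering conventions are provided because published landscape tables mix
them:

``half_up``
    Each percentage is rounded independently to the nearest multiple of the
    granularity (ties away from zero); exact values strictly between 0 and 1
    render as ``"< 1%"``.
``largest_remainder``
    Apportionment: floor every value to the granularity, then hand out the
    remaining granularity steps in decreasing order of fractional remainder
    until the rendered values sum exactly to a target (100 for a top-level
    partition, the parent's rendered value for a child block).  Every rendered
    value stays within one granularity step of the exact value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .curation import TaggedIntervention, expand_interventions
from .errors import TableUsageError
from .registry import (
    DiseaseStage,
    InterventionRecord,
    LineOfTherapy,
    Phase,
    Taxonomy,
    TaxonomyNode,
    TrialRecord,
    category_taxonomy,
    mechanism_taxonomy,
)

TRIAL_FACETS = ("phase", "stage", "line")
INTERVENTION_FACETS = ("category", "mechanism")
FACETS = TRIAL_FACETS + INTERVENTION_FACETS

#: The denominator each facet is defined over.
FACET_DENOMINATOR = {
    "phase": "trials",
    "stage": "trials",
    "line": "trials",
    "category": "interventions",
    "mechanism": "systemic",
}

PHASE_LABELS = {
    Phase.I: "Phase I",
    Phase.I_II: "Phase I/II",
    Phase.II: "Phase II",
    Phase.II_III: "Phase II/III",
    Phase.III: "Phase III",
}

LINE_LABELS = {
    LineOfTherapy.FIRST: "First",
    LineOfTherapy.SECOND_OR_LATER: "Second or later",
    LineOfTherapy.UNSPECIFIED: "Unspecified",
}

#: Disease stage rendered as a two-level hierarchy: the four localized
#: sub-stages roll up into a "Localized" parent row.
_STAGE_TAXONOMY = Taxonomy(
    [
        TaxonomyNode("advanced_metastatic", "Advanced/Metastatic"),
        TaxonomyNode("localized", "Localized"),
        TaxonomyNode("localized_resectable", "Resectable", "localized"),
        TaxonomyNode("localized_borderline", "Borderline", "localized"),
        TaxonomyNode("localized_unresectable", "Unresectable", "localized"),
        TaxonomyNode("localized_any", "Any", "localized"),
        TaxonomyNode("unspecified", "Unspecified"),
    ]
)


# ---------------------------------------------------------------------------
# Percentage rendering
# ---------------------------------------------------------------------------

def _format_pct(value: float) -> str:
    if float(value).is_integer():
        return f"{int(round(value))}%"
    return f"{value:.1f}%"


def _half_up(value: float, granularity: float) -> float:
    # ties away from zero; values are non-negative percentages
    return math.floor(value / granularity + 0.5) * granularity


def allocate_largest_remainder(
    exact: Sequence[float], granularity: float, target_total: float
) -> list[float]:
    """Numeric largest-remainder apportionment of ``exact`` onto multiples of
    ``granularity`` summing exactly to ``target_total``.

    Raises :class:`TableUsageError` when the target is not a multiple of the
    granularity or cannot be reached with at most one step per cell.
    """
    eps = 1e-9
    steps = [math.floor(e / granularity + eps) for e in exact]
    remainders = [e / granularity - s for e, s in zip(exact, steps)]
    target_steps = target_total / granularity
    if abs(target_steps - round(target_steps)) > 1e-6:
        raise TableUsageError(
            f"target_total {target_total} is not a multiple of granularity {granularity}"
        )
    deficit = int(round(target_steps)) - sum(steps)
    if deficit < 0 or deficit > len(exact):
        raise TableUsageError(
            f"target_total {target_total} unreachable within one granularity step per cell"
        )
    order = sorted(range(len(exact)), key=lambda i: (-remainders[i], i))
    for i in order[:deficit]:
        steps[i] += 1
    return [s * granularity for s in steps]


def render_percentages(
    counts: Sequence[int],
    denominator: int,
    granularity: float = 1,
    mode: str = "half_up",
    target_total: Optional[float] = None,
) -> list[str]:
    """Render counts as display percentage tokens under one convention.

    With ``half_up`` each cell is independent and exact values in (0, 1)
    render as ``"< 1%"``.  With ``largest_remainder`` the rendered values sum
    exactly to ``target_total`` (required).
    """
    if denominator <= 0:
        raise TableUsageError("denominator must be a positive integer")
    if granularity not in (1, 0.5):
        raise TableUsageError("granularity must be 1 or 0.5")
    if any(c < 0 for c in counts):
        raise TableUsageError("counts must be non-negative")
    exact = [100.0 * c / denominator for c in counts]
    if mode == "half_up":
        tokens = []
        for value in exact:
            if 0 < value < 1:
                tokens.append("< 1%")
            else:
                tokens.append(_format_pct(_half_up(value, granularity)))
        return tokens
    if mode == "largest_remainder":
        if target_total is None:
            raise TableUsageError("largest_remainder mode requires target_total")
        values = allocate_largest_remainder(exact, granularity, target_total)
        return [_format_pct(v) for v in values]
    raise TableUsageError(f"unknown rendering mode {mode!r}")


# ---------------------------------------------------------------------------
# Landscape tables
# ---------------------------------------------------------------------------

@dataclass
class TableRow:
    code: str
    label: str
    depth: int
    parent: Optional[str]
    count: int
    exact_pct: float
    rendered_pct: str = ""


@dataclass
class LandscapeTable:
    """One census table: ordered rows of (code, count, exact %, rendered %)."""

    facet: str
    denominator: str
    total: int
    rows: list[TableRow] = field(default_factory=list)

    def row(self, code: str) -> TableRow:
        for r in self.rows:
            if r.code == code:
                return r
        raise KeyError(f"no row with code {code!r}")

    def counts(self) -> dict[str, int]:
        return {r.code: r.count for r in self.rows}

    def leaf_rows(self) -> list[TableRow]:
        parents = {r.parent for r in self.rows if r.parent is not None}
        return [r for r in self.rows if r.code not in parents]

    def check_conservation(self) -> None:
        leaf_sum = sum(r.count for r in self.leaf_rows())
        if leaf_sum != self.total:
            raise TableUsageError(
                f"{self.facet} table does not conserve counts: {leaf_sum} != {self.total}"
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (r.code, r.label, r.count, round(r.exact_pct, 2), r.rendered_pct)
                for r in self.rows
            ],
            columns=["code", "label", "count", "exact_pct", "rendered_pct"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_markdown(self) -> str:
        """An aligned pipe table mirroring the published layout (child rows
        indented under their parents)."""
        header = [f"{self.facet.capitalize()} (n = {self.total})", "n", "%"]
        body = [
            ["  " * r.depth + r.label, str(r.count), r.rendered_pct]
            for r in self.rows
        ]
        widths = [max(len(row[i]) for row in [header] + body) for i in range(3)]
        def fmt(row):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |"
        lines = [fmt(header), "| " + " | ".join("-" * w for w in widths) + " |"]
        lines += [fmt(row) for row in body]
        return "\n".join(lines) + "\n"


def _as_interventions(
    items: Sequence[Union[TrialRecord, TaggedIntervention, InterventionRecord]],
) -> list[InterventionRecord]:
    if items and isinstance(items[0], TrialRecord):
        return [t.intervention for t in expand_interventions(items)]  # type: ignore[arg-type]
    out = []
    for item in items:
        if isinstance(item, TaggedIntervention):
            out.append(item.intervention)
        elif isinstance(item, InterventionRecord):
            out.append(item)
        else:
            raise TableUsageError(f"unsupported item type {type(item).__name__}")
    return out


def systemic_filter(
    interventions: Sequence[Union[TaggedIntervention, InterventionRecord, TrialRecord]],
):
    """Keep only systemically delivered interventions (drops radiation,
    technique/procedure, and pain/quality-of-life arms)."""
    if interventions and isinstance(interventions[0], TrialRecord):
        interventions = expand_interventions(interventions)  # type: ignore[assignment]
    def _inner(item):
        return item.intervention if isinstance(item, TaggedIntervention) else item
    return [item for item in interventions if _inner(item).is_systemic]


def _hierarchy_rows(taxonomy: Taxonomy, leaf_counts: dict[str, int]) -> list[TableRow]:
    rows = []
    for node in taxonomy:
        if taxonomy.is_leaf(node.code):
            count = leaf_counts.get(node.code, 0)
        else:
            count = sum(leaf_counts.get(c, 0) for c in taxonomy.leaf_descendants(node.code))
        rows.append(
            TableRow(
                code=node.code,
                label=node.label,
                depth=taxonomy.depth(node.code),
                parent=node.parent,
                count=count,
                exact_pct=0.0,
            )
        )
    return rows


def _render_table(table: LandscapeTable, mode: str, granularity: float) -> None:
    for r in table.rows:
        r.exact_pct = 100.0 * r.count / table.total if table.total else 0.0
    if table.total == 0:
        for r in table.rows:
            r.rendered_pct = "0%"
        return
    if mode == "half_up":
        tokens = render_percentages(
            [r.count for r in table.rows], table.total, granularity, "half_up"
        )
        for r, tok in zip(table.rows, tokens):
            r.rendered_pct = tok
        return
    if mode != "largest_remainder":
        raise TableUsageError(f"unknown rendering mode {mode!r}")
    # hierarchical largest-remainder: the top level is constrained to 100 and
    # each child block is constrained to its parent's rendered value.
    by_parent: dict[Optional[str], list[TableRow]] = {}
    for r in table.rows:
        by_parent.setdefault(r.parent, []).append(r)

    def render_block(parent: Optional[str], target: float) -> None:
        block = by_parent.get(parent, [])
        if not block:
            return
        values = allocate_largest_remainder(
            [r.exact_pct for r in block], granularity, target
        )
        for r, v in zip(block, values):
            r.rendered_pct = _format_pct(v)
            render_block(r.code, v)

    render_block(None, 100.0)


def tabulate(
    items: Sequence,
    facet: str,
    denominator: str,
    mode: str = "half_up",
    granularity: float = 1,
) -> LandscapeTable:
    """Build the census table for one facet.

    ``items`` may be trial records (expanded automatically for intervention
    facets) or already-expanded interventions.  The denominator must be the
    facet's natural one; a mismatch is a usage error, not a silent re-base.
    """
    if facet not in FACETS:
        raise TableUsageError(f"unknown facet {facet!r}")
    if FACET_DENOMINATOR[facet] != denominator:
        raise TableUsageError(
            f"facet {facet!r} requires denominator {FACET_DENOMINATOR[facet]!r}, got {denominator!r}"
        )

    if facet in TRIAL_FACETS:
        if any(not isinstance(i, TrialRecord) for i in items):
            raise TableUsageError(f"facet {facet!r} requires trial records")
        trials: Sequence[TrialRecord] = items
        if facet == "phase":
            rows = [
                TableRow(p.value, PHASE_LABELS[p], 0, None,
                         sum(1 for t in trials if t.phase == p), 0.0)
                for p in Phase
            ]
        elif facet == "line":
            rows = [
                TableRow(l.value, LINE_LABELS[l], 0, None,
                         sum(1 for t in trials if t.line_of_therapy == l), 0.0)
                for l in LineOfTherapy
            ]
        else:  # stage
            leaf_counts = {
                s.value: sum(1 for t in trials if t.disease_stage == s)
                for s in DiseaseStage
            }
            rows = _hierarchy_rows(_STAGE_TAXONOMY, leaf_counts)
        table = LandscapeTable(facet, denominator, len(trials), rows)
    else:
        interventions = _as_interventions(items)
        if facet == "mechanism":
            interventions = systemic_filter(interventions)
            taxonomy = mechanism_taxonomy()
            leaf_counts: dict[str, int] = {}
            for arm in interventions:
                code = arm.mechanism_code
                if code is None:
                    raise TableUsageError(
                        "systemic intervention without mechanism code; validate the registry first"
                    )
                leaf_counts[code] = leaf_counts.get(code, 0) + 1
        else:  # category
            taxonomy = category_taxonomy()
            leaf_counts = {}
            for arm in interventions:
                leaf_counts[arm.category_code] = leaf_counts.get(arm.category_code, 0) + 1
        rows = _hierarchy_rows(taxonomy, leaf_counts)
        table = LandscapeTable(facet, denominator, len(interventions), rows)

    _render_table(table, mode, granularity)
    table.check_conservation()
    return table
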