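"""Census tables, denominators, and the two percentage-rendering modes."""

import math
from itertools import product

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialscape import (
    InterventionRecord,
    TableUsageError,
    expand_interventions,
    render_percentages,
    systemic_filter,
    tabulate,
)
from trialscape.census import allocate_largest_remainder


def _arm(category, mechanism=None):
    return InterventionRecord(name="x", category_code=category, mechanism_code=mechanism)


# ---------------------------------------------------------------------------
# systemic filter
# ---------------------------------------------------------------------------

def test_systemic_filter_toy_mix():
    toy = (
        [_arm("radiation")] * 3
        + [_arm("procedure")]
        + [_arm("pain_qol")]
        + [_arm("small_molecule", "dna_cell_cycle")] * 5
    )
    survivors = systemic_filter(toy)
    assert len(survivors) == 5
    assert all(a.mechanism_code for a in survivors)


def test_systemic_filter_only_radiation_empty():
    assert systemic_filter([_arm("radiation")] * 4) == []


def test_systemic_filter_census_scale(curated):
    assert len(systemic_filter(expand_interventions(curated))) == 515


# ---------------------------------------------------------------------------
# tabulate
# ---------------------------------------------------------------------------

def test_stage_table_matches_snapshot_marginals(curated):
    table = tabulate(curated, "stage", "trials")
    assert table.total == 430
    row = table.row("advanced_metastatic")
    assert row.count == 265
    assert row.exact_pct == pytest.approx(61.63, abs=0.01)
    assert row.rendered_pct == "62%"
    localized = table.row("localized")
    assert localized.count == 135 == sum(
        table.row(c).count
        for c in ("localized_resectable", "localized_borderline",
                  "localized_unresectable", "localized_any")
    )


def test_single_item_table(curated):
    table = tabulate(curated[:1], "phase", "trials")
    assert table.total == 1
    (full,) = [r for r in table.rows if r.count]
    assert full.exact_pct == 100.0
    assert full.rendered_pct == "100%"


def test_mechanism_parent_equals_sum_of_children(curated):
    table = tabulate(expand_interventions(curated), "mechanism", "systemic")
    assert table.total == 515
    immune = table.row("immune")
    children = [73, 33, 10, 28, 45]
    assert immune.count == 189 == sum(children)
    assert [table.row(c).count for c in
            ("checkpoint", "adoptive_cell", "oncolytic_virus", "vaccine", "other_immune")
            ] == children
    assert table.row("adoptive_cell").count == table.row("t_cell").count + table.row(
        "adoptive_other").count


def test_category_table_totals(curated):
    table = tabulate(curated, "category", "interventions")
    assert table.total == 590
    assert table.row("drug").count == 310
    assert table.row("conventional").count == 188
    top_level = [r for r in table.rows if r.depth == 0]
    assert sum(r.count for r in top_level) == 590


def test_facet_denominator_mismatch_is_usage_error(curated):
    with pytest.raises(TableUsageError, match="denominator"):
        tabulate(curated, "mechanism", "trials")
    with pytest.raises(TableUsageError, match="denominator"):
        tabulate(curated, "phase", "interventions")
    with pytest.raises(TableUsageError, match="facet"):
        tabulate(curated, "endpoint", "trials")


def test_conservation_in_every_facet(curated):
    for facet, denom in (
        ("phase", "trials"), ("stage", "trials"), ("line", "trials"),
        ("category", "interventions"), ("mechanism", "systemic"),
    ):
        table = tabulate(curated, facet, denom)
        table.check_conservation()
        assert sum(r.count for r in table.leaf_rows()) == table.total


def test_markdown_and_csv_outputs(curated, tmp_path):
    table = tabulate(curated, "stage", "trials")
    md = table.to_markdown()
    assert md.splitlines()[2].startswith("| Advanced/Metastatic")
    assert "| 265" in md.splitlines()[2]
    path = tmp_path / "stage.csv"
    table.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "code,label,count,exact_pct,rendered_pct"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,denominator,granularity,expected",
    [
        ([134], 430, 1, ["31%"]),
        ([32], 430, 1, ["7%"]),       # half-up disagrees with largest-remainder here
        ([3], 515, 1, ["< 1%"]),
        ([33], 515, 0.5, ["6.5%"]),
        ([0], 430, 1, ["0%"]),
    ],
)
def test_half_up_rendering(counts, denominator, granularity, expected):
    assert render_percentages(counts, denominator, granularity) == expected


def test_largest_remainder_phase_vector():
    tokens = render_percentages(
        [134, 94, 165, 5, 32], 430, mode="largest_remainder", target_total=100
    )
    assert tokens == ["31%", "22%", "38%", "1%", "8%"]


def test_largest_remainder_immune_subtable_sums_to_parent():
    tokens = render_percentages(
        [73, 33, 10, 28, 45], 515, granularity=0.5,
        mode="largest_remainder", target_total=37,
    )
    assert tokens == ["14%", "6.5%", "2%", "5.5%", "9%"]
    values = [float(t.rstrip("%")) for t in tokens]
    assert sum(values) == 37


def test_rendering_errors():
    with pytest.raises(TableUsageError, match="positive"):
        render_percentages([1], 0)
    with pytest.raises(TableUsageError, match="target_total"):
        render_percentages([1], 10, mode="largest_remainder")
    with pytest.raises(TableUsageError, match="unreachable"):
        render_percentages([50], 100, mode="largest_remainder", target_total=100)
    with pytest.raises(TableUsageError, match="mode"):
        render_percentages([1], 10, mode="banker")


def test_half_up_permutation_invariance(curated):
    counts = [134, 94, 165, 5, 32]
    tokens = render_percentages(counts, 430)
    rev = render_percentages(counts[::-1], 430)
    assert tokens == rev[::-1]


def test_hierarchical_largest_remainder_children_sum_to_parent(curated):
    table = tabulate(
        expand_interventions(curated), "mechanism", "systemic",
        mode="largest_remainder", granularity=0.5,
    )
    immune_value = float(table.row("immune").rendered_pct.rstrip("%"))
    child_sum = sum(
        float(table.row(c).rendered_pct.rstrip("%"))
        for c in ("checkpoint", "adoptive_cell", "oncolytic_virus", "vaccine", "other_immune")
    )
    assert child_sum == immune_value
    top_sum = sum(
        float(r.rendered_pct.rstrip("%")) for r in table.rows if r.depth == 0
    )
    assert top_sum == 100


def _oracle_min_deviation(exact, granularity, target):
    """All floor/ceil allocations meeting the target, minimizing total
    absolute deviation from the exact values (brute-force enumeration)."""
    floors = [math.floor(e / granularity + 1e-9) for e in exact]
    best = None
    allocations = []
    for bits in product((0, 1), repeat=len(exact)):
        values = [(f + b) * granularity for f, b in zip(floors, bits)]
        if abs(sum(values) - target) > 1e-9:
            continue
        deviation = sum(abs(v - e) for v, e in zip(values, exact))
        allocations.append((deviation, values))
    best = min(d for d, _ in allocations)
    return best, [v for d, v in allocations if abs(d - best) < 1e-9]


@given(
    counts=st.lists(st.integers(0, 200), min_size=1, max_size=6),
    denominator=st.integers(1, 400),
    granularity=st.sampled_from([1, 0.5]),
    data=st.data(),
)
def test_largest_remainder_matches_minimal_adjustment_oracle(
    counts, denominator, granularity, data
):
    """The apportionment sums exactly to the target, stays within one
    granularity step of each exact value, and achieves the minimal total
    adjustment among all floor/ceil allocations."""
    exact = [100.0 * c / denominator for c in counts]
    floors = [math.floor(e / granularity + 1e-9) for e in exact]
    k = data.draw(st.integers(0, len(counts)))
    target = (sum(floors) + k) * granularity
    values = allocate_largest_remainder(exact, granularity, target)
    assert abs(sum(values) - target) < 1e-9
    assert all(abs(v - e) < granularity + 1e-9 for v, e in zip(values, exact))
    best, minimal = _oracle_min_deviation(exact, granularity, target)
    deviation = sum(abs(v - e) for v, e in zip(values, exact))
    assert abs(deviation - best) < 1e-9, (values, minimal)
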