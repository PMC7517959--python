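"""Curation of a registry snapshot: the filter funnel and multi-arm expansion.

The default filter set mirrors the query used to assemble the landscape:
interventional studies in phases I through III whose status is recruiting,
active-not-recruiting, or enrolling-by-invitation, with pancreatic
neuroendocrine tumor (NET) trials and non-therapeutic trials (imaging,
detection) excluded.  Each excluded record is attributed to the *first*
failing rule in a fixed order (status, study type, phase, NET,
non-therapeutic) so that the report is deterministic even when a record fails
several rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import yaml

from .errors import ConfigError, RecordValidationError
from .registry import (
    InterventionRecord,
    NoveltyGroup,
    Phase,
    RecruitmentStatus,
    StudyType,
    TrialRecord,
)

#: Fixed attribution order for the exclusion report.
RULE_ORDER = ("status", "study_type", "phase", "net", "non_therapeutic")


@dataclass(frozen=True)
class FilterSpec:
    """Which records survive curation."""

    allowed_phases: frozenset[Phase]
    allowed_statuses: frozenset[RecruitmentStatus]
    study_type: StudyType = StudyType.INTERVENTIONAL
    exclude_net: bool = True
    exclude_non_therapeutic: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_phases:
            raise ConfigError("allowed_phases must be non-empty")
        if not self.allowed_statuses:
            raise ConfigError("allowed_statuses must be non-empty")

    @classmethod
    def default(cls) -> "FilterSpec":
        """The snapshot query: phases I-III, the three active statuses,
        interventional only, NET and non-therapeutic trials dropped."""
        return cls(
            allowed_phases=frozenset(Phase),
            allowed_statuses=frozenset(
                {
                    RecruitmentStatus.RECRUITING,
                    RecruitmentStatus.ACTIVE_NOT_RECRUITING,
                    RecruitmentStatus.ENROLLING_BY_INVITATION,
                }
            ),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FilterSpec":
        """Load from a key/value configuration file (YAML or JSON)."""
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: filter spec must be a mapping")
        try:
            return cls(
                allowed_phases=frozenset(Phase(p) for p in raw["allowed_phases"]),
                allowed_statuses=frozenset(
                    RecruitmentStatus(s) for s in raw["allowed_statuses"]
                ),
                study_type=StudyType(raw.get("study_type", "interventional")),
                exclude_net=bool(raw.get("exclude_net", True)),
                exclude_non_therapeutic=bool(raw.get("exclude_non_therapeutic", True)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing filter key {exc}") from exc
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class CurationReport:
    """Funnel accounting: input size, per-rule exclusions, output size."""

    input_count: int
    excluded_by_rule: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def __post_init__(self) -> None:
        total_excluded = sum(self.excluded_by_rule.values())
        if self.input_count - total_excluded != self.output_count:
            raise ConfigError(
                "curation report does not conserve records: "
                f"{self.input_count} - {total_excluded} != {self.output_count}"
            )

    def log_lines(self) -> list[str]:
        lines = [f"curation: {self.input_count} records in"]
        for rule in RULE_ORDER:
            count = self.excluded_by_rule.get(rule, 0)
            if count:
                lines.append(f"curation: excluded {count} by rule '{rule}'")
        lines.append(f"curation: {self.output_count} records out")
        return lines

    def to_frame(self):
        import pandas as pd

        rows = [("input", self.input_count)]
        rows += [(f"excluded_{r}", self.excluded_by_rule.get(r, 0)) for r in RULE_ORDER]
        rows.append(("output", self.output_count))
        return pd.DataFrame(rows, columns=["stage", "count"])

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def _first_failed_rule(record: TrialRecord, spec: FilterSpec) -> Optional[str]:
    if record.recruitment_status not in spec.allowed_statuses:
        return "status"
    if record.study_type != spec.study_type:
        return "study_type"
    if record.phase not in spec.allowed_phases:
        return "phase"
    if spec.exclude_net and record.is_net:
        return "net"
    if spec.exclude_non_therapeutic and not record.is_therapeutic:
        return "non_therapeutic"
    return None


def apply_filters(
    records: Sequence[TrialRecord], spec: Optional[FilterSpec] = None
) -> tuple[list[TrialRecord], CurationReport]:
    """Filter a snapshot, returning the survivors and the funnel report."""
    spec = spec or FilterSpec.default()
    excluded = {rule: 0 for rule in RULE_ORDER}
    kept: list[TrialRecord] = []
    for record in records:
        rule = _first_failed_rule(record, spec)
        if rule is None:
            kept.append(record)
        else:
            excluded[rule] += 1
    report = CurationReport(
        input_count=len(records), excluded_by_rule=excluded, output_count=len(kept)
    )
    return kept, report


class TaggedIntervention(NamedTuple):
    """An intervention arm tagged with its source trial for re-grouping."""

    registry_id: str
    intervention: InterventionRecord


def expand_interventions(records: Sequence[TrialRecord]) -> list[TaggedIntervention]:
    """Separate multi-arm trials into one record per intervention arm.

    Output size equals the sum of arm counts; the source tag permits exact
    reconstruction of per-trial arm counts.
    """
    out: list[TaggedIntervention] = []
    for record in records:
        if not record.interventions:
            raise RecordValidationError(
                f"{record.registry_id}: cannot expand a trial with zero interventions"
            )
        out.extend(
            TaggedIntervention(record.registry_id, arm) for arm in record.interventions
        )
    return out


def group_phase3(records: Sequence[TrialRecord]) -> dict[NoveltyGroup, int]:
    """Count late-phase (II/III and III) trials by novelty group.

    Every eligible record must carry a novelty-group annotation; groups absent
    from the data are reported as zero.
    """
    counts = {group: 0 for group in NoveltyGroup}
    for record in records:
        if not record.phase.is_late:
            continue
        if record.novelty_group is None:
            raise RecordValidationError(
                f"{record.registry_id}: late-phase trial missing novelty_group annotation"
            )
        counts[record.novelty_group] += 1
    return counts
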