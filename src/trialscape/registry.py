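"""Domain model for registry trial records and the two controlled taxonomies.

A :class:`TrialRecord` is one registered interventional study carrying the
curated annotations used throughout the landscape analysis: phase, recruitment
status, disease stage of the enrolled population, line of therapy, an endpoint
class, and one or more intervention arms.  Each :class:`InterventionRecord`
carries a therapeutic-category code (small molecule, monoclonal antibody,
radiation, ...) and — when the intervention is delivered systemically — exactly
one mechanism-of-action code (checkpoint inhibitor, DNA/cell-cycle, ...).

Category, mechanism, and novelty-group annotations are *input data* curated by
experts upstream; this module validates them against the shipped taxonomies
but never infers them from free text.

Two file dialects are supported: a versioned JSON envelope (one object per
study) and a flat CSV with one row per intervention arm and trial-level fields
repeated.  Both round-trip losslessly through :func:`read_registry` /
:func:`write_registry`.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import RecordValidationError, RegistryParseError

SCHEMA_VERSION = "1.0"

NCT_PATTERN = re.compile(r"^NCT\d{8}$")

#: Therapeutic-category leaves that are *not* delivered systemically and
#: therefore never carry a mechanism code.
NON_SYSTEMIC_CATEGORIES = frozenset({"radiation", "procedure", "pain_qol"})


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class StudyType(str, Enum):
    INTERVENTIONAL = "interventional"
    OBSERVATIONAL = "observational"


class Phase(str, Enum):
    """Clinical phase; combined designations are first-class bins, never split."""

    I = "I"
    I_II = "I_II"
    II = "II"
    II_III = "II_III"
    III = "III"

    @property
    def is_late(self) -> bool:
        """True for the phase II/III and phase III bins (the late-phase cohort)."""
        return self in (Phase.II_III, Phase.III)


class RecruitmentStatus(str, Enum):
    RECRUITING = "recruiting"
    ACTIVE_NOT_RECRUITING = "active_not_recruiting"
    ENROLLING_BY_INVITATION = "enrolling_by_invitation"
    COMPLETED = "completed"
    TERMINATED = "terminated"
    SUSPENDED = "suspended"
    WITHDRAWN = "withdrawn"
    UNKNOWN = "unknown"


class DiseaseStage(str, Enum):
    ADVANCED_METASTATIC = "advanced_metastatic"
    LOCALIZED_RESECTABLE = "localized_resectable"
    LOCALIZED_BORDERLINE = "localized_borderline"
    LOCALIZED_UNRESECTABLE = "localized_unresectable"
    LOCALIZED_ANY = "localized_any"
    UNSPECIFIED = "unspecified"

    @property
    def is_localized(self) -> bool:
        return self.value.startswith("localized")


class LineOfTherapy(str, Enum):
    FIRST = "first"
    SECOND_OR_LATER = "second_or_later"
    UNSPECIFIED = "unspecified"


class EndpointClass(str, Enum):
    SURVIVAL = "survival"
    QUALITY_OF_LIFE = "quality_of_life"
    PAIN = "pain"
    COMPLICATION = "complication"
    SEQUELAE = "sequelae"
    INFECTION = "infection"


class NoveltyGroup(str, Enum):
    """Late-phase grouping: what kind of question a phase III trial asks."""

    NOVEL_INTERVENTION = "novel_intervention"
    CONVENTIONAL_MANIPULATION = "conventional_manipulation"
    TECHNICAL_PROCEDURE = "technical_procedure"
    PAIN_MANAGEMENT = "pain_management"


class NoveltySubgroup(str, Enum):
    """Optional sub-split of the novel-intervention group."""

    EFFICACY_OTHER_CANCER = "efficacy_other_cancer"
    REPURPOSED_NON_CANCER = "repurposed_non_cancer"
    NOVEL_TO_ALL = "novel_to_all"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

class InterventionRecord(BaseModel):
    """One therapeutic intervention arm of a trial."""

    model_config = ConfigDict(extra="forbid")

    name: str
    category_code: str
    mechanism_code: Optional[str] = None

    @property
    def is_systemic(self) -> bool:
        """Systemic delivery (drug/cell/viral/...), i.e. anything that is not
        radiation, a technique/procedure, or a pain/quality-of-life intervention."""
        return self.category_code not in NON_SYSTEMIC_CATEGORIES


class TrialRecord(BaseModel):
    """One registered study with its curated annotations and intervention arms.

    Enum fields are hard-validated at construction (unknown tokens are
    rejected).  Cross-field invariants — the systemic/mechanism rule, the
    novelty-group phase restriction, arm non-emptiness — are *soft* checks
    reported by :func:`validate_record` so that invalid data can be inspected
    rather than merely raising.
    """

    model_config = ConfigDict(extra="forbid")

    registry_id: str
    title: str
    study_type: StudyType
    phase: Phase
    recruitment_status: RecruitmentStatus
    is_net: bool
    is_therapeutic: bool
    disease_stage: DiseaseStage
    line_of_therapy: LineOfTherapy
    endpoint_class: EndpointClass
    interventions: list[InterventionRecord]
    novelty_group: Optional[NoveltyGroup] = None
    novelty_subgroup: Optional[NoveltySubgroup] = None


# ---------------------------------------------------------------------------
# Taxonomies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyNode:
    code: str
    label: str
    parent: Optional[str] = None


class Taxonomy:
    """An ordered forest of coded nodes loaded from a ``code,label,parent`` CSV.

    Node order follows file order, which is also the display order used by the
    census tables.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.code in self._nodes:
                raise RegistryParseError(f"duplicate taxonomy code {node.code!r}")
            self._nodes[node.code] = node
        for node in self._nodes.values():
            if node.parent is not None and node.parent not in self._nodes:
                raise RegistryParseError(
                    f"taxonomy node {node.code!r} references unknown parent {node.parent!r}"
                )
        # cycle check via ancestor walk
        for code in self._nodes:
            self.ancestors(code)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Taxonomy":
        with open(path, newline="", encoding="utf-8") as handle:
            return cls._from_reader(csv.DictReader(handle), str(path))

    @classmethod
    def from_text(cls, text: str, source: str = "<string>") -> "Taxonomy":
        return cls._from_reader(csv.DictReader(io.StringIO(text)), source)

    @classmethod
    def _from_reader(cls, reader: csv.DictReader, source: str) -> "Taxonomy":
        if reader.fieldnames is None or set(reader.fieldnames) != {"code", "label", "parent"}:
            raise RegistryParseError(f"{source}: taxonomy header must be code,label,parent")
        nodes = [
            TaxonomyNode(row["code"], row["label"], row["parent"] or None)
            for row in reader
        ]
        return cls(nodes)

    def __contains__(self, code: str) -> bool:
        return code in self._nodes

    def __iter__(self):
        return iter(self._nodes.values())

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, code: str) -> TaxonomyNode:
        try:
            return self._nodes[code]
        except KeyError:
            raise KeyError(f"unknown taxonomy code {code!r}") from None

    def label(self, code: str) -> str:
        return self.node(code).label

    def children(self, code: Optional[str]) -> list[TaxonomyNode]:
        return [n for n in self._nodes.values() if n.parent == code]

    def roots(self) -> list[TaxonomyNode]:
        return self.children(None)

    def is_leaf(self, code: str) -> bool:
        return not self.children(code)

    def leaves(self) -> list[TaxonomyNode]:
        return [n for n in self._nodes.values() if self.is_leaf(n.code)]

    def ancestors(self, code: str) -> list[str]:
        """Codes from the node's parent up to its root (cycle-safe)."""
        out: list[str] = []
        seen = {code}
        current = self.node(code).parent
        while current is not None:
            if current in seen:
                raise RegistryParseError(f"taxonomy cycle involving {current!r}")
            seen.add(current)
            out.append(current)
            current = self.node(current).parent
        return out

    def depth(self, code: str) -> int:
        return len(self.ancestors(code))

    def descendants(self, code: str) -> list[str]:
        """Descendant codes in depth-first preorder (display order)."""
        out: list[str] = []
        for child in self.children(code):
            out.append(child.code)
            out.extend(self.descendants(child.code))
        return out

    def leaf_descendants(self, code: str) -> list[str]:
        if self.is_leaf(code):
            return [code]
        return [c for c in self.descendants(code) if self.is_leaf(c)]


def _data_text(name: str) -> str:
    return resources.files("trialscape.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def category_taxonomy() -> Taxonomy:
    """The shipped therapeutic-category taxonomy (drug, conventional, gene
    therapy, cellular therapy, nutraceutical, procedure, pain/QoL)."""
    return Taxonomy.from_text(_data_text("therapeutic_categories.csv"), "therapeutic_categories.csv")


@lru_cache(maxsize=None)
def mechanism_taxonomy() -> Taxonomy:
    """The shipped mechanism-of-action taxonomy (immune, DNA/cell cycle,
    cell signaling, metabolism, ...)."""
    return Taxonomy.from_text(_data_text("mechanisms.csv"), "mechanisms.csv")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_record(
    record: TrialRecord,
    categories: Optional[Taxonomy] = None,
    mechanisms: Optional[Taxonomy] = None,
) -> list[str]:
    """Return violation descriptions for every broken invariant (empty = valid).

    Violations are data, not exceptions: each entry names the offending field
    and the rule so callers can report them in bulk.
    """
    categories = categories or category_taxonomy()
    mechanisms = mechanisms or mechanism_taxonomy()
    rid = record.registry_id
    violations: list[str] = []

    if not NCT_PATTERN.match(rid):
        violations.append(f"{rid}: registry_id: must match 'NCT' + 8 digits")
    if not record.interventions:
        violations.append(f"{rid}: interventions: must contain at least one arm")
    if record.novelty_group is not None and not record.phase.is_late:
        violations.append(
            f"{rid}: novelty_group: only phase II/III and III trials carry a novelty group"
        )
    if record.novelty_subgroup is not None and record.novelty_group != NoveltyGroup.NOVEL_INTERVENTION:
        violations.append(
            f"{rid}: novelty_subgroup: only novel-intervention trials carry a sub-group"
        )

    for i, arm in enumerate(record.interventions):
        where = f"{rid}: interventions[{i}]"
        if arm.category_code not in categories:
            violations.append(f"{where}.category_code: unknown code {arm.category_code!r}")
        elif not categories.is_leaf(arm.category_code):
            violations.append(
                f"{where}.category_code: {arm.category_code!r} is not a leaf category"
            )
        if arm.is_systemic:
            if arm.mechanism_code is None:
                violations.append(
                    f"{where}.mechanism_code: systemic intervention requires exactly one mechanism"
                )
            elif arm.mechanism_code not in mechanisms:
                violations.append(
                    f"{where}.mechanism_code: unknown code {arm.mechanism_code!r}"
                )
            elif not mechanisms.is_leaf(arm.mechanism_code):
                violations.append(
                    f"{where}.mechanism_code: {arm.mechanism_code!r} is not a leaf mechanism"
                )
        elif arm.mechanism_code is not None:
            violations.append(
                f"{where}.mechanism_code: non-systemic intervention must not carry a mechanism"
            )
    return violations


def validate_registry(records: Sequence[TrialRecord], **kwargs) -> list[str]:
    """Validate a whole registry; also flags duplicate registry IDs."""
    violations: list[str] = []
    seen: set[str] = set()
    for record in records:
        if record.registry_id in seen:
            violations.append(f"{record.registry_id}: registry_id: duplicate identifier")
        seen.add(record.registry_id)
        violations.extend(validate_record(record, **kwargs))
    return violations


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CSV_TRIAL_FIELDS = [
    "registry_id", "title", "study_type", "phase", "recruitment_status",
    "is_net", "is_therapeutic", "disease_stage", "line_of_therapy",
    "endpoint_class", "novelty_group", "novelty_subgroup",
]
_CSV_ARM_FIELDS = ["intervention_name", "category_code", "mechanism_code"]
CSV_COLUMNS = _CSV_TRIAL_FIELDS + _CSV_ARM_FIELDS


def _infer_dialect(path: Union[str, Path], dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("json", "csv"):
            raise RegistryParseError(f"unknown registry dialect {dialect!r}")
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise RegistryParseError(f"cannot infer registry dialect from {path!s}")


def _build_record(payload: dict, where: str) -> TrialRecord:
    try:
        return TrialRecord.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"])
        rid = payload.get("registry_id", "<missing id>")
        raise RecordValidationError(
            f"{where} (registry_id={rid}): field {field!r}: {first['msg']}"
        ) from exc


def read_registry(path: Union[str, Path], dialect: Optional[str] = None) -> list[TrialRecord]:
    """Read trial records from a JSON or CSV registry file.

    Unknown enum tokens are rejected with an error naming the field and the
    record, never coerced.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        return _read_json(path)
    return _read_csv(path)


def _read_json(path: Union[str, Path]) -> list[TrialRecord]:
    with open(path, encoding="utf-8") as handle:
        try:
            payload = json.load(handle)
        except json.JSONDecodeError as exc:
            raise RegistryParseError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, dict) or "trials" not in payload:
        raise RegistryParseError(f"{path}: expected an object with a 'trials' array")
    trials = payload["trials"]
    if not isinstance(trials, list):
        raise RegistryParseError(f"{path}: 'trials' must be an array")
    return [_build_record(entry, f"{path}: record {i}") for i, entry in enumerate(trials)]


def _read_csv(path: Union[str, Path]) -> list[TrialRecord]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise RegistryParseError(f"{path}: empty CSV file (missing header)")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise RegistryParseError(f"{path}: missing columns {sorted(missing)}")
        grouped: dict[str, dict] = {}
        for line_no, row in enumerate(reader, start=2):
            rid = row["registry_id"]
            if not rid:
                raise RegistryParseError(f"{path}: line {line_no}: empty registry_id")
            if rid not in grouped:
                payload = {f: (row[f] or None) for f in _CSV_TRIAL_FIELDS}
                payload["is_net"] = _parse_bool(row["is_net"], path, line_no, "is_net")
                payload["is_therapeutic"] = _parse_bool(
                    row["is_therapeutic"], path, line_no, "is_therapeutic"
                )
                payload["interventions"] = []
                grouped[rid] = payload
            arm = {
                "name": row["intervention_name"],
                "category_code": row["category_code"],
                "mechanism_code": row["mechanism_code"] or None,
            }
            grouped[rid]["interventions"].append(arm)
    return [
        _build_record(payload, f"{path}: record {i}")
        for i, payload in enumerate(grouped.values())
    ]


def _parse_bool(token: str, path, line_no: int, field: str) -> bool:
    if token == "true":
        return True
    if token == "false":
        return False
    raise RegistryParseError(
        f"{path}: line {line_no}: field {field!r}: expected 'true' or 'false', got {token!r}"
    )


def write_registry(
    records: Sequence[TrialRecord],
    path: Union[str, Path],
    dialect: Optional[str] = None,
) -> None:
    """Write records so that :func:`read_registry` reproduces them exactly."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "trials": [r.model_dump(mode="json", exclude_none=True) for r in records],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)
            handle.write("\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for record in records:
            base = [
                record.registry_id, record.title, record.study_type.value,
                record.phase.value, record.recruitment_status.value,
                "true" if record.is_net else "false",
                "true" if record.is_therapeutic else "false",
                record.disease_stage.value, record.line_of_therapy.value,
                record.endpoint_class.value,
                record.novelty_group.value if record.novelty_group else "",
                record.novelty_subgroup.value if record.novelty_subgroup else "",
            ]
            for arm in record.interventions:
                writer.writerow(base + [arm.name, arm.category_code, arm.mechanism_code or ""])


def load_phase3_compendium() -> list[TrialRecord]:
    """The packaged 37-trial late-phase compendium.

    Registry IDs, intervention names, and score-relevant totals follow the
    published compendium; the novelty-group column and several per-trial
    annotations (stage, line, combined-phase membership) are *reconstructions*
    consistent with the published group totals (14/13/7/3) and are shipped for
    testing, not as primary data.
    """
    ref = resources.files("trialscape.data").joinpath("phase3_trials_reconstructed.csv")
    with resources.as_file(ref) as path:
        return _read_csv(path)


def load_fda_timeline():
    """Historical FDA-approval timeline, shipped as static reference data only."""
    import pandas as pd

    return pd.read_csv(io.StringIO(_data_text("fda_timeline.csv")))
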