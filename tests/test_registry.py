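"""Registry records, taxonomies, file dialects, and invariant validation."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialscape import (
    InterventionRecord,
    NoveltyGroup,
    Phase,
    RecordValidationError,
    RegistryParseError,
    Taxonomy,
    TrialRecord,
    category_taxonomy,
    load_fda_timeline,
    mechanism_taxonomy,
    read_registry,
    validate_record,
    validate_registry,
    write_registry,
)

TWO_RECORD_PAYLOAD = {
    "schema_version": "1.0",
    "trials": [
        {
            "registry_id": "NCT00000001",
            "title": "Phase I dose escalation of a checkpoint inhibitor",
            "study_type": "interventional",
            "phase": "I",
            "recruitment_status": "recruiting",
            "is_net": False,
            "is_therapeutic": True,
            "disease_stage": "advanced_metastatic",
            "line_of_therapy": "second_or_later",
            "endpoint_class": "survival",
            "interventions": [
                {
                    "name": "anti-PD-1 antibody",
                    "category_code": "monoclonal_antibody",
                    "mechanism_code": "checkpoint",
                }
            ],
        },
        {
            "registry_id": "NCT00000002",
            "title": "Phase III chemoradiation, locally advanced disease",
            "study_type": "interventional",
            "phase": "III",
            "recruitment_status": "active_not_recruiting",
            "is_net": False,
            "is_therapeutic": True,
            "disease_stage": "localized_unresectable",
            "line_of_therapy": "first",
            "endpoint_class": "survival",
            "novelty_group": "conventional_manipulation",
            "interventions": [
                {"name": "chemoradiation", "category_code": "radiation"}
            ],
        },
    ],
}


@pytest.fixture
def two_record_file(tmp_path):
    path = tmp_path / "two.json"
    path.write_text(json.dumps(TWO_RECORD_PAYLOAD))
    return path


def test_hand_built_fixture_reads_field_by_field(two_record_file):
    records = read_registry(two_record_file)
    assert len(records) == 2
    first, second = records
    src = TWO_RECORD_PAYLOAD["trials"][0]
    assert first.registry_id == src["registry_id"]
    assert first.title == src["title"]
    assert first.phase == Phase.I
    assert first.study_type.value == src["study_type"]
    assert first.recruitment_status.value == src["recruitment_status"]
    assert first.is_net is False and first.is_therapeutic is True
    assert first.disease_stage.value == src["disease_stage"]
    assert first.line_of_therapy.value == src["line_of_therapy"]
    assert first.endpoint_class.value == src["endpoint_class"]
    assert first.novelty_group is None
    assert [i.model_dump(exclude_none=True) for i in first.interventions] == src["interventions"]
    assert second.phase == Phase.III
    assert second.novelty_group == NoveltyGroup.CONVENTIONAL_MANIPULATION
    assert second.interventions[0].mechanism_code is None


@pytest.mark.parametrize("dialect", ["json", "csv"])
def test_round_trip_identity(dialect, tmp_path, snapshot):
    path = tmp_path / f"reg.{dialect}"
    records = snapshot[:60]
    write_registry(records, path, dialect)
    assert read_registry(path, dialect) == records


@pytest.mark.parametrize("dialect", ["json", "csv"])
def test_round_trip_empty_registry(dialect, tmp_path):
    path = tmp_path / f"empty.{dialect}"
    write_registry([], path, dialect)
    assert read_registry(path, dialect) == []


@pytest.mark.parametrize("dialect", ["json", "csv"])
def test_optional_fields_stay_absent(dialect, tmp_path, compendium):
    path = tmp_path / f"comp.{dialect}"
    write_registry(compendium, path, dialect)
    back = read_registry(path, dialect)
    assert back == compendium
    no_subgroup = [r for r in back if r.novelty_subgroup is None]
    assert no_subgroup and all(r.novelty_subgroup is None for r in no_subgroup)


def test_unknown_enum_token_rejected_naming_field(tmp_path):
    payload = json.loads(json.dumps(TWO_RECORD_PAYLOAD))
    payload["trials"][0]["phase"] = "IV"
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(payload))
    with pytest.raises(RecordValidationError, match="phase"):
        read_registry(path)


def test_malformed_json_names_line(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"trials": [')
    with pytest.raises(RegistryParseError, match="line"):
        read_registry(path)


def test_csv_missing_columns_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("registry_id,title\nNCT00000001,x\n")
    with pytest.raises(RegistryParseError, match="missing columns"):
        read_registry(path)


def test_taxonomy_structure():
    cats = category_taxonomy()
    mechs = mechanism_taxonomy()
    assert {n.code for n in cats.roots()} >= {"drug", "conventional", "gene_therapy"}
    assert cats.leaf_descendants("drug") == [
        "small_molecule", "monoclonal_antibody", "other_pharma"
    ]
    assert mechs.leaf_descendants("immune") == [
        "checkpoint", "t_cell", "adoptive_other", "oncolytic_virus", "vaccine", "other_immune"
    ]
    assert mechs.depth("t_cell") == 2
    assert mechs.ancestors("t_cell") == ["adoptive_cell", "immune"]


def test_taxonomy_cycle_and_duplicate_rejected():
    from trialscape.registry import TaxonomyNode

    with pytest.raises(RegistryParseError, match="cycle"):
        Taxonomy([TaxonomyNode("a", "A", "b"), TaxonomyNode("b", "B", "a")])
    with pytest.raises(RegistryParseError, match="duplicate"):
        Taxonomy([TaxonomyNode("a", "A"), TaxonomyNode("a", "A2")])


def test_fixture_codes_resolve_to_shipped_taxonomies(compendium, snapshot):
    cats, mechs = category_taxonomy(), mechanism_taxonomy()
    for record in list(compendium) + list(snapshot):
        for arm in record.interventions:
            assert arm.category_code in cats
            if arm.mechanism_code is not None:
                assert arm.mechanism_code in mechs


def test_fixtures_fully_valid(compendium, snapshot):
    assert validate_registry(compendium) == []
    assert validate_registry(snapshot) == []


def _valid_record() -> TrialRecord:
    return TrialRecord.model_validate(TWO_RECORD_PAYLOAD["trials"][1])


MUTATIONS = {
    "systemic_without_mechanism": (
        lambda r: r.interventions.append(
            InterventionRecord(name="x", category_code="small_molecule")
        ),
        "requires exactly one mechanism",
    ),
    "radiation_with_mechanism": (
        lambda r: r.interventions.append(
            InterventionRecord(name="x", category_code="radiation", mechanism_code="unknown")
        ),
        "must not carry a mechanism",
    ),
    "unknown_category": (
        lambda r: r.interventions.append(
            InterventionRecord(name="x", category_code="devices")
        ),
        "unknown code",
    ),
    "non_leaf_category": (
        lambda r: r.interventions.append(
            InterventionRecord(name="x", category_code="drug", mechanism_code="checkpoint")
        ),
        "not a leaf",
    ),
    "empty_interventions": (
        lambda r: r.interventions.clear(),
        "at least one arm",
    ),
    "bad_id": (
        lambda r: setattr(r, "registry_id", "NCT123"),
        "8 digits",
    ),
    "novelty_on_early_phase": (
        lambda r: setattr(r, "phase", Phase.II),
        "novelty_group",
    ),
}


@given(st.sampled_from(sorted(MUTATIONS)))
def test_validation_flags_exactly_the_broken_invariant(name):
    """A record is valid iff no invariant is broken; each mutation is caught
    and named."""
    record = _valid_record()
    assert validate_record(record) == []
    mutate, needle = MUTATIONS[name]
    mutate(record)
    violations = validate_record(record)
    assert violations, name
    assert any(needle in v for v in violations), (name, violations)


def test_duplicate_ids_flagged():
    records = [_valid_record(), _valid_record()]
    assert any("duplicate" in v for v in validate_registry(records))


def test_fda_timeline_is_static_reference_data():
    frame = load_fda_timeline()
    assert list(frame.columns)[:2] == ["year", "intervention"]
    assert len(frame) == 7 and frame["year"].iloc[0] == 1962
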