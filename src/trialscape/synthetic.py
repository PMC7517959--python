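"""Seeded synthetic registry snapshots with exact marginal quotas.

The generator emulates a registry snapshot at census scale so that curation,
tabulation, and scoring are testable without any download.  Marginal
distributions are *quotas* (exact counts), not multinomial probabilities:
tabulating a generated registry reproduces the configured counts exactly for
every facet, for any seed.  The joint structure across facets is
independent-by-shuffle — each facet's quota-expanded label list is shuffled
separately and the lists are zipped — because only marginals are modeled.

Defaults reproduce the study conditions of the landscape analysis: 430
relevant trials (phases 134/94/165/5/32; stages 265/60/19/46/10/30; lines
163/168/99), 590 intervention arms across the category quotas, 515 systemic
interventions across the mechanism quotas, 37 late-phase trials across the
novelty-group quotas, plus 41 neuroendocrine-tumor decoys and 10
non-therapeutic decoys so the curation funnel sees 481 records in.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .registry import (
    DiseaseStage,
    EndpointClass,
    InterventionRecord,
    LineOfTherapy,
    NoveltyGroup,
    Phase,
    RecruitmentStatus,
    StudyType,
    TrialRecord,
    category_taxonomy,
    mechanism_taxonomy,
    NON_SYSTEMIC_CATEGORIES,
)
from .scoring import CRITERIA, RubricAssignment, Rubric

DEFAULT_PHASE_QUOTAS = {
    Phase.I: 134,
    Phase.I_II: 94,
    Phase.II: 165,
    Phase.II_III: 5,
    Phase.III: 32,
}

DEFAULT_STAGE_QUOTAS = {
    DiseaseStage.ADVANCED_METASTATIC: 265,
    DiseaseStage.LOCALIZED_RESECTABLE: 60,
    DiseaseStage.LOCALIZED_BORDERLINE: 19,
    DiseaseStage.LOCALIZED_UNRESECTABLE: 46,
    DiseaseStage.LOCALIZED_ANY: 10,
    DiseaseStage.UNSPECIFIED: 30,
}

DEFAULT_LINE_QUOTAS = {
    LineOfTherapy.FIRST: 163,
    LineOfTherapy.SECOND_OR_LATER: 168,
    LineOfTherapy.UNSPECIFIED: 99,
}

# Split of the 430 relevant trials across the three active statuses.  The
# published counts do not break status down, so this split is a realism
# choice only; every record passes the status filter either way.
DEFAULT_STATUS_QUOTAS = {
    RecruitmentStatus.RECRUITING: 301,
    RecruitmentStatus.ACTIVE_NOT_RECRUITING: 99,
    RecruitmentStatus.ENROLLING_BY_INVITATION: 30,
}

DEFAULT_CATEGORY_QUOTAS = {
    "small_molecule": 163,
    "monoclonal_antibody": 120,
    "other_pharma": 27,
    "pdac_combination_or_delivery": 84,
    "fda_approved_other_cancer": 50,
    "radiation": 54,
    "gene_therapy": 23,
    "cellular_therapy": 33,
    "nutraceutical": 15,
    "procedure": 9,
    "pain_qol": 12,
}

DEFAULT_MECHANISM_QUOTAS = {
    "checkpoint": 73,
    "t_cell": 19,
    "adoptive_other": 14,
    "oncolytic_virus": 10,
    "vaccine": 28,
    "other_immune": 45,
    "dna_cell_cycle": 154,
    "rtk": 20,
    "ras_raf_mek_erk": 15,
    "pi3k_akt_mtor": 14,
    "jak_stat": 8,
    "fak_src": 6,
    "misc_signaling": 6,
    "metabolism": 35,
    "angiogenesis": 17,
    "hormone_receptor": 15,
    "apoptosis": 15,
    "thrombosis": 5,
    "infection": 3,
    "enzyme_supplementation": 3,
    "metastasis_invasion": 7,
    "unknown": 3,
}

DEFAULT_NOVELTY_QUOTAS = {
    NoveltyGroup.NOVEL_INTERVENTION: 14,
    NoveltyGroup.CONVENTIONAL_MANIPULATION: 13,
    NoveltyGroup.TECHNICAL_PROCEDURE: 7,
    NoveltyGroup.PAIN_MANAGEMENT: 3,
}

#: Categorical level distributions for generated rubric assignments.  Chosen
#: so that a large sample attains both tails of the published score range
#: (0 through 15) with comfortable probability while keeping mid-range totals
#: most common.
DEFAULT_LEVEL_PROBS = {
    "novelty": {
        "novel_mechanism_pdac": 0.25,
        "novel_drug_or_indication_pdac": 0.30,
        "beyond_standard_of_care": 0.25,
        "established": 0.20,
    },
    "promise": {
        "phase3_success_other": 0.25,
        "untested_or_under_investigation": 0.50,
        "any_phase_failure_other": 0.25,
    },
    "allocation": {"randomized": 0.45, "not_applicable": 0.15, "non_randomized": 0.40},
    "pfs_improvement": {"gt6mo": 0.20, "one_to_6mo": 0.35, "lt1mo": 0.45},
    "os_improvement": {"gt6mo": 0.20, "one_to_6mo": 0.35, "lt1mo": 0.45},
    "susceptibility": {"gt30pct": 0.55, "pct5_to_30": 0.25, "lt5pct": 0.20},
    "desired_impact": {
        "direct_treat": 0.60,
        "procedural_or_sequencing": 0.25,
        "symptoms_or_sequelae": 0.15,
    },
    "trial_status": {"active": 0.90, "terminated_and_published": 0.10},
}


@dataclass
class GeneratorConfig:
    """Quotas and sampling parameters for one synthetic snapshot."""

    n_trials: int = 430
    phase_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_PHASE_QUOTAS))
    stage_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_STAGE_QUOTAS))
    line_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_LINE_QUOTAS))
    status_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_STATUS_QUOTAS))
    category_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_CATEGORY_QUOTAS))
    mechanism_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_MECHANISM_QUOTAS))
    novelty_quotas: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_NOVELTY_QUOTAS))
    n_net_decoys: int = 41
    n_nontherapeutic_decoys: int = 10
    level_probs: dict = dataclass_field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_LEVEL_PROBS.items()
    })
    seed: int = 0

    @property
    def n_interventions(self) -> int:
        return sum(self.category_quotas.values())

    @property
    def n_late_phase(self) -> int:
        return sum(
            count for phase, count in self.phase_quotas.items() if Phase(phase).is_late
        )

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: generator config must be a mapping")
        config = cls()
        enum_keys = {
            "phase_quotas": Phase,
            "stage_quotas": DiseaseStage,
            "line_quotas": LineOfTherapy,
            "status_quotas": RecruitmentStatus,
            "novelty_quotas": NoveltyGroup,
        }
        for key, value in raw.items():
            if not hasattr(config, key):
                raise ConfigError(f"{path}: unknown generator option {key!r}")
            if key in enum_keys and isinstance(value, dict):
                value = {enum_keys[key](k): int(v) for k, v in value.items()}
            setattr(config, key, value)
        return config

    def validate(self) -> None:
        """Reject inconsistent quotas before any generation happens."""
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        for name, quotas in (
            ("phase_quotas", self.phase_quotas),
            ("stage_quotas", self.stage_quotas),
            ("line_quotas", self.line_quotas),
            ("status_quotas", self.status_quotas),
        ):
            if any(v < 0 for v in quotas.values()):
                raise ConfigError(f"{name} must be non-negative")
            if sum(quotas.values()) != self.n_trials:
                raise ConfigError(
                    f"{name} sum {sum(quotas.values())} != n_trials {self.n_trials}"
                )
        categories = category_taxonomy()
        for code in self.category_quotas:
            if code not in categories or not categories.is_leaf(code):
                raise ConfigError(f"category_quotas: unknown leaf category {code!r}")
        mechanisms = mechanism_taxonomy()
        for code in self.mechanism_quotas:
            if code not in mechanisms or not mechanisms.is_leaf(code):
                raise ConfigError(f"mechanism_quotas: unknown leaf mechanism {code!r}")
        total_arms = self.n_interventions
        if not self.n_trials <= total_arms <= 3 * self.n_trials:
            raise ConfigError(
                f"category quotas imply {total_arms} interventions for {self.n_trials} "
                "trials; arm counts are limited to 1-3"
            )
        systemic_total = sum(
            v for code, v in self.category_quotas.items()
            if code not in NON_SYSTEMIC_CATEGORIES
        )
        if sum(self.mechanism_quotas.values()) != systemic_total:
            raise ConfigError(
                f"mechanism quotas sum {sum(self.mechanism_quotas.values())} != "
                f"systemic intervention count {systemic_total}"
            )
        if sum(self.novelty_quotas.values()) != self.n_late_phase:
            raise ConfigError(
                f"novelty quotas sum {sum(self.novelty_quotas.values())} != "
                f"late-phase trial count {self.n_late_phase}"
            )
        if self.n_net_decoys < 0 or self.n_nontherapeutic_decoys < 0:
            raise ConfigError("decoy counts must be non-negative")
        rubric = Rubric.default()
        for criterion in CRITERIA:
            probs = self.level_probs.get(criterion)
            if probs is None:
                raise ConfigError(f"level_probs missing criterion {criterion!r}")
            for level in probs:
                rubric.points(criterion, level)  # raises on unknown token
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"level_probs[{criterion!r}] must sum to 1")


def _quota_list(rng: np.random.Generator, quotas: dict) -> list:
    expanded = [token for token, count in quotas.items() for _ in range(count)]
    order = rng.permutation(len(expanded))
    return [expanded[i] for i in order]


def _arm_counts(n_trials: int, total_arms: int) -> list[int]:
    # deterministic allocation: one arm each, extra arms to the
    # lexicographically first trials (IDs are assigned sequentially)
    counts = [1] * n_trials
    extra = total_arms - n_trials
    for i in range(extra):
        counts[i % n_trials] += 1
    return counts


def generate_registry(config: Optional[GeneratorConfig] = None) -> list[TrialRecord]:
    """Generate one snapshot (relevant trials plus flagged decoys).

    Deterministic for a fixed seed; different seeds reshuffle the joint
    assignment and the ID block but keep every marginal quota exact.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    phases = _quota_list(rng, config.phase_quotas)
    stages = _quota_list(rng, config.stage_quotas)
    lines = _quota_list(rng, config.line_quotas)
    statuses = _quota_list(rng, config.status_quotas)
    categories = _quota_list(rng, config.category_quotas)
    mechanisms = _quota_list(rng, config.mechanism_quotas)
    novelty = _quota_list(rng, config.novelty_quotas)

    n_total = config.n_trials + config.n_net_decoys + config.n_nontherapeutic_decoys
    id_start = 10_000_000 + (config.seed % 80_000_000)
    if id_start + n_total > 100_000_000:
        raise ConfigError("seed-derived ID block overflows the 8-digit ID space")
    ids = [f"NCT{id_start + i:08d}" for i in range(n_total)]

    arm_counts = _arm_counts(config.n_trials, config.n_interventions)
    category_labels = category_taxonomy()

    records: list[TrialRecord] = []
    arm_cursor = 0
    mech_cursor = 0
    novelty_cursor = 0
    for i in range(config.n_trials):
        arms: list[InterventionRecord] = []
        for _ in range(arm_counts[i]):
            code = categories[arm_cursor]
            mech = None
            if code not in NON_SYSTEMIC_CATEGORIES:
                mech = mechanisms[mech_cursor]
                mech_cursor += 1
            arms.append(
                InterventionRecord(
                    name=f"{category_labels.label(code)} candidate {arm_cursor + 1}",
                    category_code=code,
                    mechanism_code=mech,
                )
            )
            arm_cursor += 1
        phase = Phase(phases[i])
        group = None
        if phase.is_late:
            group = novelty[novelty_cursor]
            novelty_cursor += 1
        records.append(
            TrialRecord(
                registry_id=ids[i],
                title=f"Synthetic PDAC trial {i + 1}",
                study_type=StudyType.INTERVENTIONAL,
                phase=phase,
                recruitment_status=statuses[i],
                is_net=False,
                is_therapeutic=True,
                disease_stage=stages[i],
                line_of_therapy=lines[i],
                endpoint_class=EndpointClass.SURVIVAL,
                interventions=arms,
                novelty_group=group,
            )
        )

    decoy_phases = [Phase.I, Phase.I_II, Phase.II]
    statuses_allowed = list(config.status_quotas)
    for j in range(config.n_net_decoys + config.n_nontherapeutic_decoys):
        is_net = j < config.n_net_decoys
        code = "small_molecule" if is_net else "procedure"
        mech = "unknown" if is_net else None
        records.append(
            TrialRecord(
                registry_id=ids[config.n_trials + j],
                title=(
                    f"Synthetic pancreatic NET decoy trial {j + 1}"
                    if is_net
                    else f"Synthetic non-therapeutic decoy trial {j + 1}"
                ),
                study_type=StudyType.INTERVENTIONAL,
                phase=decoy_phases[j % len(decoy_phases)],
                recruitment_status=statuses_allowed[j % len(statuses_allowed)],
                is_net=is_net,
                is_therapeutic=is_net,  # NET decoys are therapeutic; the others are not
                disease_stage=DiseaseStage.UNSPECIFIED,
                line_of_therapy=LineOfTherapy.UNSPECIFIED,
                endpoint_class=EndpointClass.SURVIVAL,
                interventions=[
                    InterventionRecord(
                        name=f"decoy intervention {j + 1}",
                        category_code=code,
                        mechanism_code=mech,
                    )
                ],
            )
        )

    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ranges used to draw a raw input consistent with a binned level
_DELTA_RANGES = {"gt6mo": (6.5, 14.0), "one_to_6mo": (1.0, 6.0), "lt1mo": (-0.5, 0.9)}
_FRACTION_RANGES = {"gt30pct": (0.35, 1.0), "pct5_to_30": (0.05, 0.30), "lt5pct": (0.005, 0.049)}


def generate_assignments(
    config: Optional[GeneratorConfig] = None,
    records: Optional[Sequence[TrialRecord]] = None,
    n: Optional[int] = None,
) -> list[RubricAssignment]:
    """Generate rubric assignments for late-phase records (or ``n`` synthetic
    IDs when sampling in bulk), with raw inputs drawn consistently with the
    sampled level."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    if n is None:
        if records is None:
            records = generate_registry(config)
        targets = [r.registry_id for r in records if r.phase.is_late]
    else:
        targets = [f"NCT{90_000_000 + i:08d}" for i in range(n)]

    sampled: dict[str, np.ndarray] = {}
    for criterion in CRITERIA:
        probs = config.level_probs[criterion]
        tokens = list(probs)
        sampled[criterion] = rng.choice(
            tokens, size=len(targets), p=[probs[t] for t in tokens]
        )

    out: list[RubricAssignment] = []
    for i, rid in enumerate(targets):
        levels = {c: str(sampled[c][i]) for c in CRITERIA}
        pfs_level = levels["pfs_improvement"]
        os_level = levels["os_improvement"]
        frac_level = levels["susceptibility"]
        pfs_delta = float(round(rng.uniform(*_DELTA_RANGES[pfs_level]), 1))
        os_delta = float(round(rng.uniform(*_DELTA_RANGES[os_level]), 1))
        fraction = float(round(rng.uniform(*_FRACTION_RANGES[frac_level]), 3))
        # leave roughly half of the lowest-bin deltas unreported, as real
        # interim reports often omit them
        if pfs_level == "lt1mo" and rng.random() < 0.5:
            pfs_delta = None
            del levels["pfs_improvement"]  # unreported: binned at scoring time
        if os_level == "lt1mo" and rng.random() < 0.5:
            os_delta = None
            del levels["os_improvement"]
        out.append(
            RubricAssignment(
                registry_id=rid,
                levels=levels,
                pfs_delta=pfs_delta,
                os_delta=os_delta,
                susceptible_fraction=fraction,
            )
        )
    return out
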