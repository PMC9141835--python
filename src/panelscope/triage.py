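"""Clinical triage: when to run the rapid cartridge assay vs. sequencing.

A deliberately small, auditable rule engine. A :class:`DecisionContext`
describes the testing situation (tumor type, genes in question, care setting,
tissue adequacy, urgency, any prior result); an ordered ruleset — YAML or
JSON, shipped default or user-supplied — is evaluated top to bottom and the
first matching rule wins. Every recommendation carries the rule id and the
rule's own rationale text, so a recommendation is never a silent default.

The shipped default ruleset encodes the practice points that motivate
hotspot-qPCR triage: scant tissue goes straight to NGS; community settings
without an on-site molecular laboratory run the cartridge first-line and
reflex a negative to send-out NGS; academic centers use the cartridge for
orthogonal confirmation of ambiguous NGS results or for urgent on-demand
single-gene calls; anything involving genes outside the panel needs NGS.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

import yaml

__all__ = [
    "PANEL_GENES",
    "CareSetting",
    "TissueAdequacy",
    "Urgency",
    "PriorResult",
    "Modality",
    "Reflex",
    "TUMOR_TYPES",
    "DecisionContext",
    "Recommendation",
    "Rule",
    "RulesetError",
    "load_ruleset",
    "default_ruleset_path",
    "recommend",
]

PANEL_GENES = frozenset({"BRAF", "EGFR", "KRAS", "NRAS"})


class CareSetting(str, enum.Enum):
    community_no_onsite_molecular = "community_no_onsite_molecular"
    academic_with_ngs = "academic_with_ngs"


class TissueAdequacy(str, enum.Enum):
    adequate = "adequate"
    scant = "scant"


class Urgency(str, enum.Enum):
    routine = "routine"
    urgent = "urgent"


class PriorResult(str, enum.Enum):
    idylla_negative = "idylla_negative"
    ngs_ambiguous = "ngs_ambiguous"
    none = "none"


class Modality(str, enum.Enum):
    idylla_first_line = "idylla_first_line"
    ngs_first = "ngs_first"
    idylla_orthogonal_confirmation = "idylla_orthogonal_confirmation"


class Reflex(str, enum.Enum):
    reflex_to_ngs_if_negative = "reflex_to_ngs_if_negative"
    none = "none"


TUMOR_TYPES = (
    "cutaneous melanoma",
    "colorectal cancer",
    "lung adenocarcinoma",
    "hairy cell leukemia",
    "AML",
    "other",
)


@dataclass(frozen=True)
class DecisionContext:
    """The facts a triage decision depends on."""

    tumor_type: str
    genes_in_question: frozenset[str]
    care_setting: CareSetting
    tissue_adequacy: TissueAdequacy = TissueAdequacy.adequate
    urgency: Urgency = Urgency.routine
    prior_result: PriorResult = PriorResult.none

    def __post_init__(self) -> None:
        if self.tumor_type not in TUMOR_TYPES:
            raise ValueError(f"unknown tumor type {self.tumor_type!r}; known: {TUMOR_TYPES}")
        object.__setattr__(
            self, "genes_in_question", frozenset(g.upper() for g in self.genes_in_question)
        )

    @property
    def genes_on_panel(self) -> bool:
        """True iff every gene in question is covered by the hotspot panel."""
        return bool(self.genes_in_question) and self.genes_in_question <= PANEL_GENES


@dataclass(frozen=True)
class Recommendation:
    modality: Modality
    reflex: Reflex
    rationale: str
    rule_id: str

    def __post_init__(self) -> None:
        if not self.rationale or not self.rule_id:
            raise ValueError("rationale and rule_id must be populated")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality.value,
            "reflex": self.reflex.value,
            "rationale": self.rationale,
            "rule_id": self.rule_id,
        }


class RulesetError(ValueError):
    """A ruleset file failed validation."""


# condition field -> allowed values (None means free boolean)
_CONDITION_VOCAB = {
    "tumor_type": set(TUMOR_TYPES),
    "care_setting": {m.value for m in CareSetting},
    "tissue_adequacy": {m.value for m in TissueAdequacy},
    "urgency": {m.value for m in Urgency},
    "prior_result": {m.value for m in PriorResult},
    "genes_on_panel": {True, False},
}


@dataclass(frozen=True)
class Rule:
    rule_id: str
    match: dict = field(default_factory=dict)  # field -> value or list of values
    modality: Modality = Modality.ngs_first
    reflex: Reflex = Reflex.none
    rationale: str = ""

    def applies(self, context: DecisionContext) -> bool:
        for key, wanted in self.match.items():
            actual = getattr(context, key)
            if isinstance(actual, enum.Enum):
                actual = actual.value
            allowed = wanted if isinstance(wanted, list) else [wanted]
            if actual not in allowed:
                return False
        return True

    @property
    def is_default(self) -> bool:
        return not self.match


def default_ruleset_path() -> Path:
    return Path(str(resources.files("panelscope.data") / "default_ruleset.yaml"))


def load_ruleset(path: str | Path) -> tuple[Rule, ...]:
    """Load and validate an ordered ruleset (YAML or JSON).

    Requirements enforced here: every rule has a unique ``rule_id``; every
    condition field and value is within the controlled vocabulary; the LAST
    rule is an unconditional terminal default (guarantees totality).
    """
    path = Path(path)
    if not path.exists():
        raise RulesetError(f"ruleset file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    rules_raw = data.get("rules") if isinstance(data, dict) else data
    if not isinstance(rules_raw, list) or not rules_raw:
        raise RulesetError(f"{path.name}: expected a non-empty list of rules")
    rules: list[Rule] = []
    seen_ids: set[str] = set()
    for i, raw in enumerate(rules_raw, start=1):
        rule_id = str(raw.get("rule_id", "")).strip()
        if not rule_id:
            raise RulesetError(f"{path.name}: rule {i} lacks rule_id")
        if rule_id in seen_ids:
            raise RulesetError(f"{path.name}: duplicate rule_id {rule_id!r}")
        seen_ids.add(rule_id)
        match = raw.get("match") or {}
        for key, wanted in match.items():
            if key not in _CONDITION_VOCAB:
                raise RulesetError(f"{path.name}: rule {rule_id!r}: unknown field {key!r}")
            values = wanted if isinstance(wanted, list) else [wanted]
            bad = [v for v in values if v not in _CONDITION_VOCAB[key]]
            if bad:
                raise RulesetError(
                    f"{path.name}: rule {rule_id!r}: value(s) {bad!r} outside vocabulary "
                    f"for {key!r}"
                )
        action = raw.get("action") or {}
        try:
            modality = Modality(action.get("modality", ""))
        except ValueError as exc:
            raise RulesetError(
                f"{path.name}: rule {rule_id!r}: unknown modality {action.get('modality')!r}"
            ) from exc
        try:
            reflex = Reflex(action.get("reflex") or "none")
        except ValueError as exc:
            raise RulesetError(
                f"{path.name}: rule {rule_id!r}: unknown reflex {action.get('reflex')!r}"
            ) from exc
        rationale = str(raw.get("rationale", "")).strip()
        if not rationale:
            raise RulesetError(f"{path.name}: rule {rule_id!r} lacks a rationale")
        rules.append(Rule(rule_id, dict(match), modality, reflex, rationale))
    if not rules[-1].is_default:
        raise RulesetError(
            f"{path.name}: last rule {rules[-1].rule_id!r} must be an unconditional "
            "terminal default"
        )
    return tuple(rules)


def recommend(context: DecisionContext, rules: tuple[Rule, ...]) -> Recommendation:
    """First matching rule wins; the terminal default guarantees an answer."""
    for rule in rules:
        if rule.applies(context):
            return Recommendation(
                modality=rule.modality,
                reflex=rule.reflex,
                rationale=rule.rationale,
                rule_id=rule.rule_id,
            )
    raise AssertionError("unreachable: validated rulesets end in a terminal default")
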