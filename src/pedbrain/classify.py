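"""Rule-based tumor-type prediction from location and semantic features.

The cascade ends with an ordered first-match-wins ruleset mapping the
predicted anatomical site and features to one of the four subtypes (or
``normal`` when no tumor was detected).  The default ruleset encodes the
cohort's strongest associations -- every brainstem tumor is a brainstem
glioma, a restricting cerebellar tumor is a medulloblastoma, necrosis or
haemorrhage point to ependymoma, and pilocytic astrocytoma is the
remainder -- and is fully overridable from a YAML file, since the decision
logic is the loosest part of any such pipeline and sites may wish to
re-derive it from their own cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import yaml

from .core import SemanticFeatures


@dataclass
class Rule:
    """``when`` maps feature fields to a required value or list of values;
    an empty ``when`` always matches (the default rule)."""
    rule_id: str
    label: str
    when: dict = field(default_factory=dict)

    def matches(self, features: SemanticFeatures) -> bool:
        for key, expected in self.when.items():
            value = getattr(features, key)
            allowed = expected if isinstance(expected, (list, tuple)) else [expected]
            if value not in allowed:
                return False
        return True


@dataclass
class TumorDiagnosis:
    label: str
    rule_trace: List[str] = field(default_factory=list)


DEFAULT_RULESET = [
    Rule("brainstem-location", "brainstem_glioma", {"location": "brainstem"}),
    Rule("cerebellar-restriction", "medulloblastoma",
         {"location": "cerebellum_fourth_ventricle",
          "diffusion_restriction": True}),
    Rule("necrosis", "ependymoma", {"necrosis": True}),
    Rule("haemorrhage", "ependymoma", {"haemorrhage": True}),
    Rule("default", "pilocytic_astrocytoma"),
]


def classify_tumor(features: Optional[SemanticFeatures],
                   ruleset: List[Rule] = None) -> TumorDiagnosis:
    """First matching rule wins; absent features mean a normal study."""
    if features is None:
        return TumorDiagnosis(label="normal", rule_trace=["no-tumor"])
    ruleset = DEFAULT_RULESET if ruleset is None else ruleset
    if not ruleset:
        raise ValueError("ruleset must be non-empty")
    if ruleset[-1].when:
        raise ValueError("ruleset must be total: last rule must be a default "
                         "(empty 'when')")
    trace = []
    for rule in ruleset:
        if rule.matches(features):
            trace.append(f"{rule.rule_id}:fired")
            return TumorDiagnosis(label=rule.label, rule_trace=trace)
        trace.append(f"{rule.rule_id}:skipped")
    raise AssertionError("unreachable: total ruleset did not match")


def load_ruleset(path) -> List[Rule]:
    """Read an ordered ruleset from YAML (list of {id, label, when})."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [Rule(rule_id=e["id"], label=e["label"], when=e.get("when", {}))
            for e in entries]


def save_ruleset(ruleset: List[Rule], path) -> None:
    entries = [{"id": r.rule_id, "label": r.label,
                **({"when": r.when} if r.when else {})} for r in ruleset]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
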