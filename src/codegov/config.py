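"""YAML configuration: code-syntax options, classifier policy, scope rules.

Example::

    syntax:
      hot_lengths: [13, 9]
    classifier:
      similarity_threshold: 0.9
    report:
      denominator_policy: in_scope
    scope_rules:
      DRUG_HOT:
        - rule_id: kampo
          pattern: '\\bkampo\\b'
      LAB_JLAC10: []

Omitted sections fall back to the package defaults; an explicitly listed
system with an empty rule list disables its default exclusions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .code_systems import DEFAULT_SYNTAX, CodeSystemId, SyntaxConfig
from .governance import (
    DEFAULT_CLASSIFIER,
    DEFAULT_SCOPE_RULES,
    ClassifierConfig,
    ScopeRule,
    ScopeRules,
)
from .reporting import DenominatorPolicy


@dataclass
class GovernanceConfig:
    syntax: SyntaxConfig = DEFAULT_SYNTAX
    classifier: ClassifierConfig = DEFAULT_CLASSIFIER
    scope_rules: dict[CodeSystemId, ScopeRules] = field(
        default_factory=lambda: dict(DEFAULT_SCOPE_RULES)
    )
    denominator_policy: DenominatorPolicy = "in_scope"

    def content_hash(self) -> str:
        """Stable hash of the effective configuration (for run manifests)."""
        payload = {
            "syntax": {
                "hot_lengths": list(self.syntax.hot_lengths),
                "jlac10_widths": list(self.syntax.jlac10_widths),
            },
            "classifier": {
                "similarity_threshold": self.classifier.similarity_threshold
            },
            "denominator_policy": self.denominator_policy,
            "scope_rules": {
                system.value: [[r.rule_id, r.pattern] for r in rules.rules]
                for system, rules in sorted(self.scope_rules.items())
            },
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: Optional[Union[str, Path]] = None) -> GovernanceConfig:
    if path is None:
        return GovernanceConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")

    syntax = DEFAULT_SYNTAX
    if "syntax" in raw:
        section = raw["syntax"] or {}
        syntax = SyntaxConfig(
            hot_lengths=tuple(section.get("hot_lengths", DEFAULT_SYNTAX.hot_lengths)),
            jlac10_widths=tuple(
                section.get("jlac10_widths", DEFAULT_SYNTAX.jlac10_widths)
            ),
        )

    classifier = DEFAULT_CLASSIFIER
    if "classifier" in raw:
        section = raw["classifier"] or {}
        classifier = ClassifierConfig(
            similarity_threshold=float(
                section.get("similarity_threshold", DEFAULT_CLASSIFIER.similarity_threshold)
            )
        )

    scope_rules = dict(DEFAULT_SCOPE_RULES)
    for system_name, rule_list in (raw.get("scope_rules") or {}).items():
        system = CodeSystemId(system_name)
        rules = tuple(
            ScopeRule(rule["rule_id"], rule["pattern"]) for rule in (rule_list or [])
        )
        scope_rules[system] = ScopeRules(system, rules)

    policy: DenominatorPolicy = (raw.get("report") or {}).get(
        "denominator_policy", "in_scope"
    )
    if policy not in ("in_scope", "collected_total"):
        raise ValueError(f"unknown denominator_policy {policy!r}")

    return GovernanceConfig(syntax, classifier, scope_rules, policy)
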