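import io
import re

import pytest

from icdcoder import (
    NormalizationConfig,
    RegexRule,
    RuleBase,
    compile_rulebase,
    normalize_description,
    parse_rule_file,
)

FIXED_CLOCK = lambda: "1970-01-01T00:00:00+00:00"


@pytest.fixture
def toy_rules() -> RuleBase:
    return RuleBase(rules=[
        RegexRule("I10 06", "hypertension( grade (I|II|III))?", "hypertension"),
        RegexRule("E11.901", "type 2 diabetes", "type 2 diabetes"),
        RegexRule("A09.901", "^(acute )?gastroenteritis$", "acute gastroenteritis"),
    ])


@pytest.fixture
def toy_compiled(toy_rules):
    return compile_rulebase(toy_rules, NormalizationConfig())


def naive_scan(rules: RuleBase, text: str, cfg: NormalizationConfig | None = None):
    """Independent oracle: test every rule's pattern against the text with a
    plain loop and fresh compilations; return the sorted matching codes."""
    if cfg is None:
        cfg = NormalizationConfig()
    norm = normalize_description(text, cfg)
    hits = []
    for rule in rules:
        if re.search(rule.pattern, norm):
            hits.append(rule.code)
    return sorted(hits)


def rules_from_text(text: str) -> RuleBase:
    return parse_rule_file(io.StringIO(text))
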