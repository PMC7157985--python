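"""Rule-base construction: parsing, validation, majority resolution, compilation.

A rule base binds one regular expression ("description model") to exactly one
diagnosis code.  The expression is meant to capture every phrasing clinicians
use for that diagnosis, so that a free-text description can be coded by
testing it against every rule and accepting only a unique hit.

Code syntax follows ICD-10 with the national extension used by the Chinese
Classification and Codes of Diseases (CCD): a chapter letter, two digits, an
optional ``.``-separated subdivision of 1-4 alphanumerics, and an optional
space-separated two-digit extension (``I25.101``, ``I10 06``, ``F09 01``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

__all__ = [
    "CODE_PATTERN",
    "DiagnosisCode",
    "RegexRule",
    "RuleBase",
    "ValidationIssue",
    "ValidationReport",
    "CompiledRuleBase",
    "DescriptionCodePair",
    "RuleBaseError",
    "RuleParseError",
    "is_valid_code",
    "code_cluster",
    "parse_rule_file",
    "serialize_rule_file",
    "validate_rulebase",
    "majority_resolve",
    "compile_rulebase",
    "check_dialect",
]

#: Chapter letter + two digits, optional ".xxxx" subdivision, optional " NN"
#: national extension.
CODE_PATTERN = re.compile(r"[A-Z][0-9]{2}(?:\.[A-Za-z0-9]{1,4})?(?: [0-9]{2})?")

#: A diagnosis code is plain text; validity is checked with :func:`is_valid_code`.
DiagnosisCode = str


class RuleBaseError(ValueError):
    """Structural problem with a rule base (validation errors at compile time)."""


class RuleParseError(RuleBaseError):
    """Malformed rule file; carries the offending 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def is_valid_code(code: str) -> bool:
    """Whether ``code`` is syntactically a valid (possibly extended) code."""
    return bool(CODE_PATTERN.fullmatch(code))


def code_cluster(code: DiagnosisCode) -> str:
    """Chapter/cluster letter of a code: its first character."""
    if not code or not code[0].isalpha():
        raise ValueError(f"cannot derive cluster from invalid code {code!r}")
    return code[0].upper()


@dataclass(frozen=True)
class RegexRule:
    """One description model: a regex bound to a single diagnosis code."""

    code: DiagnosisCode
    pattern: str
    canonical_label: str = ""
    note: str = ""


@dataclass
class RuleBase:
    """An ordered collection of rules; codes must be pairwise distinct."""

    rules: list[RegexRule] = field(default_factory=list)
    dialect_version: str = "core-v1"

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def codes(self) -> list[DiagnosisCode]:
        return [r.code for r in self.rules]


@dataclass(frozen=True)
class ValidationIssue:
    """One finding: the 0-based rule position, a machine kind, and a message."""

    position: int
    kind: str
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "errors": [vars(i) for i in self.errors],
            "warnings": [vars(i) for i in self.warnings],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class DescriptionCodePair:
    """A historical (description, code) pairing with its coder-agreement count."""

    description: str
    code: DiagnosisCode
    support: int = 1

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be >= 1")


# ---------------------------------------------------------------------------
# Parsing / serialization (TSV, UTF-8, '#' comments, header row)
# ---------------------------------------------------------------------------

_HEADER = ("code", "pattern", "canonical_label", "note")


def parse_rule_file(source: TextIO | Iterable[str]) -> RuleBase:
    """Parse a tab-delimited rule file into a :class:`RuleBase`.

    Columns are ``code<TAB>pattern[<TAB>canonical_label[<TAB>note]]``.  Blank
    lines and ``#``-prefixed comment lines are skipped; an optional header row
    naming the columns is recognized and dropped.  File order is preserved.
    Duplicate codes parse successfully and are reported by
    :func:`validate_rulebase`.
    """
    rules: list[RegexRule] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if tuple(f.strip().lower() for f in fields[:2]) == _HEADER[:2]:
            continue  # header row
        if len(fields) < 2:
            raise RuleParseError(lineno, f"expected >=2 tab-delimited fields, got {len(fields)}")
        code, pattern = fields[0].strip(), fields[1]
        if not code:
            raise RuleParseError(lineno, "empty code field")
        if not pattern:
            raise RuleParseError(lineno, "empty pattern field")
        label = fields[2] if len(fields) > 2 else ""
        note = fields[3] if len(fields) > 3 else ""
        rules.append(RegexRule(code=code, pattern=pattern, canonical_label=label, note=note))
    return RuleBase(rules=rules)


def serialize_rule_file(rb: RuleBase, dest: TextIO) -> None:
    """Write ``rb`` as a TSV rule file (inverse of :func:`parse_rule_file`)."""
    dest.write("\t".join(_HEADER) + "\n")
    for r in rb.rules:
        dest.write(f"{r.code}\t{r.pattern}\t{r.canonical_label}\t{r.note}\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

#: Constructs guaranteed portable across regex dialects for this rule language:
#: anchors, the Kleene star, the any-character dot, alternation, the optional
#: quantifier, grouping, and literal characters.  Anything else (character
#: classes, ``+``, bounded repeats, escape shorthands...) compiles under the
#: host dialect but draws a portability warning.
_PORTABLE_META = set("^$*.|?()")
_PORTABLE_ESCAPES = set(".^$*+?()[]{}|\\/ \t")


def check_dialect(pattern: str) -> list[str]:
    """Return descriptions of constructs outside the guaranteed portable set."""
    findings: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "\\":
            if i + 1 >= len(pattern):
                findings.append("trailing backslash")
                break
            nxt = pattern[i + 1]
            if nxt not in _PORTABLE_ESCAPES:
                findings.append(f"escape sequence '\\{nxt}'")
            i += 2
            continue
        if ch in "[]{}+":
            findings.append(f"construct '{ch}'")
        i += 1
    return findings


def validate_rulebase(rb: RuleBase) -> ValidationReport:
    """Check code uniqueness, code syntax, pattern compilability, and dialect.

    Pure: the report is a function of the rule base alone.  Errors make the
    base uncompilable; warnings flag portability risks only.
    """
    report = ValidationReport()
    seen: dict[DiagnosisCode, int] = {}
    for pos, rule in enumerate(rb.rules):
        if rule.code in seen:
            report.errors.append(ValidationIssue(
                pos, "duplicate_code",
                f"code {rule.code!r} already bound to rule at position {seen[rule.code]}"))
        else:
            seen[rule.code] = pos
        if not is_valid_code(rule.code):
            report.errors.append(ValidationIssue(
                pos, "code_syntax", f"code {rule.code!r} violates code syntax"))
        if not rule.pattern:
            report.errors.append(ValidationIssue(pos, "empty_pattern", "pattern is empty"))
            continue
        try:
            re.compile(rule.pattern)
        except re.error as exc:
            report.errors.append(ValidationIssue(
                pos, "compile_error", f"pattern {rule.pattern!r} does not compile: {exc}"))
            continue
        for finding in check_dialect(rule.pattern):
            report.warnings.append(ValidationIssue(
                pos, "dialect", f"pattern {rule.pattern!r} uses non-portable {finding}"))
    return report


# ---------------------------------------------------------------------------
# Majority resolution of historical description-code pairs
# ---------------------------------------------------------------------------

def majority_resolve(
    pairs: Iterable[DescriptionCodePair],
) -> tuple[dict[str, DiagnosisCode], set[str]]:
    """Resolve each description to the code with strictly greatest support.

    Support for the same (description, code) pair accumulates across entries.
    Descriptions whose top support is tied between two or more codes are
    returned in the *unresolved* set instead of the mapping, for manual
    handling.  Every input description lands in exactly one of the two.
    """
    totals: dict[str, dict[DiagnosisCode, int]] = {}
    for p in pairs:
        totals.setdefault(p.description, {})
        totals[p.description][p.code] = totals[p.description].get(p.code, 0) + p.support
    mapping: dict[str, DiagnosisCode] = {}
    unresolved: set[str] = set()
    for desc, by_code in totals.items():
        best = max(by_code.values())
        winners = [c for c, s in by_code.items() if s == best]
        if len(winners) == 1:
            mapping[desc] = winners[0]
        else:
            unresolved.add(desc)
    return mapping, unresolved


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledRuleBase:
    """A rule base with every pattern compiled once, ready for matching.

    ``anchored`` selects full-match semantics; the default is unanchored
    substring search, the containment semantics of a SQL ``REGEXP_LIKE``
    deployment (a pattern without ``^``/``$`` may match anywhere inside the
    description).  ``normalization_fingerprint`` records the text-normalization
    configuration the base was compiled against, so matching can verify it
    normalizes inputs the same way.
    """

    source: RuleBase
    matchers: dict[DiagnosisCode, re.Pattern]
    normalization_fingerprint: str
    anchored: bool = False
    self_match_warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def codes(self) -> list[DiagnosisCode]:
        return list(self.matchers)

    def __len__(self) -> int:
        return len(self.matchers)

    def matches(self, code: DiagnosisCode, text: str) -> bool:
        pat = self.matchers[code]
        return bool(pat.fullmatch(text) if self.anchored else pat.search(text))


def compile_rulebase(rb: RuleBase, cfg=None, *, anchored: bool = False) -> CompiledRuleBase:
    """Compile a validated rule base against a normalization configuration.

    Rejects (raises :class:`RuleBaseError`) when :func:`validate_rulebase`
    reports errors.  Each rule's canonical label, normalized with ``cfg``, is
    tested against the rule's own compiled pattern; a label that fails its own
    pattern draws a self-match warning (the rule cannot code its canonical
    phrasing), attached to the compiled base.
    """
    from .matching import NormalizationConfig, normalize_description

    if cfg is None:
        cfg = NormalizationConfig()
    report = validate_rulebase(rb)
    if not report.ok:
        msgs = "; ".join(f"[{i.kind}] {i.message}" for i in report.errors)
        raise RuleBaseError(f"cannot compile invalid rule base: {msgs}")

    matchers = {r.code: re.compile(r.pattern) for r in rb.rules}
    crb = CompiledRuleBase(
        source=rb,
        matchers=matchers,
        normalization_fingerprint=cfg.fingerprint(),
        anchored=anchored,
    )
    for pos, rule in enumerate(rb.rules):
        if not rule.canonical_label:
            continue
        label = normalize_description(rule.canonical_label, cfg)
        if not crb.matches(rule.code, label):
            crb.self_match_warnings.append(ValidationIssue(
                pos, "self_match",
                f"canonical label {rule.canonical_label!r} does not match its own pattern"))
    return crb
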