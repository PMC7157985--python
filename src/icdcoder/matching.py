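"""Normalization and the automatic-coding pass.

Each diagnosis record carries one free-text description.  The matcher tests
the description against every rule in the compiled base: exactly one hit
assigns that rule's code and appends to the coding log; zero or multiple hits
append to the failure log (reason ``no_match`` or ``ambiguous``).  Ambiguity
is never tie-broken — a description that satisfies two description models is
a rule-base defect to be audited, not a ranking problem.

Normalization order is fixed: width fold, then Latin case fold, then
punctuation stripping, then whitespace collapse.  Each step is idempotent and
no later step can re-introduce material for an earlier one, so the composite
is idempotent too.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, TextIO

from .rulebase import CompiledRuleBase, DiagnosisCode

__all__ = [
    "NormalizationConfig",
    "DiagnosisRecord",
    "MatchResult",
    "CodingRun",
    "DuplicateRecordError",
    "normalize_description",
    "match_description",
    "code_batch",
    "read_record_file",
    "write_assignments",
    "write_coding_log",
    "write_failure_log",
]

# Full-width ASCII block U+FF01-U+FF5E -> U+0021-U+007E, plus ideographic space.
_WIDTH_TABLE = {cp: cp - 0xFEE0 for cp in range(0xFF01, 0xFF5F)}
_WIDTH_TABLE[0x3000] = 0x20


@dataclass(frozen=True)
class NormalizationConfig:
    """Text-normalization switches applied before matching.

    Defaults: whitespace collapse ON, width folding ON, Latin case folding ON,
    punctuation stripping OFF — conservative cleanup that removes encoding
    and spacing noise without altering clinical wording.
    """

    collapse_whitespace: bool = True
    width_fold: bool = True
    case_fold_latin: bool = True
    strip_chars: frozenset[str] = frozenset()

    def fingerprint(self) -> str:
        """Stable text tag identifying this configuration."""
        return (
            f"ws={int(self.collapse_whitespace)};width={int(self.width_fold)};"
            f"case={int(self.case_fold_latin)};strip={''.join(sorted(self.strip_chars))}"
        )


def normalize_description(text: str, cfg: NormalizationConfig | None = None) -> str:
    """Normalize a free-text description under ``cfg``; idempotent."""
    if cfg is None:
        cfg = NormalizationConfig()
    if cfg.width_fold:
        text = text.translate(_WIDTH_TABLE)
    if cfg.case_fold_latin:
        text = text.casefold()
    if cfg.strip_chars:
        text = "".join(ch for ch in text if ch not in cfg.strip_chars)
    if cfg.collapse_whitespace:
        text = " ".join(text.split())
    return text


@dataclass(frozen=True)
class DiagnosisRecord:
    """One free-text diagnosis awaiting a code.

    ``group_id`` preserves patient/admission grouping when a multi-diagnosis
    record was split upstream into one description per record.
    """

    record_id: str
    description: str
    gold_code: Optional[DiagnosisCode] = None
    group_id: Optional[str] = None


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one description against the whole rule base."""

    status: str  # "unique" | "no_match" | "ambiguous"
    assigned_code: Optional[DiagnosisCode] = None
    candidates: tuple[DiagnosisCode, ...] = ()

    def __post_init__(self):
        if self.status == "unique":
            assert self.assigned_code is not None and len(self.candidates) == 1
        elif self.status == "no_match":
            assert self.assigned_code is None and not self.candidates
        elif self.status == "ambiguous":
            assert self.assigned_code is None and len(self.candidates) >= 2
        else:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class CodingRun:
    """Assignments plus the two audit trails of one batch pass."""

    assignments: dict[str, DiagnosisCode] = field(default_factory=dict)
    coding_log: list[dict] = field(default_factory=list)
    failure_log: list[dict] = field(default_factory=list)
    results: dict[str, MatchResult] = field(default_factory=dict)

    @property
    def record_ids(self) -> set[str]:
        return set(self.results)


class DuplicateRecordError(ValueError):
    def __init__(self, record_id: str):
        super().__init__(f"duplicate record_id {record_id!r} in batch")
        self.record_id = record_id


def match_description(crb: CompiledRuleBase, text: str,
                      cfg: NormalizationConfig | None = None) -> MatchResult:
    """Match one description against every rule; deterministic.

    The text is normalized with ``cfg`` (which must fingerprint-match the
    compiled base's configuration) before the scan.  Candidates are reported
    in code order, so the result is independent of rule-file order.
    """
    if cfg is None:
        cfg = NormalizationConfig()
    if cfg.fingerprint() != crb.normalization_fingerprint:
        raise ValueError(
            "normalization config does not match the one the rule base was "
            f"compiled with ({cfg.fingerprint()!r} != {crb.normalization_fingerprint!r})")
    norm = normalize_description(text, cfg)
    hits = sorted(code for code in crb.codes if crb.matches(code, norm))
    if len(hits) == 1:
        return MatchResult("unique", assigned_code=hits[0], candidates=tuple(hits))
    if not hits:
        return MatchResult("no_match")
    return MatchResult("ambiguous", candidates=tuple(hits))


def code_batch(crb: CompiledRuleBase, records: Iterable[DiagnosisRecord],
               cfg: NormalizationConfig | None = None,
               clock: Callable[[], str] | None = None) -> CodingRun:
    """Run the automatic-coding pass over a batch.

    Unique matches enter ``assignments`` and the coding log; failures enter
    the failure log with their reason and candidate set.  ``clock`` supplies
    timestamps (injectable so runs are byte-reproducible in tests); the
    default is the real UTC clock.
    """
    if clock is None:
        from datetime import datetime, timezone
        clock = lambda: datetime.now(timezone.utc).isoformat()
    run = CodingRun()
    for rec in records:
        if rec.record_id in run.results:
            raise DuplicateRecordError(rec.record_id)
        result = match_description(crb, rec.description, cfg)
        run.results[rec.record_id] = result
        if result.status == "unique":
            run.assignments[rec.record_id] = result.assigned_code
            run.coding_log.append({
                "record_id": rec.record_id,
                "code": result.assigned_code,
                "ts": clock(),
            })
        else:
            run.failure_log.append({
                "record_id": rec.record_id,
                "reason": result.status,
                "candidates": list(result.candidates),
                "ts": clock(),
            })
    return run


# ---------------------------------------------------------------------------
# Record / log I/O (TSV records, JSONL logs)
# ---------------------------------------------------------------------------

_RECORD_FIELDS = ("record_id", "description", "gold_code", "group_id")


def read_record_file(source: TextIO) -> list[DiagnosisRecord]:
    """Read a TSV record file: ``record_id``, ``description``, optional
    ``gold_code`` and ``group_id`` columns; header row required."""
    reader = csv.DictReader(source, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = {"record_id", "description"} - set(reader.fieldnames)
    if missing:
        raise ValueError(f"record file missing required columns: {sorted(missing)}")
    records = []
    for row in reader:
        records.append(DiagnosisRecord(
            record_id=row["record_id"],
            description=row["description"],
            gold_code=row.get("gold_code") or None,
            group_id=row.get("group_id") or None,
        ))
    return records


def write_record_file(records: Iterable[DiagnosisRecord], dest: TextIO) -> None:
    dest.write("\t".join(_RECORD_FIELDS) + "\n")
    for r in records:
        dest.write(f"{r.record_id}\t{r.description}\t{r.gold_code or ''}\t{r.group_id or ''}\n")


def write_assignments(run: CodingRun, dest: TextIO) -> None:
    """Write assignments as TSV (``record_id``, ``code``), sorted by id."""
    dest.write("record_id\tcode\n")
    for rid in sorted(run.assignments):
        dest.write(f"{rid}\t{run.assignments[rid]}\n")


def _write_jsonl(entries: Iterable[dict], dest: TextIO) -> None:
    for e in entries:
        dest.write(json.dumps(e, ensure_ascii=False, sort_keys=True) + "\n")


def write_coding_log(run: CodingRun, dest: TextIO) -> None:
    _write_jsonl(run.coding_log, dest)


def write_failure_log(run: CodingRun, dest: TextIO) -> None:
    _write_jsonl(run.failure_log, dest)
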