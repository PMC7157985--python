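"""Synthetic gold-labelled corpora with matching rule bases.

The generator emulates the statistical shape of a hospital diagnosis stream
without any real clinical text: a universe of distinct diagnosis codes whose
usage frequencies follow a Zipf law (high-frequency codes concentrated in a
short head), a rule base covering the most frequent fraction of those codes
(modeling effort goes to the head of the distribution first), and free-text
descriptions derived from per-code canonical labels by controlled variation —
synonym substitution, optional-token insertion, and spacing/width noise.

Every generated record carries its gold code and its *expected* match status,
so an end-to-end run of the matcher and the audit can be checked exactly:

* in-coverage, non-ambiguous records match exactly their own rule (each code
  owns unique surface tokens, so cross-matches are impossible by
  construction);
* ambiguity-injected records additionally contain a second rule's core
  phrase, guaranteeing >=2 hits;
* out-of-coverage records share no tokens with any rule, guaranteeing 0 hits.

Surface vocabulary is synthetic token strings, deliberately language-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .matching import DiagnosisRecord
from .rulebase import DiagnosisCode, RegexRule, RuleBase

__all__ = [
    "VariantOps",
    "CorpusSpec",
    "SyntheticCorpus",
    "generate_code_universe",
    "generate_corpus",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class VariantOps:
    """Per-record probabilities of each surface-variation operation.

    ``p_synonym``: replace the head token by a code-specific synonym (the
    rule's alternation branch).  ``p_optional``: insert an optional qualifier
    token the rule marks with ``?``.  ``p_noise``: spacing/width noise —
    doubled spaces and full-width characters — that normalization must absorb.
    """

    p_synonym: float = 0.3
    p_optional: float = 0.3
    p_noise: float = 0.15


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus.

    Defaults mirror a head-modeled hospital stream: 500 code categories under
    a Zipf(1.0) frequency law, 10,000 records, full rule coverage, no
    injected ambiguity.
    """

    n_codes: int = 500
    zipf_exponent: float = 1.0
    n_records: int = 10_000
    coverage: float = 1.0
    ambiguity_rate: float = 0.0
    variant_ops: VariantOps = field(default_factory=VariantOps)
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.n_codes < 1:
            problems.append("n_codes must be >= 1")
        if self.n_records < 1:
            problems.append("n_records must be >= 1")
        if self.zipf_exponent < 0:
            problems.append("zipf_exponent must be >= 0")
        for name in ("coverage", "ambiguity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must lie in [0, 1]")
        for name in ("p_synonym", "p_optional", "p_noise"):
            v = getattr(self.variant_ops, name)
            if not 0 <= v <= 1:
                problems.append(f"variant_ops.{name} must lie in [0, 1]")
        return problems


@dataclass
class SyntheticCorpus:
    """Generated records plus the rule base and per-record expected statuses."""

    records: list[DiagnosisRecord]
    rulebase: RuleBase
    modeled: set[DiagnosisCode]
    truth: dict[str, str]  # record_id -> expected status
    code_weights: dict[DiagnosisCode, float]

    @property
    def all_codes(self) -> set[DiagnosisCode]:
        return set(self.code_weights)


def _check_spec(spec: CorpusSpec) -> None:
    problems = spec.validate()
    if problems:
        raise ValueError("invalid corpus spec: " + "; ".join(problems))


def generate_code_universe(spec: CorpusSpec) -> list[tuple[DiagnosisCode, float]]:
    """Generate ``n_codes`` distinct valid codes with Zipf sampling weights.

    Weight of the rank-``k`` code is ``k**-s / H_n(s)`` (``s`` = the Zipf
    exponent; ``s = 0`` degenerates to uniform).  The code strings themselves
    are drawn deterministically from the seed; the list is returned in rank
    order, most frequent first.
    """
    _check_spec(spec)
    rng = np.random.default_rng(spec.seed)
    codes: list[str] = []
    seen: set[str] = set()
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    while len(codes) < spec.n_codes:
        letter = letters[rng.integers(len(letters))]
        major = rng.integers(100)
        minor = rng.integers(1000)
        code = f"{letter}{major:02d}.{minor:03d}"
        if rng.random() < 0.1:  # occasional national extension code
            code += f" {rng.integers(100):02d}"
        if code not in seen:
            seen.add(code)
            codes.append(code)
    ranks = np.arange(1, spec.n_codes + 1, dtype=float)
    weights = ranks ** -spec.zipf_exponent
    weights /= weights.sum()
    return list(zip(codes, weights.tolist()))


def _make_rule(idx: int, code: DiagnosisCode) -> RegexRule:
    """Rule for code ``idx``: unique head/tail tokens, a synonym alternation
    and an optional qualifier, all within the portable construct set."""
    head, syn, tail, opt = (f"m{idx:04d}", f"s{idx:04d}", f"t{idx:04d}", f"q{idx:04d}")
    pattern = f"(({head}|{syn}) {tail})( {opt})?"
    label = f"{head} {tail}"
    return RegexRule(code=code, pattern=pattern, canonical_label=label,
                     note="synthetic")


def _make_description(idx: int, rng: np.random.Generator, ops: VariantOps) -> str:
    head, syn, tail, opt = (f"m{idx:04d}", f"s{idx:04d}", f"t{idx:04d}", f"q{idx:04d}")
    first = syn if rng.random() < ops.p_synonym else head
    text = f"{first} {tail}"
    if rng.random() < ops.p_optional:
        text += f" {opt}"
    if rng.random() < ops.p_noise:
        text = text.replace(" ", "  ", 1)
        if rng.random() < 0.5:
            # full-width variant of the first character; normalization folds it back
            text = chr(ord(text[0]) + 0xFEE0) + text[1:]
    return text


def _uncovered_description(idx: int, rng: np.random.Generator) -> str:
    # tokens disjoint from every rule's vocabulary
    return f"u{idx:04d} v{idx:04d}"


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a corpus whose coding outcome is known record by record.

    Gold codes are drawn by Zipf weight; the top ``coverage`` fraction of
    codes (by weight rank) each get one rule accepting all their generated
    surface variants.  A random ``ambiguity_rate`` fraction of in-coverage
    records get a second rule's core phrase appended, forcing a multi-match.
    Byte-identical under a fixed seed.
    """
    _check_spec(spec)
    universe = generate_code_universe(spec)
    n_covered = round(spec.coverage * spec.n_codes)
    if spec.ambiguity_rate > 0 and n_covered < 2:
        raise ValueError(
            "ambiguity_rate > 0 requires at least 2 covered codes "
            f"(coverage {spec.coverage} of {spec.n_codes} codes covers {n_covered})")

    code_index = {code: i for i, (code, _) in enumerate(universe)}
    covered = [code for code, _ in universe[:n_covered]]
    rules = [_make_rule(code_index[c], c) for c in covered]
    rulebase = RuleBase(rules=rules, dialect_version="core-v1")
    modeled = set(covered)

    rng = np.random.default_rng(spec.seed + 1)  # independent of universe draw
    codes = [c for c, _ in universe]
    weights = np.array([w for _, w in universe])
    gold_draws = rng.choice(len(codes), size=spec.n_records, p=weights)

    records: list[DiagnosisRecord] = []
    truth: dict[str, str] = {}
    for i, gi in enumerate(gold_draws):
        rid = f"r{i:06d}"
        gold = codes[gi]
        gold_idx = code_index[gold]
        if gold in modeled:
            desc = _make_description(gold_idx, rng, spec.variant_ops)
            if rng.random() < spec.ambiguity_rate:
                other = int(rng.integers(n_covered))
                if other == gold_idx:
                    other = (other + 1) % n_covered
                desc += f" m{other:04d} t{other:04d}"
                status = "ambiguous"
            else:
                status = "unique"
        else:
            desc = _uncovered_description(gold_idx, rng)
            status = "no_match"
        records.append(DiagnosisRecord(record_id=rid, description=desc,
                                       gold_code=gold, group_id=f"g{i // 6:05d}"))
        truth[rid] = status

    return SyntheticCorpus(records=records, rulebase=rulebase, modeled=modeled,
                           truth=truth,
                           code_weights={c: w for c, w in universe})


def write_truth_sidecar(corpus: SyntheticCorpus, dest: TextIO) -> None:
    """Write the per-record expected statuses as JSONL."""
    for rec in corpus.records:
        dest.write(json.dumps({
            "record_id": rec.record_id,
            "gold_code": rec.gold_code,
            "expected_status": corpus.truth[rec.record_id],
        }, sort_keys=True) + "\n")
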