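"""Audit and evaluation of coding runs.

Outcomes follow the semi-automatic-coding confusion taxonomy: a record whose
emitted code equals its gold code is a true positive; a wrong emitted code is
a false positive; a record left uncoded is a false negative when its gold
code is in the *modeled* set (the system should have coded it) and a true
negative when it is not (no description model exists, so absence is correct).

Metrics are the standard precision, recall, weighted-harmonic F and overall
accuracy, reported as percentages:

    P = TP/(TP+FP),  R = TP/(TP+FN),
    F = 1 / (alpha/P + (1-alpha)/R)   (alpha = 0.5 by default),
    A = (TP+TN)/(TP+FP+FN+TN).

All four are computed on exact rationals and rounded half-up to two decimals
only at reporting time.  Zero denominators yield an explicit ``None`` marker,
never a silent 0 or 100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional

from .matching import CodingRun, DiagnosisRecord
from .rulebase import DiagnosisCode, code_cluster, is_valid_code

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FrequencyEntry",
    "FrequencyTable",
    "ClusterStats",
    "ClusterSummary",
    "FailureBreakdown",
    "classify_outcome",
    "tabulate",
    "precision",
    "recall",
    "f_measure",
    "accuracy",
    "metrics_report",
    "round2",
    "code_frequency",
    "cluster_summary",
    "failure_breakdown",
]


def round2(x: Fraction | float) -> float:
    """Round to 2 decimals, half away from zero (the convention of printed
    percentage tables)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(x))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_outcome(emitted: Optional[DiagnosisCode], gold: DiagnosisCode,
                     modeled: set[DiagnosisCode]) -> str:
    """Classify one audited record as ``TP``/``FP``/``FN``/``TN``.

    ``modeled`` is the set of codes the rule base covers; it operationalizes
    condition negativity — a gold code outside it means no model exists and
    the correct behaviour is to emit nothing.
    """
    if gold is None:
        raise ValueError("gold code required for outcome classification")
    if emitted is not None:
        return "TP" if emitted == gold else "FP"
    return "FN" if gold in modeled else "TN"


def tabulate(run: CodingRun, gold_records: Iterable[DiagnosisRecord],
             modeled: set[DiagnosisCode]) -> ConfusionCounts:
    """Sum :func:`classify_outcome` over a batch; conserves record count."""
    counts = Counter()
    for rec in gold_records:
        if rec.gold_code is None:
            raise ValueError(f"record {rec.record_id!r} lacks a gold code")
        emitted = run.assignments.get(rec.record_id)
        counts[classify_outcome(emitted, rec.gold_code, modeled)] += 1
    return ConfusionCounts(tp=counts["TP"], fp=counts["FP"],
                           fn=counts["FN"], tn=counts["TN"])


# ---------------------------------------------------------------------------
# Metrics (exact rationals; None marks an undefined metric)
# ---------------------------------------------------------------------------

def precision(cc: ConfusionCounts) -> Optional[Fraction]:
    """TP/(TP+FP) as an exact percentage, or ``None`` when nothing was emitted."""
    denom = cc.tp + cc.fp
    return None if denom == 0 else Fraction(100 * cc.tp, denom)


def recall(cc: ConfusionCounts) -> Optional[Fraction]:
    """TP/(TP+FN) as an exact percentage, or ``None`` when nothing was
    condition-positive."""
    denom = cc.tp + cc.fn
    return None if denom == 0 else Fraction(100 * cc.tp, denom)


def f_measure(p: Optional[Fraction | float], r: Optional[Fraction | float],
              alpha: Fraction | float = Fraction(1, 2)) -> Optional[Fraction]:
    """Weighted harmonic mean of precision and recall (percentages).

    ``F = 1/(alpha/P + (1-alpha)/R)``; at alpha = 1/2 this is 2PR/(P+R).
    Undefined (``None``) when either input is undefined or zero.
    """
    alpha = Fraction(alpha)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if p is None or r is None:
        return None
    p, r = Fraction(p), Fraction(r)
    if p == 0 or r == 0:
        return None
    return 1 / (alpha / p + (1 - alpha) / r)


def accuracy(cc: ConfusionCounts) -> Optional[Fraction]:
    """(TP+TN)/total as an exact percentage, or ``None`` on an empty audit."""
    if cc.total == 0:
        return None
    return Fraction(100 * (cc.tp + cc.tn), cc.total)


@dataclass(frozen=True)
class MetricsReport:
    """The four metrics at reporting precision, plus their exact values.

    ``*_pct`` fields are half-up 2-decimal percentages (``None`` when the
    metric is undefined); the ``exact`` mapping retains the full-precision
    rationals for downstream arithmetic.
    """

    precision_pct: Optional[float]
    recall_pct: Optional[float]
    f_pct: Optional[float]
    accuracy_pct: Optional[float]
    alpha: float = 0.5
    exact: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fmt(v):
            return None if v is None else f"{v:.2f}"
        return {
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "f_pct": self.f_pct,
            "accuracy_pct": self.accuracy_pct,
            "alpha": self.alpha,
            "display": {
                "P": fmt(self.precision_pct), "R": fmt(self.recall_pct),
                "F": fmt(self.f_pct), "A": fmt(self.accuracy_pct),
            },
            "exact": {k: [v.numerator, v.denominator] if v is not None else None
                      for k, v in self.exact.items()},
        }


def metrics_report(cc: ConfusionCounts, alpha: Fraction | float = Fraction(1, 2)) -> MetricsReport:
    """Compose P, R, F, A from confusion counts; F is taken on the *exact*
    (unrounded) P and R so rounding never compounds."""
    p, r, a = precision(cc), recall(cc), accuracy(cc)
    f = f_measure(p, r, alpha)
    return MetricsReport(
        precision_pct=None if p is None else round2(p),
        recall_pct=None if r is None else round2(r),
        f_pct=None if f is None else round2(f),
        accuracy_pct=None if a is None else round2(a),
        alpha=float(alpha),
        exact={"P": p, "R": r, "F": f, "A": a},
    )


# ---------------------------------------------------------------------------
# Frequency / cluster analytics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyEntry:
    code: DiagnosisCode
    count: int
    rank: int


@dataclass
class FrequencyTable:
    entries: list[FrequencyEntry]
    total_occurrences: int

    def __iter__(self):
        return iter(self.entries)


def code_frequency(codes: Iterable[DiagnosisCode], top_n: int) -> FrequencyTable:
    """Rank codes by occurrence count, most frequent first.

    Ties are broken lexicographically by code so the ranking is total and
    deterministic.  Returns at most ``top_n`` entries; ``total_occurrences``
    counts the whole input so share-of-total statistics stay honest.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts = Counter(codes)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    entries = [FrequencyEntry(code=c, count=n, rank=i + 1)
               for i, (c, n) in enumerate(ranked)]
    return FrequencyTable(entries=entries, total_occurrences=sum(counts.values()))


@dataclass
class ClusterStats:
    category_count: int  # distinct codes in the cluster
    code_count: int      # total occurrences in the cluster


@dataclass
class ClusterSummary:
    clusters: dict[str, ClusterStats]

    @property
    def total_codes(self) -> int:
        return sum(s.code_count for s in self.clusters.values())

    @property
    def total_categories(self) -> int:
        return sum(s.category_count for s in self.clusters.values())


def cluster_summary(codes: Iterable[DiagnosisCode]) -> ClusterSummary:
    """Per chapter letter (A-Z), count distinct code categories and total
    occurrences.  Rejects syntactically invalid codes by name."""
    occurrences: Counter = Counter()
    categories: dict[str, set] = {}
    for code in codes:
        if not is_valid_code(code):
            raise ValueError(f"syntactically invalid code {code!r}")
        cl = code_cluster(code)
        occurrences[cl] += 1
        categories.setdefault(cl, set()).add(code)
    return ClusterSummary(clusters={
        cl: ClusterStats(category_count=len(categories[cl]), code_count=occurrences[cl])
        for cl in sorted(occurrences)
    })


# ---------------------------------------------------------------------------
# Failure breakdown (repeated / mismatch / loss)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FailureBreakdown:
    """Auditor-facing failure tally: ``repeated`` counts (group, code) pairs
    assigned more than once within one patient group; ``mismatch`` and
    ``loss`` are the FP and FN counts of the same audit."""

    repeated: int
    mismatch: int
    loss: int


def failure_breakdown(run: CodingRun, gold_records: Iterable[DiagnosisRecord],
                      modeled: set[DiagnosisCode]) -> FailureBreakdown:
    gold_records = list(gold_records)
    cc = tabulate(run, gold_records, modeled)
    pair_counts: Counter = Counter()
    for rec in gold_records:
        code = run.assignments.get(rec.record_id)
        if code is not None and rec.group_id is not None:
            pair_counts[(rec.group_id, code)] += 1
    repeated = sum(1 for n in pair_counts.values() if n > 1)
    return FailureBreakdown(repeated=repeated, mismatch=cc.fp, loss=cc.fn)
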