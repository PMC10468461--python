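"""Three-stage high-quality-data extraction.

Hospital ECG archives contain technically unusable traces.  This module
implements the exclusion protocol used when distilling such an archive into a
modelling dataset:

1. **statement screen** — drop records whose machine interpretation contains a
   statement from the low-quality / arm-lead-reversal vocabulary;
2. **signal screen** — drop records with a lead measured as 0 µV throughout
   (electrode not attached) or with fewer frames than expected;
3. **first-visit deduplication** — keep only each subject's earliest record.

Every input record receives a machine-readable QualityDecision so exclusions
are fully auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .leads import LEAD_NAMES
from .records import ECGRecord

REASON_CODES = ("bad_statement", "missing_lead", "short_frames", "duplicate_visit")


@dataclass(frozen=True)
class ExclusionRule:
    group: str       # "low_quality" | "arm_leads_reversed"
    vendor: str
    pattern: str

    def compile(self) -> re.Pattern:
        # Case-insensitive substring; "(s)" in a pattern marks a spot where
        # vendors splice in a lead list ("Artifact in lead(s)" must match
        # "Artifact in leads V1, V2"), so it becomes an optional-s wildcard.
        escaped = re.escape(self.pattern)
        escaped = escaped.replace(re.escape("(s)"), r"s?.*")
        return re.compile(escaped, re.IGNORECASE)


@dataclass
class ExclusionRuleSet:
    rules: list[ExclusionRule]
    _compiled: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("ExclusionRuleSet must be non-empty")
        for r in self.rules:
            if not r.pattern.strip():
                raise ValueError("blank pattern in ExclusionRuleSet")
        self._compiled = [r.compile() for r in self.rules]

    def match(self, statement: str) -> ExclusionRule | None:
        for rule, rx in zip(self.rules, self._compiled):
            if rx.search(statement):
                return rule
        return None


def load_rules(path: str | Path | None = None) -> ExclusionRuleSet:
    """Load the exclusion vocabulary; defaults to the packaged TSV resource."""
    if path is None:
        source = resources.files("ecgsynth").joinpath("data/exclusion_statements.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    rules = [
        ExclusionRule(group=row["group"], vendor=row["vendor"], pattern=row["pattern"])
        for _, row in frame.iterrows()
    ]
    return ExclusionRuleSet(rules)


@dataclass
class QualityDecision:
    record_id: str
    passed: bool
    reasons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)

    @classmethod
    def ok(cls, record_id: str) -> "QualityDecision":
        return cls(record_id=record_id, passed=True)

    @classmethod
    def fail(cls, record_id: str, reasons: list[tuple[str, str]]) -> "QualityDecision":
        return cls(record_id=record_id, passed=False, reasons=reasons)

    def merge(self, other: "QualityDecision") -> "QualityDecision":
        reasons = self.reasons + other.reasons
        return QualityDecision(self.record_id, passed=not reasons, reasons=reasons)


def check_statements(record: ECGRecord, rules: ExclusionRuleSet) -> QualityDecision:
    """Fail iff any interpretation statement matches an exclusion pattern."""
    reasons = []
    for st in record.statements:
        rule = rules.match(st)
        if rule is not None:
            reasons.append(
                ("bad_statement", f"statement {st!r} matches pattern {rule.pattern!r}")
            )
    return QualityDecision(record.record_id, passed=not reasons, reasons=reasons)


def check_signal(
    record: ECGRecord,
    min_frames: int = 5000,
    *,
    zero_tolerance: float = 0.0,
) -> QualityDecision:
    """Fail on any all-zero lead (missing electrode) or short frame count."""
    reasons = []
    for name in LEAD_NAMES:
        if bool((abs(record.leads[name]) <= zero_tolerance).all()):
            reasons.append(("missing_lead", f"lead {name} is 0 µV over all frames"))
    n = record.n_frames
    if n < min_frames:
        reasons.append(("short_frames", f"{n} frames < required {min_frames}"))
    return QualityDecision(record.record_id, passed=not reasons, reasons=reasons)


def deduplicate_first_visit(records: list[ECGRecord]) -> list[ECGRecord]:
    """Keep each subject's earliest record (ties broken by smallest record_id).

    Surviving records are returned ordered by (subject_id, acquisition_time).
    """
    for r in records:
        if r.acquisition_time is None:
            raise ValueError(f"record {r.record_id!r} has no acquisition_time")
    best: dict[str, ECGRecord] = {}
    for r in records:
        key = r.subject_id if r.subject_id is not None else f"__anon__{r.record_id}"
        cur = best.get(key)
        if cur is None or (r.acquisition_time, r.record_id) < (
            cur.acquisition_time,
            cur.record_id,
        ):
            best[key] = r
    return sorted(best.values(), key=lambda r: (str(r.subject_id), r.acquisition_time))


def run_filter(
    records: list[ECGRecord],
    rules: ExclusionRuleSet | None = None,
    min_frames: int = 5000,
    *,
    dedup_first: bool = False,
) -> tuple[list[ECGRecord], list[QualityDecision]]:
    """Apply statement screen, signal screen, then first-visit deduplication.

    By default deduplication runs last, over records that already passed the
    other screens, so a subject whose first visit was excluded still
    contributes their earliest clean record.  ``dedup_first=True`` instead
    deduplicates on raw acquisition order before any screening, in which case
    a subject whose first visit is defective is dropped entirely.

    Returns (survivors, one decision per input record in input order).
    """
    if rules is None:
        rules = load_rules()
    decisions: dict[str, QualityDecision] = {}

    pool = list(records)
    if dedup_first:
        kept = {r.record_id for r in deduplicate_first_visit(pool)}
        for r in pool:
            if r.record_id not in kept:
                decisions[r.record_id] = QualityDecision.fail(
                    r.record_id,
                    [("duplicate_visit", "not the subject's first visit")],
                )
        pool = [r for r in pool if r.record_id in kept]

    screened = []
    for r in pool:
        d = check_statements(r, rules).merge(check_signal(r, min_frames))
        if d.passed:
            screened.append(r)
        else:
            decisions[r.record_id] = d

    if not dedup_first:
        kept_ids = {r.record_id for r in deduplicate_first_visit(screened)}
        for r in screened:
            if r.record_id not in kept_ids:
                decisions[r.record_id] = QualityDecision.fail(
                    r.record_id,
                    [("duplicate_visit", "an earlier clean visit exists for this subject")],
                )
        survivors = [r for r in screened if r.record_id in kept_ids]
    else:
        survivors = screened

    for r in survivors:
        decisions[r.record_id] = QualityDecision.ok(r.record_id)
    ordered = [decisions[r.record_id] for r in records]
    return survivors, ordered


def decisions_frame(decisions: list[QualityDecision]) -> pd.DataFrame:
    """Tabular audit report: one row per record with reason codes and details."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "record_id": d.record_id,
                "passed": d.passed,
                "reasons": ";".join(code for code, _ in d.reasons),
                "details": " | ".join(detail for _, detail in d.reasons),
            }
        )
    return pd.DataFrame(rows, columns=["record_id", "passed", "reasons", "details"])
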