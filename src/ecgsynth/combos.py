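"""Per-lead selection of the best 3-input-lead combination.

Any one of the 12 leads can be regressed on subsets of the other 11.  For
each target lead this module scores all C(11,3) = 165 unordered input triples
with one pooled ordinary-least-squares fit (intercept included, all frames of
all records stacked) and keeps the triple with the smallest residual RMSE.
Because the limb leads are exact linear combinations of one another
(Einthoven/Goldberger), any triple containing leads I and II predicts lead
III with zero residual — a property tests use as an oracle.

A published reference table of per-target triples, obtained by the same
search on a large hospital dataset, is shipped for use when no search data
are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES, check_lead_name
from .records import ECGRecord


@dataclass(frozen=True)
class LeadCombination:
    target: str
    inputs: tuple[str, str, str]
    score: float       # residual RMSE of the pooled OLS fit, normalized scale
    rank: int = 0      # 1 = best among the 165 candidates
    degenerate: bool = False

    def __post_init__(self) -> None:
        check_lead_name(self.target)
        if len(set(self.inputs)) != 3 or self.target in self.inputs:
            raise ValueError(
                f"inputs must be 3 distinct leads != target, got "
                f"{self.inputs} for target {self.target}"
            )


@dataclass
class ComboTable:
    """Selected combination per target lead; source is 'searched' or 'reference'."""

    combos: dict[str, LeadCombination]
    source: str
    ranked: dict[str, list[LeadCombination]] | None = None

    def __post_init__(self) -> None:
        missing = [n for n in LEAD_NAMES if n not in self.combos]
        if missing:
            raise ValueError(f"ComboTable missing targets: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": name,
                "input1": c.inputs[0],
                "input2": c.inputs[1],
                "input3": c.inputs[2],
                "score": c.score,
                "rank": c.rank,
                "source": self.source,
            }
            for name, c in ((n, self.combos[n]) for n in LEAD_NAMES)
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ComboTable":
        frame = pd.read_csv(path, sep="\t")
        combos = {}
        source = "searched"
        for _, row in frame.iterrows():
            combos[row["target"]] = LeadCombination(
                target=row["target"],
                inputs=(row["input1"], row["input2"], row["input3"]),
                score=float(row["score"]),
                rank=int(row["rank"]),
            )
            source = str(row["source"])
        return cls(combos=combos, source=source)


def enumerate_candidates(target: str) -> list[tuple[str, str, str]]:
    """All 165 unordered triples of the 11 non-target leads, in lexicographic
    order by canonical lead index."""
    check_lead_name(target)
    others = [name for name in LEAD_NAMES if name != target]
    return list(combinations(others, 3))


def _pooled_design(
    records: list[ECGRecord], target: str, inputs: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    ys = [r.leads[target] for r in records]
    xs = [np.column_stack([r.leads[name] for name in inputs]) for r in records]
    return np.vstack(xs), np.concatenate(ys)


def score_candidate(
    records: list[ECGRecord], target: str, inputs: tuple[str, str, str]
) -> LeadCombination:
    """Residual RMSE of target ~ 1 + input1 + input2 + input3, frames pooled."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to score a candidate")
    X, y = _pooled_design(records, target, inputs)
    design = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    score = float(np.sqrt(np.mean(resid**2)))
    return LeadCombination(
        target=target,
        inputs=tuple(inputs),
        score=score,
        degenerate=rank < design.shape[1],
    )


#: Scores within this absolute distance of the minimum are treated as tied
#: (floating-point noise must not reorder exactly-derivable candidates).
TIE_TOLERANCE = 1e-9


def select_combinations(records: list[ECGRecord]) -> ComboTable:
    """Exhaustive search: for each target, score all 165 triples and keep the
    best.  Candidates within ``TIE_TOLERANCE`` of the minimum score count as
    tied and the tie is broken by enumeration order.  The full ranked
    candidate lists are retained for reporting."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for the combination search")
    combos: dict[str, LeadCombination] = {}
    ranked: dict[str, list[LeadCombination]] = {}
    for target in LEAD_NAMES:
        scored = [
            score_candidate(records, target, triple)
            for triple in enumerate_candidates(target)
        ]
        best_score = min(c.score for c in scored)
        winner = next(i for i, c in enumerate(scored) if c.score <= best_score + TIE_TOLERANCE)
        order = [winner] + sorted(
            (i for i in range(len(scored)) if i != winner),
            key=lambda i: scored[i].score,
        )
        ranked_list = [
            LeadCombination(
                target=c.target,
                inputs=c.inputs,
                score=c.score,
                rank=pos + 1,
                degenerate=c.degenerate,
            )
            for pos, c in enumerate(scored[i] for i in order)
        ]
        ranked[target] = ranked_list
        combos[target] = ranked_list[0]
    return ComboTable(combos=combos, source="searched", ranked=ranked)


#: Published per-target input triples from a large-hospital search with the
#: same protocol; usable when no local cohort is available for searching.
_REFERENCE_TRIPLES: dict[str, tuple[str, str, str]] = {
    "I": ("aVR", "aVL", "V6"),
    "II": ("aVR", "aVF", "V6"),
    "III": ("II", "aVL", "aVF"),
    "aVR": ("I", "II", "V6"),
    "aVL": ("I", "III", "aVR"),
    "aVF": ("II", "III", "aVR"),
    "V1": ("I", "aVR", "V2"),
    "V2": ("V1", "V3", "V4"),
    "V3": ("V2", "V4", "V5"),
    "V4": ("V2", "V3", "V5"),
    "V5": ("V3", "V4", "V6"),
    "V6": ("aVR", "V4", "V5"),
}


def reference_table() -> ComboTable:
    """The published 12-entry combination table (score unknown, marked NaN)."""
    combos = {
        target: LeadCombination(target=target, inputs=triple, score=float("nan"), rank=1)
        for target, triple in _REFERENCE_TRIPLES.items()
    }
    return ComboTable(combos=combos, source="reference")
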