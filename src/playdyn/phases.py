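"""Treatment-phase comparison and reliable-change outcome assessment.

Each patient's categorical series (state labels per session, or activity
types per segment) is split into treatment halves — the first half takes
floor(N/2) sessions — and each category's occurrence is compared across
halves by the ratio of relative frequencies (n_first/N_first) /
(n_second/N_second).  Although the source study labels these "odds
ratios", its printed values follow the frequency-ratio rule, which is
therefore the default; a true odds ratio (optionally with the Haldane 0.5
continuity correction) is available for sensitivity.  A ratio is undefined
("n.d.") whenever either half-count is zero.

Outcome change is assessed with the reliable change index: the pre/post
difference in the improving direction divided by the instrument's standard
error of the difference, significant when it exceeds 1.96, alongside
whether the score crossed the instrument's clinical cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .core import (ACTIVITY_TYPES, OutcomeRecord, SegmentRating,
                   StateSequence, register_report_type)

logger = logging.getLogger(__name__)

T = TypeVar("T")

#: Clinical cutoffs per instrument (scores at/above are clinical range for
#: decrease_is_better instruments, at/below for increase_is_better ones).
DEFAULT_CUTOFFS: dict[str, float] = {
    "CBCL-Internalizing": 64.0,
    "CBCL-Anxiety": 70.0,
}


def split_halves(sequence: Sequence[T]) -> tuple[list[T], list[T]]:
    """Split an ordered series into treatment halves (floor rule).

    The first half holds floor(N/2) elements, the second the remainder
    (e.g. 47 → 23 + 24).
    """
    if len(sequence) < 2:
        raise ValueError("need at least two elements to split")
    half = len(sequence) // 2
    return list(sequence[:half]), list(sequence[half:])


@register_report_type
@dataclass(frozen=True)
class PhaseComparison:
    """First-half vs second-half occurrence counts and ratios.

    ``rows`` maps category → dict with n_first, n_second and ratio (None
    when undefined, i.e. either half-count is zero — printed as "n.d.").
    """

    patient_id: str
    unit: str  # "state" or "activity_type"
    n_first_total: int
    n_second_total: int
    rows: Mapping

    def ratio(self, category) -> float | None:
        return self.rows[category]["ratio"]

    def defined_ratios(self) -> dict:
        return {c: r["ratio"] for c, r in self.rows.items()
                if r["ratio"] is not None}

    def summary(self) -> dict:
        """Mean and SD over the defined ratios only."""
        vals = list(self.defined_ratios().values())
        return {"mean": float(np.mean(vals)) if vals else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"category": c, **r} for c, r in self.rows.items()
        ])

    def to_dict(self) -> dict:
        return {"patient_id": self.patient_id, "unit": self.unit,
                "n_first_total": self.n_first_total,
                "n_second_total": self.n_second_total,
                "rows": {str(c): dict(r) for c, r in self.rows.items()}}

    @classmethod
    def from_dict(cls, d) -> "PhaseComparison":
        rows = {(int(c) if d["unit"] == "state" else c): dict(r)
                for c, r in d["rows"].items()}
        return cls(d["patient_id"], d["unit"], int(d["n_first_total"]),
                   int(d["n_second_total"]), rows)


def occurrence_ratio(n_first: int, n_second: int, total_first: int,
                     total_second: int, formula: str = "frequency_ratio",
                     haldane: bool = False) -> float | None:
    """First-vs-second-half occurrence ratio for one category.

    ``frequency_ratio`` (default): (n1/N1) / (n2/N2).  ``odds_ratio``:
    (n1/(N1−n1)) / (n2/(N2−n2)), optionally Haldane-corrected (add 0.5 to
    every cell).  Returns None ("n.d.") when either raw count is zero.
    """
    if formula not in ("frequency_ratio", "odds_ratio"):
        raise ValueError(f"unknown ratio formula {formula!r}")
    if n_first == 0 or n_second == 0:
        return None
    if formula == "frequency_ratio":
        return (n_first / total_first) / (n_second / total_second)
    a, b = float(n_first), float(total_first - n_first)
    c, d = float(n_second), float(total_second - n_second)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b == 0 or d == 0 or c == 0:
        return None
    return (a / b) / (c / d)


def state_phase_comparison(sequence: StateSequence,
                           formula: str = "frequency_ratio",
                           haldane: bool = False) -> PhaseComparison:
    """Per-state occurrence ratios between treatment halves of one patient."""
    first, second = split_halves(sequence.states)
    rows = {}
    for state in range(1, sequence.n_states + 1):
        nf, ns = first.count(state), second.count(state)
        rows[state] = {
            "n_first": nf, "n_second": ns,
            "ratio": occurrence_ratio(nf, ns, len(first), len(second),
                                      formula, haldane),
        }
    return PhaseComparison(sequence.patient_id, "state",
                           len(first), len(second), rows)


def activity_phase_comparison(segments: Sequence[SegmentRating],
                              patient_id: str,
                              formula: str = "frequency_ratio",
                              haldane: bool = False) -> PhaseComparison:
    """Activity-type occurrence ratios between treatment halves.

    Sessions (not segments) are split into halves by session order; the
    counts are of segments of each activity type within each half, and the
    denominators are the numbers of sessions per half (so the ratio
    compares per-session activity rates across halves).
    """
    mine = [s for s in segments if s.patient_id == patient_id]
    if not mine:
        raise ValueError(f"no segments for patient {patient_id!r}")
    session_order = sorted({s.session_index for s in mine})
    first_sessions, second_sessions = split_halves(session_order)
    first_set, second_set = set(first_sessions), set(second_sessions)
    rows = {}
    n1, n2 = len(first_sessions), len(second_sessions)
    for act in ACTIVITY_TYPES:
        nf = sum(1 for s in mine
                 if s.activity_type == act and s.session_index in first_set)
        ns = sum(1 for s in mine
                 if s.activity_type == act and s.session_index in second_set)
        rows[act] = {"n_first": nf, "n_second": ns,
                     "ratio": occurrence_ratio(nf, ns, n1, n2, formula, haldane)}
    return PhaseComparison(patient_id, "activity_type", n1, n2, rows)


# ---------------------------------------------------------------------------
# reliable change
# ---------------------------------------------------------------------------


@register_report_type
@dataclass(frozen=True)
class ReliableChange:
    """Reliable change index and clinical-cutoff crossing for one outcome."""

    outcome: OutcomeRecord
    rci: float
    significant: bool
    crossed_cutoff: bool | None  # None when no cutoff is configured

    def to_dict(self) -> dict:
        return {"outcome": self.outcome.to_dict(), "rci": self.rci,
                "significant": self.significant,
                "crossed_cutoff": self.crossed_cutoff}

    @classmethod
    def from_dict(cls, d) -> "ReliableChange":
        return cls(OutcomeRecord.from_dict(d["outcome"]), float(d["rci"]),
                   bool(d["significant"]), d["crossed_cutoff"])


def reliable_change(outcome: OutcomeRecord,
                    cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS
                    ) -> ReliableChange:
    """Reliable change index of one pre/post outcome.

    RCI = (pre − post)/se_diff for instruments where decrease means
    improvement, (post − pre)/se_diff where increase does; change is
    reliable when RCI > 1.96.  ``crossed_cutoff`` reports whether the
    patient moved from the clinical to the non-clinical side of the
    instrument's configured cutoff (None when no cutoff is configured).
    """
    if outcome.improvement_direction == "decrease_is_better":
        rci = (outcome.pre - outcome.post) / outcome.se_diff
    else:
        rci = (outcome.post - outcome.pre) / outcome.se_diff
    cutoff = cutoffs.get(outcome.instrument)
    crossed: bool | None = None
    if cutoff is not None:
        if outcome.improvement_direction == "decrease_is_better":
            crossed = outcome.pre >= cutoff > outcome.post
        else:
            crossed = outcome.pre <= cutoff < outcome.post
    return ReliableChange(outcome, float(rci), bool(rci > 1.96), crossed)


def reliable_change_table(outcomes: Sequence[OutcomeRecord],
                          cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS
                          ) -> pd.DataFrame:
    """RCI table over outcome records (one row per patient × instrument)."""
    rows = []
    for rec in outcomes:
        rc = reliable_change(rec, cutoffs)
        rows.append({"patient_id": rec.patient_id, "instrument": rec.instrument,
                     "pre": rec.pre, "post": rec.post, "se_diff": rec.se_diff,
                     "rci": rc.rci, "significant": rc.significant,
                     "crossed_cutoff": rc.crossed_cutoff})
    return pd.DataFrame(rows)
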