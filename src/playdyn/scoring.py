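"""CPTI composite play-profile scoring, instrument reliability, segmentation.

Each rated play segment receives five composite scores — Adaptive,
Inhibited, Impulsive, Disorganized and Play Engagement — computed as the
arithmetic mean of the segment's scores on the CPTI items assigned to that
profile.  All items share the 1–5 Likert metric, so no standardisation is
applied.  Items may legitimately belong to several profiles (e.g.
Facilitation of Play counts toward both Adaptive and Engagement; Inhibition
of Play toward Inhibited, Impulsive and Disorganized).

Reliability helpers compute Cronbach's alpha over the items of a profile and
a two-way random, absolute-agreement, single-rater intraclass correlation
(ICC(2,1)) between independent raters.  Segmentation summaries report
activity-type composition per patient and select each session's longest
play segment — the unit of all downstream state analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ACTIVITY_TYPES, PROFILES, SegmentRating, register_report_type

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# profile item map
# ---------------------------------------------------------------------------

#: CPTI items constituting each composite profile.
DEFAULT_PROFILE_ITEMS: dict[str, tuple[str, ...]] = {
    "adaptive": (
        "facilitation_of_play",
        "play_in_microsphere",
        "affect_regulation_flexible",
        "affect_transitions_smooth",
        "hedonic_tone_pleasurable",
        "affect_appropriate_to_content",
        "one_or_more_play_roles",
        "voluntary_role_transformation",
        "verbalization_of_roles",
        "describing_play",
        "defense_adaptive",
        "aware_of_play",
    ),
    "inhibited": (
        "inhibition_of_play",
        "hedonic_tone_somber",
        "affect_spectrum_narrow",
        "affect_regulation_rigid",
        "solitary_play_roles",
        "self_related_relations",
        "language_silence",
        "play_alone",
        "defense_conflicted",
    ),
    "impulsive": (
        "inhibition_of_play",
        "play_in_macrosphere",
        "affect_tone_overt_distress",
        "affect_regulation_rigid",
        "affect_transitions_abrupt",
        "affect_anger",
        "involuntary_role_transformation",
        "magical_representations",
        "defense_polarized",
        "unaware_of_play",
    ),
    "disorganized": (
        "inhibition_of_play",
        "affect_tone_overt_distress",
        "affect_inappropriate_to_content",
        "affect_anger",
        "involuntary_role_transformation",
        "bizarre_representations",
        "isolated_play",
        "defense_extreme_anxiety",
        "unaware_of_play",
    ),
    "engagement": (
        "facilitation_of_play",
        "hedonic_tone_pleasurable",
        "affect_regulation_flexible",
        "affect_transitions_smooth",
        "defense_adaptive",
    ),
}

#: Every CPTI item referenced by some profile, in deterministic order.
ALL_ITEMS: tuple[str, ...] = tuple(sorted(
    {item for items in DEFAULT_PROFILE_ITEMS.values() for item in items}
))


@dataclass(frozen=True)
class ProfileItemMap:
    """Assignment of CPTI item labels to the five composite profiles."""

    items: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_ITEMS))

    def __post_init__(self) -> None:
        missing = [p for p in PROFILES if p not in self.items]
        if missing:
            raise ValueError(f"profile item map missing profiles: {missing}")
        empty = [p for p, its in self.items.items() if len(its) == 0]
        if empty:
            raise ValueError(f"profiles with no items: {empty}")


DEFAULT_ITEM_MAP = ProfileItemMap()


@register_report_type
@dataclass(frozen=True)
class ProfileScores:
    """The five composite scores of one play segment (each in [1, 5])."""

    adaptive: float
    inhibited: float
    impulsive: float
    disorganized: float
    engagement: float

    def as_vector(self) -> np.ndarray:
        """Scores as a vector in canonical :data:`~playdyn.core.PROFILES` order."""
        return np.array([getattr(self, p) for p in PROFILES], dtype=float)

    def to_dict(self) -> dict:
        return {p: getattr(self, p) for p in PROFILES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ProfileScores":
        return cls(**{p: float(d[p]) for p in PROFILES})


class MissingItemError(KeyError):
    """An item required by the profile map is absent from a segment."""


def score_profiles(segment: SegmentRating,
                   item_map: ProfileItemMap = DEFAULT_ITEM_MAP) -> ProfileScores:
    """Compute the five composite profile scores for one rated segment.

    Each composite is the arithmetic mean of the segment's scores on the
    items the map assigns to that profile.  Items shared between profiles
    are counted once per profile.  A missing item raises
    :class:`MissingItemError` naming the item and the profile.
    """
    values = {}
    for profile in PROFILES:
        items = item_map.items[profile]
        try:
            scores = [segment.item_scores[i] for i in items]
        except KeyError as exc:
            raise MissingItemError(
                f"segment ({segment.patient_id}, s{segment.session_index}, "
                f"g{segment.segment_index}) lacks item {exc.args[0]!r} "
                f"required by profile {profile!r}"
            ) from None
        values[profile] = float(np.mean(scores))
    return ProfileScores(**values)


def score_segments(segments: Sequence[SegmentRating],
                   item_map: ProfileItemMap = DEFAULT_ITEM_MAP) -> pd.DataFrame:
    """Score every rated play segment; returns one row per segment.

    Columns: ``patient_id, session_index, segment_index`` plus the five
    profiles.  Non-play segments (which carry no item ratings) are skipped.
    """
    rows = []
    for seg in segments:
        if seg.activity_type != "play" or not seg.item_scores:
            continue
        ps = score_profiles(seg, item_map)
        rows.append({"patient_id": seg.patient_id,
                     "session_index": seg.session_index,
                     "segment_index": seg.segment_index,
                     **ps.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a segments × items score table.

    alpha = k/(k−1) · (1 − Σ item variances / variance of item sums).
    Returns NaN (with a logged warning) when the total variance is zero.
    Requires at least two items and two segments.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 segments and 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        logger.warning("zero total variance: Cronbach alpha undefined")
        return float("nan")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def icc_agreement(ratings, variant: str = "ICC2") -> float:
    """Inter-rater ICC of a segments × raters table.

    Default ``ICC2``: two-way random effects, absolute agreement, single
    rater — appropriate when the same fixed set of independent raters rates
    every segment.  Other pingouin variants (``ICC1``..``ICC3k``) are
    accepted for sensitivity analysis.  Degenerate tables (no
    between-segment variance) return NaN with a logged warning.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 segments and 2 raters")
    if np.allclose(X.var(axis=1, ddof=0), 0) and np.var(X.mean(axis=1)) == 0:
        logger.warning("degenerate ratings table: ICC undefined")
        return float("nan")
    import pingouin as pg

    n, k = X.shape
    long = pd.DataFrame({
        "segment": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": X.ravel(),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pg.intraclass_corr(data=long, targets="segment",
                                   raters="rater", ratings="score")
    # pingouin labels the variants ICC(1,1)/ICC(A,1)/... in newer releases
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
               "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}
    wanted = {variant, aliases.get(variant, variant)}
    row = table.loc[table["Type"].isin(wanted), "ICC"]
    if row.empty:
        raise ValueError(f"unknown ICC variant {variant!r}")
    value = float(row.iloc[0])
    if np.isnan(value):
        logger.warning("degenerate ratings table: ICC undefined")
    return value


def profile_alphas(segments: Sequence[SegmentRating],
                   item_map: ProfileItemMap = DEFAULT_ITEM_MAP,
                   grouping: str = "pooled") -> dict:
    """Cronbach's alpha per profile over rated play segments.

    ``grouping='pooled'`` (default) pools segments across patients, giving
    one alpha per profile; ``'per_patient'`` returns a nested mapping
    patient → profile → alpha.
    """
    rated = [s for s in segments if s.activity_type == "play" and s.item_scores]
    if grouping == "per_patient":
        out: dict = {}
        for pid in sorted({s.patient_id for s in rated}):
            out[pid] = profile_alphas([s for s in rated if s.patient_id == pid],
                                      item_map, "pooled")
        return out
    if grouping != "pooled":
        raise ValueError(f"unknown alpha grouping {grouping!r}")
    result = {}
    for profile in PROFILES:
        items = item_map.items[profile]
        mat = np.array([[s.item_scores[i] for i in items] for s in rated],
                       dtype=float)
        result[profile] = cronbach_alpha(mat) if len(mat) >= 2 else float("nan")
    return result


# ---------------------------------------------------------------------------
# segmentation summary
# ---------------------------------------------------------------------------


@register_report_type
@dataclass(frozen=True)
class SegmentationSummary:
    """Per-patient activity composition and per-session longest play segment.

    ``proportions`` maps patient → activity type → fraction of that
    patient's segments (summing to 1).  ``longest_play`` maps patient →
    session index → segment index of the selected longest play segment.
    Sessions without any play segment are listed in ``sessions_without_play``
    and excluded from selection.
    """

    counts: dict
    proportions: dict
    longest_play: dict
    sessions_without_play: list

    def to_dict(self) -> dict:
        return {
            "counts": {p: dict(c) for p, c in self.counts.items()},
            "proportions": {p: dict(c) for p, c in self.proportions.items()},
            "longest_play": {p: {str(s): g for s, g in m.items()}
                             for p, m in self.longest_play.items()},
            "sessions_without_play": [list(x) for x in self.sessions_without_play],
        }

    @classmethod
    def from_dict(cls, d) -> "SegmentationSummary":
        return cls(
            counts={p: dict(c) for p, c in d["counts"].items()},
            proportions={p: dict(c) for p, c in d["proportions"].items()},
            longest_play={p: {int(s): g for s, g in m.items()}
                          for p, m in d["longest_play"].items()},
            sessions_without_play=[tuple(x) for x in d["sessions_without_play"]],
        )


def _segment_length(seg: SegmentRating) -> float:
    # rated duration when available; without one, all segments tie and the
    # earliest wins
    return seg.duration if seg.duration is not None else 0.0


def segmentation_summary(segments: Sequence[SegmentRating]) -> SegmentationSummary:
    """Summarise activity composition and select longest play segments.

    The longest play segment per session is the one with the greatest rated
    duration; ties (including segments without a duration field) go to the
    earliest segment and are logged.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    counts: dict = {}
    for seg in segments:
        counts.setdefault(seg.patient_id, {t: 0 for t in ACTIVITY_TYPES})
        counts[seg.patient_id][seg.activity_type] += 1
    proportions = {
        pid: {t: c[t] / sum(c.values()) for t in ACTIVITY_TYPES}
        for pid, c in counts.items()
    }

    longest: dict = {}
    no_play: list = []
    sessions: dict = {}
    for seg in segments:
        sessions.setdefault((seg.patient_id, seg.session_index), []).append(seg)
    for (pid, sess) in sorted(sessions):
        plays = [s for s in sessions[(pid, sess)] if s.activity_type == "play"]
        if not plays:
            no_play.append((pid, sess))
            continue
        plays.sort(key=lambda s: s.segment_index)
        lengths = [_segment_length(s) for s in plays]
        best = int(np.argmax(lengths))  # argmax takes the earliest on ties
        if lengths.count(lengths[best]) > 1:
            logger.info("session (%s, %d): tie on longest play segment, "
                        "keeping earliest (segment %d)",
                        pid, sess, plays[best].segment_index)
        longest.setdefault(pid, {})[sess] = plays[best].segment_index
    if no_play:
        logger.warning("%d session(s) without a play segment excluded: %s",
                       len(no_play), no_play)
    return SegmentationSummary(counts, proportions, longest, no_play)
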