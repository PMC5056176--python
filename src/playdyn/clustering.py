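"""Discrete play states via K-means in profile space.

Before pooling patients into one clustering, the cross-patient invariance of
the profile correlation structure is checked: Play Engagement must correlate
negatively with the Disorganized and Inhibited profiles, the three
non-adaptive profiles (Disorganized, Impulsive, Inhibited) positively with
one another, and Adaptive positively with Engagement, in every patient.
When these sign relations hold, the profile descriptors carry the same
meaning across patients and their segments can be clustered jointly.

States are K-means clusters of segments over the five profile scores only
(unstandardised — all profiles share the 1–5 metric).  Modal theme codes
are attached per cluster afterwards; unordered categorical codes are not
Euclidean features.  The number of states follows the first peak (or
plateau) of the explained-variance curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .core import PROFILES, ClusterCenters, StateSequence, register_report_type

logger = logging.getLogger(__name__)

#: The required sign relations of the profile correlation structure, as
#: (profile_a, profile_b, expected sign) triples.
REQUIRED_SIGN_RELATIONS: tuple[tuple[str, str, int], ...] = (
    ("engagement", "disorganized", -1),
    ("engagement", "inhibited", -1),
    ("disorganized", "impulsive", +1),
    ("disorganized", "inhibited", +1),
    ("impulsive", "inhibited", +1),
    ("adaptive", "engagement", +1),
)


@register_report_type
@dataclass(frozen=True, eq=False)
class CorrelationCheck:
    """Per-patient profile correlation matrices and sign-relation verdicts.

    ``matrices`` maps patient → 5×5 Pearson correlation DataFrame (profiles
    in canonical order); ``relations`` maps patient → relation label →
    bool; ``undefined`` lists (patient, a, b) pairs whose correlation is
    undefined because one series is constant.
    """

    matrices: Mapping[str, pd.DataFrame]
    relations: Mapping[str, Mapping[str, bool]]
    undefined: list

    @property
    def all_hold(self) -> bool:
        return all(all(v.values()) for v in self.relations.values())

    def to_dict(self) -> dict:
        return {
            "matrices": {p: m.values.tolist() for p, m in self.matrices.items()},
            "profiles": list(PROFILES),
            "relations": {p: dict(r) for p, r in self.relations.items()},
            "undefined": [list(u) for u in self.undefined],
        }

    @classmethod
    def from_dict(cls, d) -> "CorrelationCheck":
        mats = {p: pd.DataFrame(np.asarray(m), index=list(PROFILES),
                                columns=list(PROFILES))
                for p, m in d["matrices"].items()}
        return cls(mats, {p: dict(r) for p, r in d["relations"].items()},
                   [tuple(u) for u in d["undefined"]])


def correlation_invariance(series_by_patient: Mapping[str, pd.DataFrame],
                           min_segments: int = 10) -> CorrelationCheck:
    """Check the cross-patient invariance of the profile correlation structure.

    ``series_by_patient`` maps patient id to a DataFrame with the five
    profile columns (one row per segment, session order).  Each patient must
    contribute at least ``min_segments`` rows.  A constant series makes its
    pairwise correlations undefined; the affected relations are flagged as
    not holding and listed in ``undefined``.
    """
    matrices, relations, undefined = {}, {}, []
    for pid, df in series_by_patient.items():
        if len(df) < min_segments:
            raise ValueError(
                f"patient {pid!r} contributes only {len(df)} segments "
                f"(need >= {min_segments})")
        sub = df.loc[:, list(PROFILES)].astype(float)
        corr = sub.corr()  # pandas leaves NaN for constant columns
        matrices[pid] = corr
        verdict = {}
        for a, b, sign in REQUIRED_SIGN_RELATIONS:
            r = corr.loc[a, b]
            label = f"{a}~{b}{'+' if sign > 0 else '-'}"
            if np.isnan(r):
                undefined.append((pid, a, b))
                verdict[label] = False
            else:
                verdict[label] = bool(np.sign(r) == sign)
        relations[pid] = verdict
    if undefined:
        logger.warning("correlations undefined for constant series: %s",
                       undefined)
    return CorrelationCheck(matrices, relations, undefined)


def select_k(explained_variance_curve: Mapping[int, float],
             tolerance: float = 0.01) -> int:
    """Pick K at the first peak/plateau of the explained-variance curve.

    Returns the smallest K whose gain to K+1 is negative or at most
    ``tolerance`` (a stationary value).  The curve must be defined on a
    contiguous K range.  If every gain exceeds the tolerance the maximal K
    is returned with a warning.
    """
    ks = sorted(explained_variance_curve)
    if len(ks) < 2:
        raise ValueError("curve must cover at least two K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("curve must be defined on a contiguous K range")
    for k in ks[:-1]:
        gain = explained_variance_curve[k + 1] - explained_variance_curve[k]
        if gain <= tolerance:
            return k
    logger.warning("explained variance still rising at K=%d; returning max K",
                   ks[-1])
    return ks[-1]


@register_report_type
@dataclass(frozen=True, eq=False)
class StateModel:
    """A fitted K-state clustering of segments in profile space.

    ``labels`` are 1..K, re-indexed by descending cluster size for
    reproducible naming; ``explained_variance`` maps candidate K to the
    between-cluster share of total sum of squares.
    """

    n_states: int
    centers: ClusterCenters
    labels: np.ndarray
    explained_variance: Mapping[int, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "centers": self.centers.to_dict(),
            "labels": np.asarray(self.labels).tolist(),
            "explained_variance": {str(k): float(v)
                                   for k, v in self.explained_variance.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d) -> "StateModel":
        return cls(int(d["n_states"]), ClusterCenters.from_dict(d["centers"]),
                   np.asarray(d["labels"], dtype=int),
                   {int(k): float(v) for k, v in d["explained_variance"].items()},
                   int(d["seed"]))


def _profile_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        return profiles.loc[:, list(PROFILES)].to_numpy(dtype=float)
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PROFILES):
        raise ValueError(f"profile matrix must be n × {len(PROFILES)}")
    return X


def explained_variance_scan(profiles, k_range: Sequence[int] = range(2, 13),
                            seed: int = 0, n_init: int = 25) -> dict[int, float]:
    """Explained variance (between-cluster SS / total SS) over candidate K."""
    X = _profile_matrix(profiles)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    if tss == 0:
        raise ValueError("all segments identical: explained variance undefined")
    curve = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        curve[int(k)] = 1.0 - km.inertia_ / tss
    return curve


def fit_states(profiles, n_states: int, seed: int = 0, n_init: int = 25,
               explained_variance_curve: Mapping[int, float] | None = None
               ) -> StateModel:
    """K-means over the five (unstandardised) profile scores.

    Clusters are re-labelled 1..K by descending size.  ``profiles`` is a
    DataFrame with the profile columns or an n×5 array.  Deterministic for a
    given ``seed``.  Raises on K > n segments or on degenerate (all
    identical) input.
    """
    X = _profile_matrix(profiles)
    if n_states > len(X):
        raise ValueError(f"K={n_states} exceeds {len(X)} segments")
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    if tss == 0:
        raise ValueError("all segments identical: clustering undefined")
    km = KMeans(n_clusters=n_states, n_init=n_init, random_state=seed).fit(X)
    sizes = np.bincount(km.labels_, minlength=n_states)
    if np.any(sizes == 0):  # sklearn avoids this, but keep the contract explicit
        logger.warning("empty cluster after fit; refitting with a new seed")
        km = KMeans(n_clusters=n_states, n_init=n_init,
                    random_state=seed + 1).fit(X)
        sizes = np.bincount(km.labels_, minlength=n_states)
    order = np.argsort(-sizes, kind="stable")  # descending size, stable ties
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(1, n_states + 1)
    labels = relabel[km.labels_]
    centers = np.clip(km.cluster_centers_[order], 1.0, 5.0)
    ev = dict(explained_variance_curve or {})
    ev[n_states] = 1.0 - km.inertia_ / tss
    return StateModel(n_states, ClusterCenters(n_states, centers),
                      labels.astype(int), ev, seed)


def attach_modal_themes(model: StateModel,
                        segments: pd.DataFrame) -> StateModel:
    """Attach per-cluster modal theme codes (post hoc, not features).

    ``segments`` must align row-wise with the fitted labels and carry the
    four code columns ``theme_primary, theme_secondary, relational_primary,
    relational_secondary``.  The mode (smallest value on ties) of each code
    within each cluster becomes the cluster's modal theme vector.
    """
    code_cols = ["theme_primary", "theme_secondary",
                 "relational_primary", "relational_secondary"]
    if len(segments) != len(model.labels):
        raise ValueError("segments must align with fitted labels")
    modal = np.zeros((model.n_states, len(code_cols)), dtype=int)
    for k in range(1, model.n_states + 1):
        sub = segments.loc[np.asarray(model.labels) == k, code_cols]
        for j, col in enumerate(code_cols):
            modal[k - 1, j] = int(sub[col].mode().iloc[0]) if len(sub) else 0
    centers = ClusterCenters(model.n_states, model.centers.centers, modal)
    return StateModel(model.n_states, centers, model.labels,
                      model.explained_variance, model.seed)


def assign_states(model_or_centers, profiles: pd.DataFrame
                  ) -> list[StateSequence]:
    """Assign new segments to the nearest cluster center, per patient.

    ``profiles`` is a DataFrame with ``patient_id``, ``session_index`` and
    the five profile columns; rows are ordered by session within patient.
    Equidistant segments take the lower-indexed state (logged).  Returns one
    :class:`~playdyn.core.StateSequence` per patient, in order of first
    appearance.
    """
    centers = (model_or_centers.centers if isinstance(model_or_centers, StateModel)
               else model_or_centers)
    X = profiles.loc[:, list(PROFILES)].to_numpy(dtype=float)
    dist = cdist(X, centers.centers)
    labels = dist.argmin(axis=1)  # argmin keeps the lower index on ties
    ties = (dist == dist[np.arange(len(X)), labels][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d segment(s) equidistant to multiple centers; "
                    "assigned the lower-indexed state", int(ties.sum()))
    out = []
    df = profiles.assign(_state=labels + 1)
    for pid in pd.unique(df["patient_id"]):
        sub = df[df["patient_id"] == pid].sort_values("session_index",
                                                      kind="stable")
        out.append(StateSequence(str(pid), tuple(int(s) for s in sub["_state"]),
                                 centers.n_states))
    return out
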