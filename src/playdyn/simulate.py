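"""Synthetic cohorts with the statistical structure the pipeline assumes.

Ground-truth generator for end-to-end testing: a latent first-order Markov
chain over K play states drives each patient's session trajectory; every
session's longest play segment emits profile scores centred on its state's
cluster center (Gaussian noise, clipped to the 1–5 Likert range) or, in
item-level mode, integer CPTI item scores whose profile means approximate
the state targets.  Activity types are drawn per treatment half with
phase-dependent rates (interruptions halve by default in the second half),
and pre/post outcome scores are drawn around a configurable treatment
effect.  Everything is reproducible from one master seed.

Defaults mirror the published case study: the planted transition matrix is
the printed pooled percentage matrix renormalised row-stochastic, the
planted centers are the printed seven cluster centers, and each patient
receives 55 sessions (the study's mean treatment length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (PROFILES, ClusterCenters, OutcomeRecord, SegmentRating,
                   StateSequence, fixture, register_report_type,
                   PRINTED_TRANSITION_PERCENTAGES)
from .scoring import DEFAULT_ITEM_MAP, ProfileItemMap

__all__ = [
    "SimulationConfig", "SyntheticCohort", "generate_cohort",
    "generate_profile_series", "default_transition_matrix",
    "stationary_distribution",
]


def default_transition_matrix() -> np.ndarray:
    """The published pooled percentage matrix, renormalised row-stochastic."""
    m = PRINTED_TRANSITION_PERCENTAGES.astype(float)
    return m / m.sum(axis=1, keepdims=True)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left
    eigenvector, normalised)."""
    m = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eig(m.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


def _validate_stochastic(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("transition matrix must be square")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    return m


#: Default activity-type rates per treatment half.  Interruptions halve in
#: the second half (the direction of change the study reports), the freed
#: mass going to play.
DEFAULT_ACTIVITY_RATES: dict[str, dict[str, float]] = {
    "first": {"pre_play": 0.15, "play": 0.50, "non_play": 0.25,
              "interruption": 0.10},
    "second": {"pre_play": 0.15, "play": 0.55, "non_play": 0.25,
               "interruption": 0.05},
}

#: Default pre/post outcome effects: (pre_mean, post_mean, score_sd,
#: se_diff, improvement_direction), on the scales of the study instruments.
DEFAULT_OUTCOME_EFFECT: dict[str, tuple] = {
    "CBCL-Internalizing": (64.0, 47.0, 3.0, 2.80, "decrease_is_better"),
    "CBCL-Anxiety": (65.0, 52.0, 3.0, 1.20, "decrease_is_better"),
    "CGAS": (52.0, 77.0, 3.0, 5.16, "increase_is_better"),
}


@register_report_type
@dataclass(frozen=True, eq=False)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``sessions_per_patient`` is an int or an inclusive (lo, hi) range;
    ``profile_noise_sd`` the per-coordinate Gaussian sd of emitted profile
    scores (score units); ``item_emission`` either ``profile_level``
    (continuous profile scores attached directly) or ``item_level``
    (integer CPTI item scores whose profile means approximate the state
    targets, with per-item noise ``item_noise_sd``).
    """

    n_patients: int = 3
    sessions_per_patient: int | tuple[int, int] = 55
    n_states: int = 7
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    state_centers: ClusterCenters = field(
        default_factory=lambda: fixture("table3_centers"))
    profile_noise_sd: float = 0.15
    item_emission: str = "profile_level"
    item_noise_sd: float = 0.3
    item_shared_sd: float = 0.5
    segments_per_session: tuple[int, int] = (4, 7)
    activity_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {h: dict(r)
                                 for h, r in DEFAULT_ACTIVITY_RATES.items()})
    outcome_effect: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECT))
    master_seed: int = 0

    def __post_init__(self) -> None:
        m = _validate_stochastic(self.transition_matrix)
        object.__setattr__(self, "transition_matrix", m)
        if m.shape[0] != self.n_states:
            raise ValueError("transition matrix size must equal n_states")
        if self.state_centers.n_states != self.n_states:
            raise ValueError("state centers must cover n_states clusters")
        if self.item_emission not in ("profile_level", "item_level"):
            raise ValueError(f"unknown item_emission {self.item_emission!r}")
        for half in ("first", "second"):
            rates = self.activity_rates[half]
            total = sum(rates.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"activity rates for {half!r} half sum to "
                                 f"{total}, expected 1")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "sessions_per_patient": (list(self.sessions_per_patient)
                                     if isinstance(self.sessions_per_patient, tuple)
                                     else self.sessions_per_patient),
            "n_states": self.n_states,
            "transition_matrix": self.transition_matrix.tolist(),
            "state_centers": self.state_centers.to_dict(),
            "profile_noise_sd": self.profile_noise_sd,
            "item_emission": self.item_emission,
            "item_noise_sd": self.item_noise_sd,
            "item_shared_sd": self.item_shared_sd,
            "segments_per_session": list(self.segments_per_session),
            "activity_rates": {h: dict(r) for h, r in self.activity_rates.items()},
            "outcome_effect": {k: list(v) for k, v in self.outcome_effect.items()},
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d) -> "SimulationConfig":
        spp = d["sessions_per_patient"]
        return cls(
            n_patients=int(d["n_patients"]),
            sessions_per_patient=tuple(spp) if isinstance(spp, list) else int(spp),
            n_states=int(d["n_states"]),
            transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
            state_centers=ClusterCenters.from_dict(d["state_centers"]),
            profile_noise_sd=float(d["profile_noise_sd"]),
            item_emission=d["item_emission"],
            item_noise_sd=float(d["item_noise_sd"]),
            item_shared_sd=float(d.get("item_shared_sd", 0.5)),
            segments_per_session=tuple(d["segments_per_session"]),
            activity_rates={h: dict(r) for h, r in d["activity_rates"].items()},
            outcome_effect={k: tuple(v) for k, v in d["outcome_effect"].items()},
            master_seed=int(d["master_seed"]),
        )


@dataclass(frozen=True, eq=False)
class SyntheticCohort:
    """A generated cohort with its ground truth.

    ``segments`` holds every generated segment (item scores filled only in
    item-level mode); ``profiles`` one row per session's longest play
    segment with the five emitted profile scores and the planted
    ``true_state``; ``true_states`` the per-patient planted trajectories;
    ``outcomes`` the drawn pre/post records.
    """

    segments: list[SegmentRating]
    profiles: pd.DataFrame
    true_states: list[StateSequence]
    outcomes: list[OutcomeRecord]
    config: SimulationConfig


def _simulate_chain(rng: np.random.Generator, matrix: np.ndarray,
                    n_steps: int) -> np.ndarray:
    pi = stationary_distribution(matrix)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    for t in range(1, n_steps):
        states[t] = rng.choice(len(pi), p=matrix[states[t - 1]])
    return states + 1  # 1-based labels


def _emit_items(rng: np.random.Generator, center: np.ndarray,
                item_map: ProfileItemMap, noise_sd: float,
                shared_sd: float) -> dict[str, int]:
    # an item shared by several profiles targets the mean of their centers;
    # a segment-level common factor (the rater's global impression of the
    # segment) shifts every item together, planting the inter-item
    # correlation that gives the instrument its internal consistency
    targets: dict[str, list[float]] = {}
    for p_idx, profile in enumerate(PROFILES):
        for item in item_map.items[profile]:
            targets.setdefault(item, []).append(center[p_idx])
    halo = rng.normal(0, shared_sd)
    return {item: int(np.clip(np.round(np.mean(t) + halo
                                       + rng.normal(0, noise_sd)), 1, 5))
            for item, t in sorted(targets.items())}


def generate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`SimulationConfig`.

    Per patient: the initial state is drawn from the stationary
    distribution of the planted transition matrix and a first-order chain
    run for the patient's session count.  Each session receives 4–7
    segments with activity types drawn from the half-specific rates (at
    least one play segment is forced); the longest play segment carries the
    state-conditional profile emission.  Byte-identical output for a given
    ``master_seed``.
    """
    cfg = config or SimulationConfig()
    root = np.random.default_rng(cfg.master_seed)
    patient_seeds = root.integers(0, 2 ** 31 - 1, size=cfg.n_patients + 1)

    segments: list[SegmentRating] = []
    profile_rows: list[dict] = []
    true_states: list[StateSequence] = []
    outcomes: list[OutcomeRecord] = []

    for p in range(cfg.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        pid = f"P{p + 1:02d}"
        if isinstance(cfg.sessions_per_patient, tuple):
            lo, hi = cfg.sessions_per_patient
            n_sessions = int(rng.integers(lo, hi + 1))
        else:
            n_sessions = int(cfg.sessions_per_patient)
        chain = _simulate_chain(rng, cfg.transition_matrix, n_sessions)
        true_states.append(StateSequence(pid, tuple(int(s) for s in chain),
                                         cfg.n_states))
        half_cut = n_sessions // 2

        for sess in range(1, n_sessions + 1):
            half = "first" if sess <= half_cut else "second"
            rates = cfg.activity_rates[half]
            acts = list(rng.choice(list(rates), p=list(rates.values()),
                                   size=int(rng.integers(
                                       cfg.segments_per_session[0],
                                       cfg.segments_per_session[1] + 1))))
            if "play" not in acts:
                acts[int(rng.integers(0, len(acts)))] = "play"
            durations = rng.uniform(1.0, 10.0, size=len(acts))
            play_idx = [i for i, a in enumerate(acts) if a == "play"]
            longest = play_idx[int(np.argmax(durations[play_idx]))]
            state = int(chain[sess - 1])
            center = cfg.state_centers.centers[state - 1]

            for i, act in enumerate(acts):
                item_scores: dict[str, int] = {}
                if act == "play" and cfg.item_emission == "item_level":
                    item_scores = _emit_items(rng, center, DEFAULT_ITEM_MAP,
                                              cfg.item_noise_sd,
                                              cfg.item_shared_sd)
                segments.append(SegmentRating(
                    patient_id=pid, session_index=sess, segment_index=i + 1,
                    activity_type=act, item_scores=item_scores,
                    duration=float(durations[i]),
                ))
                if i == longest:
                    emitted = np.clip(
                        center + rng.normal(0, cfg.profile_noise_sd,
                                            size=len(PROFILES)), 1.0, 5.0)
                    profile_rows.append({
                        "patient_id": pid, "session_index": sess,
                        "segment_index": i + 1, "true_state": state,
                        **{prof: float(emitted[j])
                           for j, prof in enumerate(PROFILES)},
                    })

        for instrument, (pre_m, post_m, sd, se, direction) in sorted(
                cfg.outcome_effect.items()):
            outcomes.append(OutcomeRecord(
                pid, instrument,
                float(np.round(rng.normal(pre_m, sd), 1)),
                float(np.round(rng.normal(post_m, sd), 1)),
                se, direction))

    profiles = pd.DataFrame(profile_rows)
    if cfg.item_emission == "item_level":
        # profile scores follow from the emitted integer item ratings
        from .scoring import score_profiles
        by_key = {(s.patient_id, s.session_index, s.segment_index): s
                  for s in segments}
        for idx, row in profiles.iterrows():
            seg = by_key[(row["patient_id"], row["session_index"],
                          row["segment_index"])]
            ps = score_profiles(seg)
            for prof in PROFILES:
                profiles.at[idx, prof] = getattr(ps, prof)
    return SyntheticCohort(segments, profiles, true_states, outcomes, cfg)


def generate_profile_series(n_segments: int = 1000,
                            coupling: float = 1.0,
                            noise_sd: float = 0.3,
                            adaptive_loading: float = 0.4,
                            engagement_dys_loading: float = 0.55,
                            dys_loading: float = 0.45,
                            seed: int = 0,
                            clip: bool = False) -> pd.DataFrame:
    """Profile-score series with the planted correlation-sign structure.

    A two-factor model: an adaptive factor g loads positively on Adaptive
    and Engagement; a dysfunction factor h loads positively on Inhibited,
    Impulsive and Disorganized and negatively on Engagement.  ``coupling``
    scales all loadings (0 → independent noise); with ``adaptive_loading=0``
    and ``noise_sd=0`` Engagement and Disorganized become exactly
    anticorrelated.  Scores are left unclipped by default so planted
    correlations are exact in the degenerate cases; pass ``clip=True`` to
    bound them to [1, 5].
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(size=n_segments)
    h = rng.normal(size=n_segments)
    eps = rng.normal(scale=1.0, size=(n_segments, len(PROFILES)))
    a = coupling * adaptive_loading
    b = coupling * engagement_dys_loading
    c = coupling * dys_loading
    means = {"engagement": 3.7, "adaptive": 3.0, "inhibited": 2.0,
             "impulsive": 2.1, "disorganized": 1.85}
    cols = {
        "engagement": means["engagement"] + a * g - b * h,
        "adaptive": means["adaptive"] + a * g,
        "inhibited": means["inhibited"] + c * h,
        "impulsive": means["impulsive"] + c * h,
        "disorganized": means["disorganized"] + c * h,
    }
    df = pd.DataFrame({p: cols[p] + noise_sd * eps[:, i]
                       for i, p in enumerate(PROFILES)})
    if clip:
        df = df.clip(1.0, 5.0)
    return df.loc[:, list(PROFILES)]
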