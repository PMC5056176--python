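"""First-order Markov dynamics over play states.

Pooled single-step transition counts across patients (never across a
patient boundary), row-normalised percentage matrices, identification of
the dominant reciprocal oscillation ("attractor" pair), and the ergodicity
diagnostic: whether the number of transitions between two states scales
with the composite of their marginal frequencies, independently of how far
apart the states lie in profile space.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .core import ClusterCenters, StateSequence, register_report_type

logger = logging.getLogger(__name__)


@register_report_type
@dataclass(frozen=True, eq=False)
class TransitionMatrix:
    """Pooled transition counts and row-stochastic percentages.

    ``counts[i, j]`` is the number of single-step transitions from state
    i+1 to state j+1 pooled over sequences; ``percentages`` (once
    populated) is 100 × the row-normalised counts, with all-NaN rows where
    a state was never left.
    """

    n_states: int
    counts: np.ndarray
    percentages: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (self.n_states, self.n_states) or (c < 0).any():
            raise ValueError("counts must be a K×K non-negative integer matrix")
        object.__setattr__(self, "counts", c)
        if self.percentages is not None:
            object.__setattr__(self, "percentages",
                               np.asarray(self.percentages, dtype=float))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        if self.n_states != other.n_states or not np.array_equal(self.counts,
                                                                 other.counts):
            return False
        if (self.percentages is None) != (other.percentages is None):
            return False
        return self.percentages is None or np.array_equal(
            self.percentages, other.percentages, equal_nan=True)

    def to_dict(self) -> dict:
        return {"n_states": self.n_states,
                "counts": self.counts.tolist(),
                "percentages": None if self.percentages is None
                else [[None if np.isnan(v) else v for v in row]
                      for row in self.percentages]}

    @classmethod
    def from_dict(cls, d) -> "TransitionMatrix":
        perc = d.get("percentages")
        if perc is not None:
            perc = np.array([[np.nan if v is None else v for v in row]
                             for row in perc], dtype=float)
        return cls(int(d["n_states"]), np.asarray(d["counts"], dtype=int), perc)


def transition_counts(sequences: Sequence[StateSequence]) -> TransitionMatrix:
    """Pool single-step transition counts over per-patient sequences.

    Transitions are counted within each patient only — the last state of
    one patient and the first of the next are never paired — so the total
    equals Σ (len − 1) over sequences.
    """
    if not sequences:
        raise ValueError("no sequences given")
    ks = {s.n_states for s in sequences}
    if len(ks) != 1:
        raise ValueError(f"sequences disagree on the number of states: {ks}")
    k = ks.pop()
    counts = np.zeros((k, k), dtype=int)
    for seq in sequences:
        arr = np.asarray(seq.states) - 1
        np.add.at(counts, (arr[:-1], arr[1:]), 1)
    return TransitionMatrix(k, counts)


def transition_percentages(matrix: TransitionMatrix) -> TransitionMatrix:
    """Row-normalise counts to percentages (rows summing to 100).

    Rows whose state was never left become all-NaN and are flagged with a
    warning.
    """
    totals = matrix.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        perc = 100.0 * matrix.counts / totals[:, None]
    empty = totals == 0
    if empty.any():
        logger.warning("state(s) %s never left: percentage rows undefined",
                       [int(i) + 1 for i in np.flatnonzero(empty)])
        perc[empty] = np.nan
    return TransitionMatrix(matrix.n_states, matrix.counts, perc)


@register_report_type
@dataclass(frozen=True)
class Attractor:
    """The reciprocal state oscillation dominating the transition matrix.

    ``pairs`` holds every unordered pair {a, b} (a < b) maximising
    N_ab + N_ba (more than one on ties); ``n_transitions`` that maximal
    count and ``share`` its fraction of all pooled transitions.
    """

    pairs: tuple[tuple[int, int], ...]
    n_transitions: int
    share: float

    @property
    def pair(self) -> tuple[int, int]:
        """The (single) maximal pair; raises if tied."""
        if len(self.pairs) != 1:
            raise ValueError(f"attractor tied between pairs {self.pairs}")
        return self.pairs[0]

    def to_dict(self) -> dict:
        return {"pairs": [list(p) for p in self.pairs],
                "n_transitions": self.n_transitions, "share": self.share}

    @classmethod
    def from_dict(cls, d) -> "Attractor":
        return cls(tuple(tuple(p) for p in d["pairs"]),
                   int(d["n_transitions"]), float(d["share"]))


def find_attractor(matrix: TransitionMatrix) -> Attractor:
    """Find the unordered state pair with the most reciprocal transitions."""
    k = matrix.n_states
    best, pairs = -1, []
    for a, b in itertools.combinations(range(k), 2):
        t = int(matrix.counts[a, b] + matrix.counts[b, a])
        if t > best:
            best, pairs = t, [(a + 1, b + 1)]
        elif t == best:
            pairs.append((a + 1, b + 1))
    if len(pairs) > 1:
        logger.warning("attractor tied between pairs %s", pairs)
    total = matrix.total_transitions
    return Attractor(tuple(pairs), best, best / total if total else float("nan"))


@register_report_type
@dataclass(frozen=True, eq=False)
class ErgodicityResult:
    """Transition-count vs composite-frequency scaling diagnostic.

    One row per ordered state pair: the transition count N_ij, the marginal
    state frequencies f_i and f_j, their composite c_ij, and the Euclidean
    distance d_ij between the cluster centers in profile space.  ``r`` is
    the Pearson correlation of N_ij with c_ij over those rows and
    ``r_partial`` the same with the linear effect of d_ij removed.  High r
    with r_partial ≈ r means transitions scale with state frequency
    regardless of profile distance — every state is reachable from every
    other (the system is ergodic in the loose dynamical sense).
    """

    table: pd.DataFrame = field(repr=False)
    r: float
    r_partial: float
    composite_rule: str
    include_diagonal: bool

    def to_dict(self) -> dict:
        return {"table": self.table.to_dict(orient="list"),
                "r": self.r, "r_partial": self.r_partial,
                "composite_rule": self.composite_rule,
                "include_diagonal": self.include_diagonal}

    @classmethod
    def from_dict(cls, d) -> "ErgodicityResult":
        return cls(pd.DataFrame(d["table"]), float(d["r"]),
                   float(d["r_partial"]), d["composite_rule"],
                   bool(d["include_diagonal"]))


def _partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    r_xy = pearsonr(x, y).statistic
    r_xz = pearsonr(x, z).statistic
    r_yz = pearsonr(y, z).statistic
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / denom)


def state_frequencies(sequences: Sequence[StateSequence]) -> np.ndarray:
    """Relative frequency of each state over all pooled occurrences."""
    ks = {s.n_states for s in sequences}
    if len(ks) != 1:
        raise ValueError("sequences disagree on the number of states")
    k = ks.pop()
    counts = np.zeros(k)
    for seq in sequences:
        np.add.at(counts, np.asarray(seq.states) - 1, 1)
    return counts / counts.sum()


def ergodicity_analysis(matrix: TransitionMatrix, centers: ClusterCenters,
                        sequences: Sequence[StateSequence] | None = None,
                        composite_rule: str = "product",
                        include_diagonal: bool = False) -> ErgodicityResult:
    """Correlate transition counts with composite state frequencies.

    Marginal frequencies come from all pooled state occurrences when
    ``sequences`` is given, otherwise from the matrix row totals.  The
    composite of a pair defaults to the product f_i·f_j (the expected
    transition share under independence); ``composite_rule='sum'`` is a
    sensitivity alternative.  Distances are Euclidean between cluster
    centers over the five profile coordinates.  With fewer than three
    states the partial correlation is undefined (NaN, flagged).
    """
    if matrix.n_states != centers.n_states:
        raise ValueError("matrix and centers disagree on the number of states")
    if composite_rule not in ("product", "sum"):
        raise ValueError(f"unknown composite rule {composite_rule!r}")
    k = matrix.n_states
    if sequences is not None:
        freq = state_frequencies(sequences)
    else:
        totals = matrix.row_totals.astype(float)
        freq = totals / totals.sum()
    dist = cdist(centers.centers, centers.centers)

    rows = []
    for i in range(k):
        for j in range(k):
            if i == j and not include_diagonal:
                continue
            c = freq[i] * freq[j] if composite_rule == "product" else freq[i] + freq[j]
            rows.append({"from": i + 1, "to": j + 1,
                         "n_transitions": int(matrix.counts[i, j]),
                         "freq_i": freq[i], "freq_j": freq[j],
                         "composite": c, "distance": dist[i, j]})
    table = pd.DataFrame(rows)

    n = table["n_transitions"].to_numpy(dtype=float)
    comp = table["composite"].to_numpy()
    if np.ptp(comp) == 0 or np.ptp(n) == 0:
        logger.warning("composite frequency or transition counts constant "
                       "across pairs: correlation undefined")
        r = r_partial = float("nan")
    else:
        r = float(pearsonr(n, comp).statistic)
        if k < 3:
            logger.warning("fewer than 3 states: partial correlation undefined")
            r_partial = float("nan")
        else:
            r_partial = _partial_corr(n, comp, table["distance"].to_numpy())
    return ErgodicityResult(table, r, r_partial, composite_rule,
                            include_diagonal)
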