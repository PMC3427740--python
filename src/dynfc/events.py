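"""Event-interval detection on a time-varying graph sequence.

Successive graphs are compared with a node-wise l-infinity distance

    d_{t,t+1}(i) = max_k | G_{t+1}(i, k) - G_t(i, k) |,

which highlights the maximum change in a node's connectivity, and the graph
distance is the node average D_{t,t+1} = (1/N) sum_i d_{t,t+1}(i).

Boundaries are detected by adaptive thresholding: with a trailing moving
window of delta distances, mu_t and sigma_t are the window mean and
(population) standard deviation, and transition (t, t+1) is flagged when

    | D_{t,t+1} - mu_t | >= max(2 sigma_t, floor).

The absolute floor (default 1e-12) handles the degenerate sigma_t = 0 case:
an exactly constant history produces no spurious flags, while a genuine
step on a constant history is still detected.  The window does not reset at
detected boundaries, and no detection is attempted for the first delta
transitions (warm-up), so the first interval always starts at the first
graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import GraphSequence

__all__ = [
    "DistanceSeries",
    "Interval",
    "EventIntervals",
    "node_distance",
    "graph_distance",
    "distance_series",
    "default_delta",
    "detect_boundaries",
    "segment",
    "interval_sample_counts",
]

SIGMA_FLOOR = 1e-12


@dataclass
class DistanceSeries:
    """Node and mean distances between successive graphs (length T-1)."""

    node_dist: np.ndarray  # [(T-1) x N]
    mean_dist: np.ndarray  # [T-1]
    time_axis: np.ndarray | None = None  # ms of transition midpoints, optional


@dataclass
class Interval:
    """One event interval: inclusive 0-based graph indices and ms span."""

    start_idx: int
    end_idx: int
    start_ms: float
    end_ms: float

    @property
    def n_graphs(self) -> int:
        """M, the number of graphs composing the interval."""
        return self.end_idx - self.start_idx + 1


@dataclass
class EventIntervals:
    """A partition of graph indices 0..T-1 into event intervals.

    ``boundaries`` lists the flagged transitions as 0-based indices s,
    meaning the change between graphs s and s+1; each ends an interval at s.
    """

    boundaries: list[int]
    intervals: list[Interval]
    n_times: int

    def __post_init__(self) -> None:
        total = sum(iv.n_graphs for iv in self.intervals)
        if total != self.n_times:
            raise ValueError("intervals do not partition the graph sequence")


def node_distance(G_t: np.ndarray, G_t1: np.ndarray) -> np.ndarray:
    """l-infinity change of each node's connectivity row between two graphs."""
    G_t = np.asarray(G_t, dtype=float)
    G_t1 = np.asarray(G_t1, dtype=float)
    if G_t.shape != G_t1.shape or G_t.ndim != 2 or G_t.shape[0] != G_t.shape[1]:
        raise ValueError("graph slices must be square and of equal shape")
    return np.max(np.abs(G_t1 - G_t), axis=1)


def graph_distance(node_dist: np.ndarray) -> float:
    """Average node distance D = (1/N) sum_i d(i)."""
    return float(np.mean(np.asarray(node_dist, dtype=float)))


def distance_series(seq: GraphSequence) -> DistanceSeries:
    """Distances between each pair of successive graphs in a sequence."""
    A = seq.adjacency
    if A.shape[0] < 2:
        raise ValueError("need at least two graphs")
    diffs = np.abs(A[1:] - A[:-1])  # [(T-1) x N x N]
    nd = diffs.max(axis=2)
    md = nd.mean(axis=1)
    ta = None
    if seq.time_axis is not None:
        ta = 0.5 * (seq.time_axis[1:] + seq.time_axis[:-1])
    return DistanceSeries(node_dist=nd, mean_dist=md, time_axis=ta)


def default_delta(n_times: int, fraction: float = 0.025) -> int:
    """Moving-window length as a fraction of the epoch's sample count.

    2.5% of T = 256 samples gives delta = 6; at least 2 is enforced so a
    standard deviation is defined.
    """
    return max(2, round(fraction * n_times))


def detect_boundaries(
    mean_dist: np.ndarray,
    delta: int,
    sigma_floor: float = SIGMA_FLOOR,
    min_interval_length: int = 1,
    time_axis: np.ndarray | None = None,
    edge_guard: int = 0,
) -> EventIntervals:
    """Adaptive-threshold change detection on the graph-distance series.

    Parameters
    ----------
    mean_dist
        D_{t,t+1} for t = 0..T-2 (length T-1).
    delta
        Trailing window length (>= 2); transitions with fewer than delta
        preceding distances are warm-up and never flagged.
    sigma_floor
        Absolute detection floor guarding the sigma_t = 0 degenerate case.
    min_interval_length
        Minimum number of graphs per interval; flags that would create a
        shorter interval are suppressed (default 1 = no suppression).
    time_axis
        Optional graph times in ms (length T) used for interval spans;
        defaults to the sample index.
    edge_guard
        Number of transitions at the end of the series excluded from
        flagging (analytic-signal conversion corrupts phase estimates at
        epoch edges); 0 disables the guard.
    """
    D = np.asarray(mean_dist, dtype=float)
    if delta < 2:
        raise ValueError("delta must be >= 2")
    if D.size < delta + 1:
        raise ValueError(
            f"distance series of length {D.size} too short for delta={delta}"
        )
    T = D.size + 1
    if time_axis is None:
        time_axis = np.arange(T, dtype=float)
    else:
        time_axis = np.asarray(time_axis, dtype=float)
        if time_axis.size != T:
            raise ValueError("time_axis must have length T = len(mean_dist) + 1")

    flags: list[int] = []
    last_start = 0
    stop = D.size - max(0, int(edge_guard))
    for s in range(delta, stop):
        win = D[s - delta : s]
        mu = win.mean()
        sigma = win.std()  # population form, 1/delta
        if abs(D[s] - mu) >= max(2.0 * sigma, sigma_floor):
            # flag at transition (s, s+1): interval ends at s, next starts s+1
            if (s - last_start + 1) >= min_interval_length:
                flags.append(s)
                last_start = s + 1

    starts = [0] + [s + 1 for s in flags]
    ends = [s for s in flags] + [T - 1]
    intervals = [
        Interval(
            start_idx=a,
            end_idx=b,
            start_ms=float(time_axis[a]),
            end_ms=float(time_axis[b]),
        )
        for a, b in zip(starts, ends)
    ]
    return EventIntervals(boundaries=flags, intervals=intervals, n_times=T)


def segment(
    seq: GraphSequence,
    delta: int | None = None,
    delta_fraction: float = 0.025,
    sigma_floor: float = SIGMA_FLOOR,
    min_interval_length: int = 1,
    edge_guard: int = 0,
) -> tuple[DistanceSeries, EventIntervals]:
    """Distance series plus detected event intervals for a graph sequence."""
    ds = distance_series(seq)
    if delta is None:
        delta = default_delta(seq.n_times, delta_fraction)
    ev = detect_boundaries(
        ds.mean_dist,
        delta=delta,
        sigma_floor=sigma_floor,
        min_interval_length=min_interval_length,
        time_axis=seq.time_axis,
        edge_guard=edge_guard,
    )
    return ds, ev


def interval_sample_counts(
    intervals_ms: list[tuple[float, float]],
    t_start_ms: float,
    t_end_ms: float,
    n_samples: int,
) -> list[int]:
    """Number of grid samples falling in each millisecond-labelled interval.

    The n samples are treated as centres of n equal-width bins spanning the
    epoch [t_start_ms, t_end_ms]; a sample belongs to an interval [a, b]
    when a <= centre <= b.  This is the convention under which a 2 s epoch
    of 256 samples at 128 Hz partitions into published interval tables
    whose boundaries are printed in integer milliseconds.

    Raises ``ValueError`` if the intervals do not assign every sample to
    exactly one interval.
    """
    width = (t_end_ms - t_start_ms) / n_samples
    centres = t_start_ms + (np.arange(n_samples) + 0.5) * width
    hits = np.zeros(n_samples, dtype=int)
    counts = []
    for a, b in intervals_ms:
        inside = (centres >= a) & (centres <= b)
        counts.append(int(inside.sum()))
        hits += inside
    if not np.all(hits == 1):
        bad = np.flatnonzero(hits != 1)
        raise ValueError(
            f"intervals do not partition the grid: samples {bad.tolist()} "
            f"covered {hits[bad].tolist()} times"
        )
    return counts
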