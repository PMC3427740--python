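"""Time-varying weighted connectivity graphs from band-averaged PLV.

The graph at time t has edge weights

    G_t(i, j) = (1/W) sum_{w_a <= w <= w_b} PLV_ij(t, w),

the mean synchrony over the W frequency bins falling inside the analysis
band (endpoints inclusive on the discrete bin grid; the EEG theta band is
4-8 Hz).  Each slice is symmetric with zero diagonal and weights in [0, 1].

A group-level sequence is the elementwise mean over subjects' sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synchrony import PLVTensor

__all__ = ["GraphSequence", "MeanGraphSequence", "band_average", "mean_over_subjects"]


@dataclass
class GraphSequence:
    """T symmetric N x N weighted graphs with a shared time axis."""

    adjacency: np.ndarray  # [T x N x N]
    time_axis: np.ndarray  # ms, length T
    band: tuple[float, float] | None = None  # Hz
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.adjacency.ndim != 3 or self.adjacency.shape[1] != self.adjacency.shape[2]:
            raise ValueError("adjacency must be T x N x N")
        if self.adjacency.shape[0] != self.time_axis.size:
            raise ValueError("time axis length does not match number of graphs")

    @property
    def n_times(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        """Check symmetry, zero diagonal and the [0, 1] weight range."""
        A = self.adjacency
        if not np.allclose(A, np.transpose(A, (0, 2, 1)), atol=atol):
            raise ValueError("graph slices are not symmetric")
        if not np.allclose(A[:, np.arange(A.shape[1]), np.arange(A.shape[1])], 0):
            raise ValueError("graph diagonals are not zero")
        if np.nanmin(A) < -atol or np.nanmax(A) > 1 + atol:
            raise ValueError("weights outside [0, 1]")


@dataclass
class MeanGraphSequence(GraphSequence):
    """Subject-averaged graph sequence."""

    n_subjects: int = 1


def band_average(plv: PLVTensor, band: tuple[float, float]) -> GraphSequence:
    """Average the PLV tensor over a frequency band into a graph sequence.

    Band endpoints are inclusive on the discrete frequency-bin grid; at
    least one bin must fall inside the band.
    """
    w_a, w_b = band
    if w_a > w_b:
        raise ValueError(f"band must satisfy w_a <= w_b, got {band}")
    freqs = np.asarray(plv.freq_axis, dtype=float)
    in_band = (freqs >= w_a) & (freqs <= w_b)
    if not in_band.any():
        raise ValueError(
            f"no frequency bins inside band {band}; bin grid spans "
            f"{freqs.min():g}..{freqs.max():g} Hz with spacing "
            f"{freqs[1] - freqs[0] if freqs.size > 1 else 0:g} Hz"
        )
    banded = plv.values[:, :, in_band].mean(axis=2)  # [pairs x T]

    N = plv.n_channels
    T = banded.shape[1]
    A = np.zeros((T, N, N))
    for p, (i, j) in enumerate(plv.pair_index):
        A[:, i, j] = banded[p]
        A[:, j, i] = banded[p]
    return GraphSequence(adjacency=A, time_axis=np.asarray(plv.time_axis), band=(w_a, w_b))


def mean_over_subjects(sequences: list[GraphSequence]) -> MeanGraphSequence:
    """Elementwise mean of per-subject graph sequences (same T, N, time axis)."""
    if len(sequences) == 0:
        raise ValueError("need at least one subject sequence")
    ref = sequences[0]
    for q, s in enumerate(sequences[1:], start=1):
        if s.adjacency.shape != ref.adjacency.shape or not np.allclose(
            s.time_axis, ref.time_axis
        ):
            raise ValueError(
                f"subject {s.subject_id or q} has mismatching shape/time axis"
            )
    mean = np.mean([s.adjacency for s in sequences], axis=0)
    return MeanGraphSequence(
        adjacency=mean,
        time_axis=ref.time_axis.copy(),
        band=ref.band,
        n_subjects=len(sequences),
    )
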