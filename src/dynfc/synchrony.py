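"""Cross-trial phase-locking value (PLV) from time-frequency phase estimates.

For channels i, j and trial k, the time-frequency phase difference is

    Phi_ij^k(t, w) = arg[ C_i/|C_i| * conj(C_j)/|C_j| ],

and the PLV across K trials is the resultant length of the unit phasors

    PLV_ij(t, w) = (1/K) | sum_k exp(j Phi_ij^k(t, w)) |  in [0, 1].

PLV is 1 iff the per-trial phase differences at a bin agree modulo 2pi, and
for independent uniform phases its expectation is the Rayleigh floor
sqrt(pi / (4K)).

Bins whose distribution magnitude falls below the magnitude floor in a trial
carry no phase information; they are excluded from that bin's sum and K is
reduced accordingly (a warning flags the reduction).  ``strict=True`` turns
any masked bin into an error instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .tfd import DEFAULT_FLOOR_REL, DEFAULT_KERNEL_SIGMA, TFDMatrix, rid_rihaczek

__all__ = ["PairPhaseDiff", "PLVTensor", "phase_difference", "plv", "plv_tensor", "rayleigh_floor"]


@dataclass
class PairPhaseDiff:
    """Per-trial time-frequency phase difference for one channel pair."""

    values: np.ndarray  # radians, wrapped to (-pi, pi], [L_t x L_f]
    valid_mask: np.ndarray
    pair: tuple[int, int] | None = None


@dataclass
class PLVTensor:
    """PLV over (pair, time, frequency) with the pair enumeration i < j."""

    values: np.ndarray  # [n_pairs x L_t x L_f], in [0, 1]
    pair_index: list[tuple[int, int]]
    n_trials: int
    time_axis: np.ndarray = None
    freq_axis: np.ndarray = None
    n_valid: np.ndarray | None = None  # effective trial count per bin

    @property
    def n_channels(self) -> int:
        return max(j for _, j in self.pair_index) + 1


def rayleigh_floor(n_trials: int) -> float:
    """Expected PLV of K independent uniform phases: sqrt(pi/(4K))."""
    return float(np.sqrt(np.pi / (4.0 * n_trials)))


def _unit_phasor(C: np.ndarray, floor_rel: float) -> tuple[np.ndarray, np.ndarray]:
    mag = np.abs(C)
    floor = floor_rel * mag.max() if mag.size else 0.0
    valid = mag >= floor
    if floor == 0:
        valid &= mag > 0
    U = np.zeros_like(C)
    np.divide(C, mag, out=U, where=valid)
    return U, valid


def phase_difference(
    tfd_i: TFDMatrix,
    tfd_j: TFDMatrix,
    magnitude_floor_rel: float = DEFAULT_FLOOR_REL,
    pair: tuple[int, int] | None = None,
) -> PairPhaseDiff:
    """Phase difference arg[(C_i/|C_i|)(C_j*/|C_j|)] on a shared grid.

    Raises ``ValueError`` if the two distributions are not on the same
    (time, frequency) grid.  Bins below either channel's magnitude floor are
    masked invalid (value 0).
    """
    if not tfd_i.same_grid(tfd_j):
        raise ValueError("time-frequency grids of the two channels do not match")
    Ui, vi = _unit_phasor(tfd_i.values, magnitude_floor_rel)
    Uj, vj = _unit_phasor(tfd_j.values, magnitude_floor_rel)
    valid = vi & vj
    vals = np.where(valid, np.angle(Ui * np.conj(Uj)), 0.0)
    return PairPhaseDiff(values=vals, valid_mask=valid, pair=pair)


def plv(diffs: list[PairPhaseDiff], strict: bool = False) -> np.ndarray:
    """PLV across trials from per-trial phase differences.

    Masked bins are excluded per bin with the trial count reduced; bins with
    no valid trial at all are NaN.  ``strict=True`` raises on any masked bin.
    """
    if len(diffs) == 0:
        raise ValueError("need at least one trial")
    shape = diffs[0].values.shape
    phasor_sum = np.zeros(shape, dtype=np.complex128)
    count = np.zeros(shape, dtype=np.int64)
    for d in diffs:
        if d.values.shape != shape:
            raise ValueError("inconsistent grids across trials")
        phasor_sum += np.exp(1j * d.values) * d.valid_mask
        count += d.valid_mask
    n_masked = int(np.sum(count < len(diffs)))
    if n_masked:
        if strict:
            raise ValueError(f"{n_masked} bins are masked in at least one trial")
        warnings.warn(
            f"{n_masked} bins excluded masked trials; trial count reduced there"
        )
    out = np.full(shape, np.nan)
    np.divide(np.abs(phasor_sum), count, out=out, where=count > 0)
    return out


def plv_tensor(
    epochs: np.ndarray,
    fs: float,
    t0: float = 0.0,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    magnitude_floor_rel: float = DEFAULT_FLOOR_REL,
    pairs: list[tuple[int, int]] | None = None,
) -> PLVTensor:
    """Pairwise cross-trial PLV for a trials x channels x samples array.

    Computes each channel's RID-Rihaczek distribution per trial, forms unit
    phasors, and accumulates the pair products over trials, so memory scales
    with pairs rather than trials.  Pairs are enumerated with i < j; the
    graph layer mirrors them symmetrically.
    """
    epochs = np.asarray(epochs)
    if epochs.ndim != 3:
        raise ValueError("epochs must be trials x channels x samples")
    K, N, L = epochs.shape
    if K < 1 or N < 2:
        raise ValueError("need at least 1 trial and 2 channels")
    if pairs is None:
        pairs = list(itertools.combinations(range(N), 2))
    else:
        pairs = [tuple(p) for p in pairs]
        if any(not (0 <= i < j < N) for i, j in pairs):
            raise ValueError("pairs must satisfy 0 <= i < j < n_channels")

    grid = rid_rihaczek(epochs[0, 0], sigma=kernel_sigma, fs=fs, t0=t0)
    Lt, Lf = grid.values.shape
    phasor_sum = np.zeros((len(pairs), Lt, Lf), dtype=np.complex128)
    count = np.zeros((len(pairs), Lt, Lf), dtype=np.int32)

    for k in range(K):
        U = np.empty((N, Lt, Lf), dtype=np.complex128)
        V = np.empty((N, Lt, Lf), dtype=bool)
        for c in range(N):
            tf = rid_rihaczek(epochs[k, c], sigma=kernel_sigma, fs=fs, t0=t0)
            U[c], V[c] = _unit_phasor(tf.values, magnitude_floor_rel)
        for p, (i, j) in enumerate(pairs):
            phasor_sum[p] += U[i] * np.conj(U[j])
            count[p] += V[i] & V[j]

    values = np.full(phasor_sum.shape, np.nan)
    np.divide(np.abs(phasor_sum), count, out=values, where=count > 0)
    return PLVTensor(
        values=values,
        pair_index=pairs,
        n_trials=K,
        time_axis=grid.time_axis,
        freq_axis=grid.freq_axis,
        n_valid=count,
    )
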