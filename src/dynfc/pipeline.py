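"""End-to-end orchestration: epochs -> PLV -> graphs -> intervals -> key graphs.

The stages mirror the method: RID-Rihaczek PLV per channel pair, band
averaging into a time-varying graph sequence, adaptive-threshold event
segmentation on successive-graph distances, PCA key-graph summarization per
interval, and surrogate edge-significance testing.  ``run_pipeline`` runs
everything from an epochs array (or a synthetic config); ``summarize_graphs``
enters at the graph-sequence stage for precomputed sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io
from .events import DistanceSeries, EventIntervals, default_delta, segment
from .graphs import GraphSequence, band_average
from .inference import (
    DEFAULT_LEVELS,
    DEFAULT_N_SURROGATES,
    SignificanceMask,
    edge_significance,
    make_surrogates,
)
from .keygraph import DEFAULT_XI, KeyGraph, key_graph
from .synchrony import plv_tensor
from .tfd import DEFAULT_FLOOR_REL, DEFAULT_KERNEL_SIGMA

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize_graphs"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, defaulting to the study values:
    theta band 4-8 Hz, xi = 90% retained energy, 2000 surrogates, significance
    levels 0.01 and 0.001, window fraction 2.5% of the sample count."""

    kernel_sigma: float = DEFAULT_KERNEL_SIGMA
    magnitude_floor_rel: float = DEFAULT_FLOOR_REL
    band: tuple[float, float] = (4.0, 8.0)
    delta: int | None = None  # samples; None -> delta_fraction of T
    delta_fraction: float = 0.025
    min_interval_length: int = 1
    sigma_floor: float = 1e-12  # absolute detection floor on |D - mu|
    edge_guard: int = 0  # trailing transitions excluded from detection
    xi: float = DEFAULT_XI
    n_surrogates: int = DEFAULT_N_SURROGATES
    surrogate_mode: str = "per_slice"
    pooled: bool = True
    levels: tuple[float, float] = DEFAULT_LEVELS
    seed: int = 0

    def validate(self, fs: float | None = None) -> None:
        if not self.kernel_sigma > 0:
            raise ValueError("kernel_sigma must be positive")
        if not 0 < self.xi <= 100:
            raise ValueError("xi must be in (0, 100]")
        if self.band[0] > self.band[1]:
            raise ValueError("band must be (low, high)")
        if fs is not None and self.band[1] > fs / 2:
            raise ValueError(
                f"band {self.band} exceeds the Nyquist frequency {fs / 2:g} Hz"
            )
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.surrogate_mode not in ("per_slice", "fixed_permutation"):
            raise ValueError(f"unknown surrogate mode {self.surrogate_mode!r}")


@dataclass
class PipelineResult:
    """Artifacts of a full (or partial) pipeline run."""

    config: PipelineConfig
    graphs: GraphSequence
    distances: DistanceSeries
    intervals: EventIntervals
    key_graphs: list[KeyGraph]
    significance: list[SignificanceMask]
    plv: object | None = None  # PLVTensor when the run started from epochs

    def save(self, outdir) -> None:
        """Write all stage outputs plus a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.plv is not None:
            io.save_plv_h5(outdir / "pipeline.h5", self.plv)
        io.save_graphs_h5(outdir / "pipeline.h5", self.graphs)
        io.distance_series_csv(
            outdir / "distance_series.csv",
            self.distances.mean_dist,
            self.distances.time_axis
            if self.distances.time_axis is not None
            else np.arange(self.distances.mean_dist.size, dtype=float),
        )
        io.intervals_json(outdir / "intervals.json", self.intervals)
        for i, (kg, sig) in enumerate(zip(self.key_graphs, self.significance)):
            io.keygraph_csv(
                outdir / f"keygraph_{i}.csv", kg, outdir / f"keygraph_{i}_edges.tsv"
            )
            if sig is not None:
                io.significance_tsv(outdir / f"significance_{i}.tsv", kg, sig)
        manifest = asdict(self.config)
        manifest["n_intervals"] = len(self.intervals.intervals)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def summarize_graphs(
    seq: GraphSequence,
    config: PipelineConfig | None = None,
    significance: bool = True,
) -> PipelineResult:
    """Segment a graph sequence and summarize each interval with a key graph."""
    cfg = config or PipelineConfig()
    cfg.validate()
    distances, intervals = segment(
        seq,
        delta=cfg.delta,
        delta_fraction=cfg.delta_fraction,
        sigma_floor=cfg.sigma_floor,
        min_interval_length=cfg.min_interval_length,
        edge_guard=cfg.edge_guard,
    )
    key_graphs: list[KeyGraph] = []
    masks: list[SignificanceMask | None] = []
    for i, iv in enumerate(intervals.intervals):
        slices = seq.adjacency[iv.start_idx : iv.end_idx + 1]
        kg = key_graph(slices, xi=cfg.xi, interval=iv)
        key_graphs.append(kg)
        if significance:
            ens = make_surrogates(
                slices,
                n=cfg.n_surrogates,
                mode=cfg.surrogate_mode,
                seed=cfg.seed + i,
                xi=cfg.xi,
            )
            masks.append(
                edge_significance(kg, ens, pooled=cfg.pooled, levels=cfg.levels)
            )
        else:
            masks.append(None)
    return PipelineResult(
        config=cfg,
        graphs=seq,
        distances=distances,
        intervals=intervals,
        key_graphs=key_graphs,
        significance=masks,
    )


def run_pipeline(
    epochs: np.ndarray,
    fs: float,
    t0: float = 0.0,
    config: PipelineConfig | None = None,
    significance: bool = True,
) -> PipelineResult:
    """Full pipeline from a trials x channels x samples epochs array."""
    cfg = config or PipelineConfig()
    cfg.validate(fs=fs)
    plv = plv_tensor(
        epochs,
        fs=fs,
        t0=t0,
        kernel_sigma=cfg.kernel_sigma,
        magnitude_floor_rel=cfg.magnitude_floor_rel,
    )
    seq = band_average(plv, cfg.band)
    result = summarize_graphs(seq, cfg, significance=significance)
    result.plv = plv
    return result
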