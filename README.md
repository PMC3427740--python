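# dynfc — time-varying functional connectivity by time-frequency phase synchrony

`dynfc` summarizes how a functional network — e.g. theta-band EEG
connectivity around a response event — evolves over time.  Static
connectivity analyses average over an entire epoch and hide the formation
and dissolution of functional links; `dynfc` instead builds a *sequence* of
weighted graphs at the full temporal resolution of the recording, segments
the sequence into event intervals, and reduces each interval to a single
representative "key graph" whose edges are significance-tested against
surrogate networks.

It is a library first (NumPy/SciPy stack, importable API, narrative scripts
in `examples/`), with a thin `dynfc` command-line wrapper for running the
pipeline on stored epoch files.

## Method

Given multitrial epochs `x_i^k(t)` (trial k, channel i):

1. **Time-frequency phase.**  Each channel's complex energy distribution is
   the reduced-interference Rihaczek (RID-Rihaczek) distribution
   `C(t,ω) = ∬ exp(−(θτ)²/σ) exp(jθτ/2) A(θ,τ) e^{−j(θt+τω)} dτ dθ`,
   where `A(θ,τ)` is the ambiguity function and `exp(−(θτ)²/σ)` is a
   Choi-Williams kernel that suppresses cross-terms of multicomponent
   signals (σ = ∞ recovers the plain Rihaczek
   `(1/2π) x(t) X*(ω) e^{−jωt}`).  The phase estimate is
   `Φ(t,ω) = arg[C/|C|]`.
2. **Phase-locking value.**  For each channel pair, the cross-trial PLV
   `PLV_{ij}(t,ω) = (1/K) |Σ_k exp(jΦ_{ij}^k(t,ω))| ∈ [0,1]`
   measures how consistent the phase difference is across K trials.
3. **Time-varying graphs.**  Averaging PLV over a frequency band (theta,
   4–8 Hz, by default) gives a symmetric weighted graph `G_t` per sample;
   subject-level sequences can be averaged into a group sequence.
4. **Event intervals.**  Successive graphs are compared with the node-wise
   l∞ distance `d_{t,t+1}(i) = max_k |G_{t+1}(i,k) − G_t(i,k)|` and its node
   average `D_{t,t+1}`; boundaries are flagged where `|D − μ_t| ≥ 2σ_t`
   relative to a trailing moving window (length δ ≈ 2.5% of the epoch's
   samples).
5. **Key graphs.**  The M graphs of an interval are vectorized (upper
   triangle), decomposed by PCA, and projected onto the leading eigenvectors
   retaining ξ = 90% of the energy; the devectorized mean reconstruction is
   the interval's key graph.
6. **Significance.**  Each key graph is compared against an ensemble of
   surrogate networks built by reshuffling edge weights (2000 by default),
   yielding empirical per-edge p-values at the P < 0.01 and P < 0.001
   levels, and node strength can be compared across intervals with Welch's
   t-test.

Because no public dataset accompanies the method, the package ships a
synthetic-data generator (`dynfc.synthgen`) that plants known coupling
regimes in stochastic narrowband oscillations, so every stage is testable
against ground truth (see `docs/methods.md` for the signal model and its
rationale).

## Worked example

```bash
python examples/03_event_segmentation.py
```

prints, for the default planted dataset (16 channels, 50 trials, 128 Hz,
regime changes at samples 86 and 171):

```
distance series: baseline mean 0.029, max 0.127
planted regime starts (sample index): [86, 171]
flagged transitions: [84, 85, 169, 170]
  interval   0.. 84  (-1000.0.. -343.8 ms, M = 85)
  interval  85.. 85  ( -335.9.. -335.9 ms, M = 1)
  interval  86..169  ( -328.1..  320.3 ms, M = 84)
  interval 170..170  (  328.1..  328.1 ms, M = 1)
  interval 171..255  (  335.9..  992.2 ms, M = 85)
```

The distance series is quiet inside regimes (≈ 0.03) and jumps by 4× at the
planted transitions, which the adaptive threshold flags within one sample of
the truth.  `examples/04_key_graphs_significance.py` then shows that every
interval's key graph ranks exactly the planted within-cluster pairs on top
(rank agreement 1.00 for all five intervals at seed 1).

The other examples cover the time-frequency phase estimator (`01`), PLV and
band-averaged graphs (`02`), and the full artifact-writing pipeline (`05`).
The same stages are available from the shell:

```bash
dynfc synth --seed 1 --out epochs.h5
dynfc run --epochs epochs.h5 --band 4 8 --outdir out/
```

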