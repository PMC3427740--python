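"""Cross-trial PLV and band-averaged connectivity graphs.

Generates a small synthetic dataset with two coupled clusters of channels,
computes the pairwise PLV tensor with the Rihaczek phase estimator, and
band-averages it into a time-varying weighted graph sequence.  Coupled
pairs lock near exp(-jitter_sd^2) at the carrier bin; uncoupled pairs stay
near the Rayleigh floor sqrt(pi/(4K)).
"""

import numpy as np

import dynfc

cfg = dynfc.SynthConfig(
    n_channels=6,
    n_trials=30,
    regimes=[dynfc.Regime(-1000.0, 1000.0, [[0, 1, 2], [3, 4, 5]], 6.0)],
    sync_mod_depth=0.0,
    common_mix=0.0,
    phase_diffusion=0.3,
    seed=7,
)
ds = dynfc.generate(cfg)
tensor = dynfc.plv_tensor(ds.epochs, fs=cfg.fs, t0=cfg.t_start_ms, kernel_sigma=np.inf)

carrier = np.argmin(np.abs(tensor.freq_axis - 6.0))
within = set(ds.within_cluster_pairs[0])
win = np.array([p in within for p in tensor.pair_index])
mid = tensor.values.shape[1] // 2
print(f"PLV at the 6 Hz bin, mid-epoch:")
print(f"  coupled pairs   {tensor.values[win, mid, carrier].mean():.3f}  "
      f"(jitter-limited level exp(-sd^2) = {ds.expected_within_plv:.3f})")
print(f"  uncoupled pairs {tensor.values[~win, mid, carrier].mean():.3f}  "
      f"(Rayleigh floor for K={cfg.n_trials}: {ds.expected_cross_plv:.3f})")

seq = dynfc.band_average(tensor, (4.0, 8.0))
G = seq.adjacency[mid]
print(f"band-averaged 4-8 Hz edge weights at mid-epoch: "
      f"coupled {G[0, 1]:.3f}, uncoupled {G[0, 3]:.3f}")
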