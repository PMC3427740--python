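"""Time-frequency phase of a two-tone signal: Rihaczek vs RID-Rihaczek.

Builds a 64-sample signal containing two complex exponentials, computes the
plain Rihaczek distribution (kernel sigma = inf) and the reduced-interference
version (sigma = 0.01), and shows how the Choi-Williams kernel removes the
cross-term beating on the auto-term frequency columns.
"""

import numpy as np

from dynfc import ambiguity, phase, rid_rihaczek

L = 64
t = np.arange(L)
x = np.exp(2j * np.pi * 8 * t / L) + np.exp(2j * np.pi * 24 * t / L)

A = ambiguity(x)
print(f"ambiguity at the origin A(0,0) = {A[0, 0].real:.1f}  "
      f"(signal energy = {np.sum(np.abs(x) ** 2):.1f})")

plain = rid_rihaczek(x, sigma=np.inf)
rid = rid_rihaczek(x, sigma=0.01)

col = 8  # auto-term column of the first tone
std_plain = np.abs(plain.values[:, col]).std()
std_rid = np.abs(rid.values[:, col]).std()
print(f"|C| beating (std over time) at the 1st auto column: "
      f"plain Rihaczek {std_plain:.3f}, RID-Rihaczek {std_rid:.3f}")
print("-> the kernel suppresses the interference between the two tones")

pm = phase(rid)
print(f"phase at the auto column is flat in time: "
      f"std = {pm.values[:, col].std():.4f} rad")
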