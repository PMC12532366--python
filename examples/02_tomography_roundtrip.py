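"""Coincidence-count tomography of a decohered photon pair.

Simulates one 16-projection coincidence measurement of a Werner state at
the source operating point (7650 Hz pairs, 80 kHz singles, 10 ns window,
1 s per projection), reconstructs the density matrix by maximum
likelihood and compares the recovered metrics with the ground truth.
"""

import numpy as np

from entsense import (
    SourceParams,
    make_bell_state,
    make_werner_state,
    fidelity,
    mle_reconstruct,
    simulate_tomography_set,
    summarize,
)

p_true = 0.85
source = SourceParams()
rho_true = make_werner_state(p_true)

ts = simulate_tomography_set(rho_true, source, rng=7)
print("counts per projection (signal x idler in HVDR order):")
print(np.array(ts.counts, dtype=int).reshape(4, 4))

rho_hat = mle_reconstruct(ts)
s = summarize(rho_hat)
print(f"\ntrue Werner p          : {p_true:.3f}")
print(f"estimated Werner p     : {s.werner_p_hat:.3f}")
print(f"fidelity to |Phi+>     : {fidelity(rho_hat, make_bell_state('phi_plus')):.4f}")
print(f"tangle / linear entropy: {s.tangle:.4f} / {s.linear_entropy:.4f}")
print(f"deviation from Werner path: {s.ts_deviation:+.4f}")
print("\nThe ~64 accidental counts per projection (10 ns x (80 kHz)^2) are")
print("visible in settings where the true projection probability is zero.")
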