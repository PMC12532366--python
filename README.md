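# entsense

Quantum-sensing analysis of scattering tissue via entanglement
decoherence. The package provides a tested, reusable implementation of
the full analysis chain used to distinguish transgenic mouse-model
brain tissue (amyloidosis and tauopathy) from control tissue with
polarization-entangled photon pairs — with a synthetic-data generator
standing in for the optical bench and the animal samples.

## The science in brief

A spontaneous parametric down-conversion source emits photon pairs in a
Bell state |Φ⁺⟩ = (|HH⟩ + |VV⟩)/√2. One photon of each pair traverses a
thin tissue section; scattering decoheres the pair into a Werner state

ρ_W(p) = p |Φ⁺⟩⟨Φ⁺| + (1 − p) I/4,  p ∈ [0, 1],

interpolating between the intact Bell state (p = 1) and white noise
(p = 0). The state is reconstructed by quantum state tomography from 16
polarization-projective coincidence measurements (analyzers in the
H/V/D/A/R/L eigenstates), and characterized by

- **concurrence** C = max(0, λ₁ − λ₂ − λ₃ − λ₄), with λᵢ the descending
  square roots of the eigenvalues of ρ(σ_y⊗σ_y)ρ*(σ_y⊗σ_y),
- **tangle** T = C² (degree of entanglement),
- **linear entropy** S_L = (4/3)(1 − Tr ρ²) (degree of mixture),
- a **Werner-probability estimate** p̂ = (4F − 1)/3 from the fidelity F
  to the prepared Bell state.

Along the Werner family, T(p) = max(0, (3p−1)/2)² and S_L(p) = 1 − p²
trace a curve in the (T, S) plane; measured spots fall on it when
scattering decoheres without loss. Transgenic tissue preserves
entanglement better than control tissue, so a linear SVM on
(T, S_L) separates the groups; leave-one-replicate-out evaluation,
variance-gated group tests with effect sizes, and correlation of
entanglement with fluorescence-quantified plaque burden complete the
analysis.

## Worked example

Simulate one noisy tomography of a Werner state at the source operating
point (7650 Hz pair rate, 80 kHz singles, 10 ns coincidence window, 1 s
per projection) and reconstruct it:

```bash
$ python examples/02_tomography_roundtrip.py
counts per projection (signal x idler in HVDR order):
[[3624  367 1950 2018]
 [ 340 3557 1977 1937]
 [1991 1972 3624 1976]
 [2002 1960 2025  338]]

true Werner p          : 0.850
estimated Werner p     : 0.831
fidelity to |Phi+>     : 0.8735
tangle / linear entropy: 0.5586 / 0.3084
deviation from Werner path: -0.0000
```

The HH/VV/DD counts near 3825 reflect the perfect correlations of
|Φ⁺⟩; the ~340 counts in HV/VH/RR settings are the accidental
background (10 ns × (80 kHz)² ≈ 64 Hz) plus the residual decoherence of
p = 0.85. The reconstruction lands on the Werner path (deviation ≈ 0)
and recovers p to ~0.02 at these count rates.

The other examples cover the Werner decoherence path
(`01_werner_decoherence.py`), leave-one-replicate-out classification of
a synthetic cohort with every metric equal to 1
(`03_cohort_classification.py`), variance-gated statistics with Hedges'
g / Glass's Δ effect sizes in the ±6–9 range
(`04_group_statistics.py`), and plaque quantification with the
burden–entanglement correlation signs (r > 0 for tangle, r < 0 for
linear entropy) (`05_plaque_quantification.py`).

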