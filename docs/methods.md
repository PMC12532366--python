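# Methods

## Model and scope

The package models the polarization degree of freedom of photon pairs
only. A pair is prepared in a Bell state (default |Φ⁺⟩ with zero
relative phase); transmission through tissue is a Werner channel,
ρ_W(p) = p|ϕ⟩⟨ϕ| + (1−p)I/4. This is the standard description of
scattering-induced depolarization that degrades entanglement without
rotating the state; measured tissue data fall on the Werner (T, S)
path, which motivates the pure-Werner default. No spatial beam
propagation, spectra or phase-matching physics is simulated. A unitary
off-curve perturbation is not generated by default; off-curve behavior
can be probed by feeding arbitrary density matrices to the simulator.

Conventions fixed once and used everywhere:

- basis order (HH, HV, VH, VV), signal qubit first;
- circular polarization R = (H − iV)/√2, L = (H + iV)/√2;
- Bell phases |Φ±⟩ = (|HH⟩ ± e^{iφ}|VV⟩)/√2, |Ψ±⟩ analogous on
  {HV, VH}.

## Coincidence-count simulation

Expected counts per projection k are
μ_k = R_cc · t · Tr(ρ P_sₖ⊗P_iₖ) + R_acc · t with R_cc = 7650 Hz the
total coincidence rate (summed over a complete analyzer basis — the
maximum single projection, e.g. HH for |Φ⁺⟩, is then ≈ 3825 counts at
t = 1 s), R_acc = τ·S_s·S_i the accidental rate (64 Hz at the default
10 ns window and 80 kHz singles), and counts drawn Poisson. Singles
rates are treated as setting-independent. The accidental background is
**added** in simulation and **not subtracted** during reconstruction by
default; subtraction is available as a flag and is used where an
unbiased comparison against ground truth is the point (e.g. the
Werner-p recovery checks).

Cohorts mirror the animal-study layout: per (strain, region) group, 4
replicates × 5 spots × 5 repeated tomographies. Each spot draws its
Werner p from a truncated normal on [0, 1] via the inverse CDF (so a
fixed seed reproduces the draw exactly); all repeats at a spot share
that p and differ only by counting noise. The default group means —
transgenic 0.95, control 0.75, SD 0.02 — are a fixture convention
chosen to reproduce the qualitative ordering of the study (transgenic
closer to p = 1; a glass-slide reference would sit near 0.99), not
measured constants. What passing tests on this generator show is that
the *analysis chain* behaves correctly under realistic counting noise;
they cannot show that real tissue separates this way.

## Tomography

Any 16-setting list over {H,V,D,A,R,L}² is accepted and validated only
through the rank of the flattened projector design matrix (rank 16 =
informationally complete), so user-supplied designs work. The default
list is {H,V,D,R}⊗{H,V,D,R}.

*Linear inversion* solves counts_k = Tr(ρ̃P_k) exactly, Hermitizes and
normalizes the trace; it reproduces noiseless data to machine precision
but may be non-PSD under noise.

*Maximum likelihood* (default) optimizes the Poisson likelihood over
the physical manifold ρ = T†T/Tr(T†T), T lower-triangular (16 real
parameters). The overall scale of T is left free and absorbs the total
flux, which profiles the rate nuisance exactly and removes the scale
degeneracy of the normalized parameterization. Optimization is L-BFGS
with an analytic Wirtinger gradient, initialized from the
eigenvalue-clipped linear inversion; convergence at relative
log-likelihood change < 1e-12 or gradient norm < 1e-8, with
non-convergence raising an error that carries the best iterate. A
variance-weighted Gaussian likelihood is available as a flag.
Eigenvalue clipping uses ascending-eigenvalue-then-index ordering for
deterministic behavior under degeneracy.

## Entanglement metrics

Concurrence clips spin-flip eigenvalues below 1e-12 to zero before the
square root (numerical floor far below count-noise scale). The 4/3
prefactor of linear entropy normalizes S_L to [0, 1] for two qubits and
is kept exactly. The Werner-probability estimator inverts the
closed-form fidelity, p̂ = clip((4F−1)/3, 0, 1), against the *declared*
prepared Bell state; it is exact on the Werner family and robust
off-family, and a nearest-Bell option maximizes F over the four
zero-phase Bell states instead. The signed deviation from the Werner
path is the minimal Euclidean distance in the (T, S) plane (grid search
refined by bounded minimization, endpoint-safe), positive above the
curve.

### Statistical limit of the tangle estimate

At the default rates (≈ 3.1×10⁴ pairs per tomography), the Cramér–Rao
bound for tangle under the unconstrained 15-parameter state model is
≈ 0.039 at p = 0.9; the MLE reaches ≈ 0.042, i.e. it is essentially
efficient, and averaged over p ∈ [0.7, 1] the within-spot SD of tangle
is ≈ 0.03 (linear entropy ≈ 0.02). A Werner-constrained estimator
would reach ≈ 0.011. Reported reproducibility figures are therefore
honest properties of full-state tomography at these count rates; a
lower tangle scatter requires either more counts or the constrained
estimator.

## Classification

Units of classification are individual measurements (one row per
repeated tomography), not spot means (aggregation available as a flag
through the feature table). Features are bounded in [0, 1] and used
unscaled. The SVM is linear-kernel (scikit-learn SVC); C is selected on
the training split only, by stratified 5-fold cross-validation over the
grid {0.01, 0.1, 1, 10, 100}, ties broken toward the smallest C (larger
margin). Leave-one-replicate-out holds out the transgenic and control
animals with the same replicate index together, so each split's test
data is never seen in training or model selection. Sensitivity is the
recall of the transgenic class, specificity that of the control class.
Undefined ratios (0/0) are reported as NaN with a warning, never
silently zero. The 1D-vs-2D comparison evaluates {p̂} and {T, S_L} on
identical splits.

## Group statistics

The variance pretest is the median-centered Brown–Forsythe variant of
Levene's test (robust at small n; mean-centering configurable) at
α = 0.05. Equal variances → two-sided Student t; unequal → two-sided
Mann–Whitney U with midrank ties. This gate pairs unequal variances
with the rank test by design, mirroring the analysis protocol this
package implements, even though Welch's t would be the textbook
alternative. Effect sizes: pooled-SD Cohen's d with the Hedges
small-sample correction J = 1 − 3/(4·df−1), reported as g (equal
variances); Glass's Δ with the control-group SD (unequal). The sign
convention is (mean_control − mean_transgenic)/SD: negative when
transgenic exceeds control, matching the reported negative CIs for
transgenic-vs-control comparisons. CIs: noncentral-t inversion for d/g
(each CI labeled with its estimator); seeded 10,000-resample percentile
bootstrap for Δ. Paired region comparisons use the exact-distribution
Wilcoxon signed-rank test (zero differences dropped). Degenerate inputs
(both groups constant and identical) are declared equal-variance with
p = 1 and zero effect. No multiple-testing correction is applied.

## Image quantification

Single-channel images only. The threshold criterion is between-class
variance maximization (Otsu), implemented exactly over sorted sample
values rather than a binned histogram, which makes the mask invariant
under positive affine intensity rescaling; a fixed threshold can be
supplied. Smoothing is interpreted as opening-then-closing with a disk
of equal radius (default 2 px) after hole filling. Components are
8-connected; components under 10 px are dropped as speckle (both
configurable). Area percentage is dimensionless (µm/px scale carried as
metadata only). The synthetic generator places disjoint disks with a
gap wide enough (8 px default) that closing cannot merge neighbors;
overlapping disks are merged in the ground truth and flagged. Default
rendering gives SNR 10 ((600 − 100)/50); recovery checks run at SNR 5.

## Pipeline, sizes and reproducibility

All randomness flows from one global seed through numpy SeedSequence
streams; every stage writes its outputs (with `<file>.meta.json`
provenance sidecars carrying seed, config hash and package version)
before the next begins, and reruns are byte-identical. Problem sizes
in the shipped checks — 200-measurement cohorts, 20 spots × 5 repeats
for reproducibility, 200 seeded plaque images, 1000-state tomography
round trips, 5000-replication type-I simulations — were chosen as the
smallest sizes at which the corresponding statistical statements are
stable across seeds.

## Known limitations

- The generator produces exactly Werner-type decoherence; detector
  drift, polarization-dependent loss and analyzer miscalibration are
  not modeled.
- The tangle reproducibility floor discussed above is intrinsic to
  unconstrained 16-projection tomography at the default rates.
- Plaque images are far simpler than confocal data (no background
  structure, uniform plaque brightness); segmentation performance on
  them bounds only the algorithmic correctness, not real-image
  accuracy.
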