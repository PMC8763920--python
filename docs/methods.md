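# Methods

## The kinetic Zimm–Bragg generator

The synthetic system stands in for all-atom trajectory ensembles of short
stapled peptides. Each of the `n_res` residues is binary (helix/coil) and a
configuration's statistical weight is the Zimm–Bragg measure — `σ` per
helical run, `s` per helical residue — times a staple bonus `J` whenever
both crosslinked residues are helical. The staple model is deliberately
minimal: a multiplicative reward on doubly-helical configurations is the
simplest coupling that reproduces the two experimental signatures of
stapling, higher equilibrium helicity and slower folding relaxation, without
pretending to model linker strain or chirality effects.

Dynamics are single-residue Glauber flips: a uniformly chosen residue flips
with heat-bath probability `w'/(w + w')`. The move set changes one residue
at a time, so helix nucleation (creating a run, weight σ) is the
rate-limiting step and the kinetics are two-basin for small σ. The
`flip_attempts_per_frame` parameter sets how much the chain decorrelates
between saved frames and plays the role of the saving interval of an MD
engine.

Default study conditions, fixed once for all tests and the acceptance
script:

| parameter | value | why |
| --- | --- | --- |
| `n_res` | 15 | typical stapled-peptide length (an i,i+4 stapled 15-mer) |
| `staple` | (5, 9) | central i,i+4 turn |
| `σ` | 0.01 | nucleation-limited, clean two-basin kinetics |
| `s` | 1.1 | coil-leaning baseline (unstapled ⟨h⟩ ≈ 0.34) |
| `J` | 2.0 | stapled ⟨h⟩ ≈ 0.42, relaxation 14.7 → 17.3 ns |
| `flip_attempts_per_frame` | 15 | one sweep per saved frame |
| `frame_dt` | 0.5 ns | nominal saving interval |

With these values the staple raises helicity *and* slows relaxation. That
sign pattern is not automatic: if the baseline already favours helix
(s well above 1), deepening the helix basin shortens the relaxation time
because folding flux dominates. The coil-leaning baseline was chosen — using
the exact oracles below, before any pipeline test was run — so that
unfolding flux dominates and the staple slows the slowest mode, the regime
the reference experiments describe.

### Exact oracles

* **Equilibrium**: per-residue helix probabilities by exhaustive
  enumeration of all 2^n configurations (n ≤ 20), or by a forward/backward
  transfer-matrix pass for longer unstapled chains. A stapled chain beyond
  the enumeration limit is refused: the staple couples non-adjacent
  residues and breaks the nearest-neighbour factorization.
* **Kinetics**: the exact relaxation time of the sampler comes from the
  second eigenvalue of the full 2^n-state single-flip kernel, symmetrized
  with the known stationary distribution and solved sparsely (n ≤ 18;
  n = 15 takes ≈ 0.5 s). One saved frame is `m` attempts, so
  t = −frame_dt / (m·ln λ₂).

These oracles are what the MSM pipeline's recovered timescale and helicity
are judged against.

## Coordinate construction and secondary structure

Backbone coordinates are built per frame by torsion-driven (NeRF) placement
with ideal bond lengths/angles; helical residues use (φ, ψ) = (−57°, −47°),
coil residues draw uniformly from a β/PPII-like basin
(φ ∈ [−180°, −60°], ψ ∈ [60°, 180°]) so the two basins are geometrically
separated. The amide H sits 1.0 Å from N along the negative bisector of its
two heavy-atom neighbours — the standard construction when hydrogens are
absent. Isotropic Gaussian jitter (default 0.1 Å in the pipeline) emulates
thermal noise.

Helix assignment uses the classic electrostatic hydrogen-bond criterion,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol for the
i → i+4 bond, and labels residues helical when they lie in a stretch
supported by two consecutive such bonds. Only the α-helix class is
implemented — 3₁₀/π helices, sheets and turns are all "coil" here — and both
the cutoff and the run-length requirement are configurable.

**A definitional caveat used deliberately:** the H-bond rule cannot label
chain termini or helical runs shorter than ~5 residues as helical, so its
expectation is systematically below the Zimm–Bragg per-residue helicity.
Parameter-recovery checks therefore weight the generator's own helix/coil
labels with the MSM stationary distribution (pipeline default
`use_dssp_labels=False`); the geometric assigner is validated separately on
ideal-helix and extended-chain oracles and can be switched on for
profile shape studies.

## The MSM pipeline

Features are all pairwise Cα/Cβ distances (435 for the 15-mer), pooled
within trajectories only. tICA solves C(Δt)α = λ(C(0)+εI)α with Δt = 5 ns,
four components kept, symmetrized C(Δt), and ridge ε = 1e−6·tr(C0)/n by
default — the symmetrization and regularization are required for a
well-posed symmetric problem and are exposed in the model object.
Projections are plain unit-variance components (no kinetic-map scaling).

Clustering is greedy farthest-point k-centers (k = 50 by default; first
center at index `seed mod n`, ties to the lowest index), a deterministic
2-approximation of the minimax radius. MSMs use sliding-window counts,
ergodic trimming to the strongly connected component carrying the most
counts, and the literal maximum-likelihood row normalization
T_ij = c_ij/Σc_ij; a reversible variant (row-normalized symmetrized counts)
is available behind a flag. Implied timescales are reported as
t_i = −τ/ln λ_i (positive for 0 < λ < 1); non-positive or complex
eigenvalues have no defined relaxation time at that lag and are excluded.
The final-model lag default is 25 ns, inside the plateau of the lag scan
for the default system (relaxation ≈ 15–17 ns); lag tables over 1–100 ns
equivalents support plateau inspection.

GMRQ cross-validation uses trajectory-level folds (5, or leave-one-out
below 5 trajectories); the test score is the summed generalized Rayleigh
quotient trace[(VᵀC0V)⁻¹(VᵀC(τ)V)] of the leading `n_timescales + 1` train
eigenvectors under the held-out correlation matrices, evaluated on the
shared train/test state support; folds that cannot cover the eigenvector
support are skipped with a warning.

Uncertainty comes from a trajectory bootstrap: each of n = 5 replicates
redraws the trajectory list with replacement and refits the MSM and every
downstream quantity; replicates that lose connectivity are redrawn (at most
10 times, logged). Reported errors are the SEM across replicates.

## Problem sizes

The reference study is 50 trajectories × 2200 saved frames with the first
100 ns (200 frames) discarded, i.e. 100 000 analysed frames per system —
roughly 6 000 relaxation times of aggregate data, which the package
processes in about a minute. At that size the recovered slowest timescale
sits within ~5% of the exact eigensolve value and the MSM-weighted helicity
within about one bootstrap SEM of the transfer-matrix value. The paired
staple-versus-no-staple comparison uses 30 trajectories per arm, a size
chosen by a power check against the exact kinetics oracle so that the
18%-timescale and 0.08-helicity staple effects are resolved reliably.

## CD quantification

MRE normalization and the %helicity formula follow the standard
instrument-analysis chain; the random-coil baseline is [θ]₀ = 2220 − 53T
(T in °C). The theoretical helix maximum uses the finite-length form
[θ]_max = θ_∞(1 − x/n) with θ_∞ = −39 500 deg·cm²·dmol⁻¹ and x = 2.57;
these constants are configuration, not claims — different labs use slightly
different values, and both are exposed as arguments. %helicity is returned
unclamped so that noisy spectra outside [0, 100] are visible to the caller.
A synthetic-spectrum constructor inverts the chain exactly and serves as
the round-trip oracle.

## Uptake statistics

The module consumes per-cell mean-intensity tables (segmentation is
upstream and out of scope). Lognormal fits are maximum-likelihood (mean and
population SD of log intensities); Grubbs outlier removal runs iteratively
to exhaustion on the log scale by default — consistent with the lognormal
intensity model — with a raw-scale flag and a `max_iter` cap; Welch's
t-statistic and Satterthwaite df are computed per formula with p-values
from the t-distribution (sample SDs). Fold changes divide group means by
the reference mean (reference ≡ 1) with the group's own SEM propagated
through the division. The whole chain is invariant to global intensity
rescaling.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on —
two-basin interconversion, nucleation-limited kinetics, a staple-dependent
equilibrium shift, many independent finite trajectories, an equilibration
transient — so passing tests demonstrate that the estimators recover known
equilibria and timescales from trajectory data of realistic shape. It does
not emulate force-field physics, solvent, side-chain chemistry, linker
strain or chirality, so agreement here says nothing about the accuracy of
any particular molecular mechanics model; for real trajectories the
coordinate ingestion path (multi-model PDB) and every stage downstream of
featurization apply unchanged.

## Numerical choices and degenerate inputs

* Glauber acceptance uses a ±40 clip on the log-weight difference to avoid
  overflow; enumeration weights are computed in log space and shifted by
  the maximum before exponentiation.
* tICA sign convention: the largest-magnitude loading of each component is
  positive. Ties in k-centers (farthest point, nearest center) resolve to
  the lowest index; `np.argmax`/`np.argmin` provide this deterministically.
* A count matrix whose strongly connected components are all
  transition-free has no stationary distribution and is rejected rather
  than patched.
* Grubbs critical values clamp to the (n−1)/√n bound when the t-quantile
  overflows (α → 0), so the no-rejection limit is exact.
* Constant data: Freedman–Diaconis width 0 is returned with a degenerate
  flag; zero-variance Welch comparisons return t = 0, p = 1 when means
  agree.
* All stage seeds derive from the global seed and integer stage
  coordinates via `SeedSequence`, so reruns are bit-identical and stages
  can be recomputed in isolation.

## Known limitations

* The staple bonus is a single multiplicative weight; it cannot represent
  staple-induced *de*stabilization (J < 1 is rejected) or position-dependent
  nucleation effects.
* Only α-helix assignment is implemented; mixed secondary structure in
  real trajectories would be labelled coil.
* The non-reversible ML estimator does not enforce detailed balance;
  eigenvalues can come out complex on sparse data (they are excluded from
  timescales rather than symmetrized away). Use the reversible flag when
  detailed balance is a modelling assumption.
* GMRQ scores on very small folds can be undefined (skipped with a
  warning), so the selected state count is only as good as the fold
  coverage.
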