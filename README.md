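# helixmsm

Markov state model (MSM) analysis of helix–coil conformational dynamics in
side-chain–stapled peptides, together with the circular-dichroism (CD)
helicity quantification and confocal-uptake statistics that accompany such
studies, and a kinetic Zimm–Bragg trajectory generator with exact
equilibrium and kinetic oracles for validating the whole chain.

## Who this is for

Peptide designers crosslink residues at *i*, *i*+4 (or *i*, *i*+7) positions
to lock short peptides into their bioactive α-helical conformation. Judging
whether a staple works means estimating equilibrium helicity and
folding/unfolding kinetics from ensembles of trajectories, and comparing the
prediction with CD-measured %helicity and with cell-uptake quantification.
This package implements that analysis stack end to end on synthetic
trajectories whose ground truth is known exactly, so every stage can be
checked against an oracle rather than against another black box.

## The models

**Generator.** Each residue is helical (1) or coil (0). A configuration `x`
has Zimm–Bragg weight

    w(x) = σ^(runs) · s^(helical residues) · J^[both stapled residues helical]

with nucleation weight σ, propagation weight s, and a staple bonus J ≥ 1.
Single-residue Glauber flips (acceptance `w'/(w+w')`) satisfy detailed
balance, so trajectories sample the exact Zimm–Bragg equilibrium with
nucleation-limited two-basin kinetics. Exact oracles: per-residue
equilibrium helicity by transfer matrix / enumeration, and the exact
relaxation time of the flip chain by a sparse eigensolve of the full
2^n-state kernel.

**Analysis.** Frames are built into backbone coordinates (N, Cα, C, O, Cβ,
amide H), featurized as all pairwise Cα/Cβ distances (a 15-mer gives
30·29/2 = 435 features), reduced by tICA — maximize ⟨α|C(Δt)|α⟩ subject to
⟨α|C(0)|α⟩ = 1, i.e. the generalized eigenproblem C(Δt)α = λ(C(0)+εI)α —
then clustered by greedy k-centers into discrete states. MSM transition
matrices T(τ) are maximum-likelihood estimates from sliding transition
counts on the largest strongly connected state set; implied timescales are
t_i = −τ/ln λ_i, stationary populations π come from the leading left
eigenvector, and ensemble helicity is the MSM-weighted state average
⟨h⟩ = Σ_i π_i h_i. GMRQ cross-validation selects the state count, and a
trajectory bootstrap (n = 5 by default) provides SEMs.

**CD and uptake.** Mean residue ellipticity [θ]_λ = [θ]_obs/(10·l·C·n),
%helicity = 100·([θ]_222 − [θ]_0)/([θ]_max − [θ]_0) with coil baseline
[θ]_0 = 2220 − 53T and finite-length helix maximum
[θ]_max = θ_∞(1 − x/n). Uptake tables get Freedman–Diaconis binning,
lognormal ML fits, iterative two-sided Grubbs outlier removal (log scale),
Welch t-tests and fold normalization against a reference stapling chemistry.

## Worked example

```python
from helixmsm import (HelixCoilParams, simulate_helix_coil,
                      equilibrium_helicity_exact, relaxation_time_exact)
from helixmsm.pipeline import (PipelineConfig, SystemConfig,
                               analyze_state_trajectories, derive_seed)
from helixmsm.featurize import discard_equilibration
from helixmsm.msm import implied_timescales

stapled = SystemConfig(name="stapled", staple=(5, 9), staple_bonus=2.0)
cfg = PipelineConfig(systems=[stapled], seed=1, n_trajectories=50,
                     n_frames=2200, t_eq=100.0, msm_lags=[25.0],
                     msm_lag=25.0)

trajs = [discard_equilibration(
             simulate_helix_coil(stapled.helix_coil_params(), cfg.n_frames,
                                 seed=derive_seed(cfg.seed, 0, 1, i)),
             cfg.t_eq)
         for i in range(cfg.n_trajectories)]
res = analyze_state_trajectories(trajs, cfg, 0, stapled)

print("MSM slowest timescale:", implied_timescales(res["msm"], 1)[0], "ns")
print("exact relaxation time:",
      relaxation_time_exact(stapled.helix_coil_params()), "ns")
print("MSM <h>:", res["profile"].overall, "+/-", res["profile"].overall_sem)
print("exact <h>:",
      equilibrium_helicity_exact(stapled.helix_coil_params()).mean())
```

prints (seed 1):

```
MSM slowest timescale: 16.544600292825223 ns
exact relaxation time: 17.306794265553204 ns
MSM <h>: 0.41937459311111464 +/- 0.004342669030844297
exact <h>: 0.42396462335430607
```

i.e. the pipeline recovers the generator's exact folding relaxation time to
~4% and its equilibrium helicity within about one bootstrap SEM. Against the
unstapled twin (J = 1) the same run gives ⟨h⟩ = 0.342 and a slowest
timescale of 14.7 ns: the staple raises helicity and slows folding.

The same stages are available from the shell:

```
helixmsm simulate --n-res 15 --staple 5,9 --staple-bonus 2 --n-traj 10 --out states.npz
helixmsm featurize --states states.npz --teq 100 --out feats.npz
helixmsm tica --features feats.npz --lag 5 --n-components 4 --out tics.npz
helixmsm cluster --projections tics.npz --k 50 --out labels.npz
helixmsm msm --labels labels.npz --scan-lags 1,5,25,100
helixmsm run --config config.yaml --out out/
```

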