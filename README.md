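# idpensemble

Sequence-conditioned SE(3) diffusion for generating backbone conformational
ensembles of intrinsically disordered proteins (IDPs), with the training
objective and the ensemble-evaluation metrics used to judge such
generators — exercisable end-to-end on a desk CPU with synthetic ensembles.

## Who this is for

IDPs have no single native structure; their behaviour is described by a
conformational ensemble approximating the Boltzmann distribution. This
package is for computational structural biologists who want a transparent,
fully inspectable implementation of the frame-diffusion generative approach
to ensemble prediction: every component — the rotation/translation noise
kernels, the invariant-point-attention denoiser, the score-matching loss,
the reverse-SDE sampler, and the evaluation suite — is plain numpy/scipy
code with tests against independent oracles.

## The model

A chain of *n* residues is parametrized by backbone frames
`T_j = [R_j, v_j]` (rotation `R_j ∈ SO(3)`, translation `v_j ∈ R³` = the CA
position). Diffusion treats the two channels independently:

* **Rotations** follow a variance-exploding process whose perturbation
  kernel is the isotropic Gaussian on SO(3),
  `IGSO3(R_t; R_0, σ²(t))` with angle series
  `f̃(ω) = Σ_l (2l+1) e^{−l(l+1)σ²} sin((l+½)ω)/sin(ω/2)`
  and the logarithmic schedule
  `σ(t) = log(t·e^{σmax} + (T−t)·e^{σmin})`, σ ∈ [0.1, 1.5], T = 1.
* **Translations** follow a variance-preserving Ornstein–Uhlenbeck process
  on the centre-of-mass-free subspace,
  `v_t | v_0 ~ N(v_0 e^{−½∫β}, (1−e^{−∫β}) I)` with the linear schedule
  `β(t) = βmin + t(βmax−βmin)`, β ∈ [0.1, 20].

A sequence-conditioned denoiser (initialization block + stacked
IPA-transformer blocks, AlphaFold2 structure-module style) predicts the
clean frames `T̂0`; scores follow analytically from the kernels. Training
minimizes `L = L_dsm + ω₁·L_bb + ω₂·L_dist` with ω₁ = ω₂ = 0.25, where
`L_dsm` is the λ(t)-normalized score-matching error
(`λ(t) = 1/E‖∇ log p_t‖²`, so a zero prediction scores exactly 1 per
channel) and the backbone/distance-matrix MSE terms act only at small noise
(t < T/4). Ensembles are generated by integrating the reverse SDE from the
Gaussian/Haar prior (by convention 300 conformations per system).

Evaluation implements the standard IDP-ensemble metrics: **validity**
(fraction of conformations with every consecutive CA–CA distance inside
(δ_vdw, δ_bond), δ_vdw = 2·1.7 − 0.4 Å), **ε_Rg** = (⟨Rg⟩_pred −
Rg_exp)/Rg_exp, per-observable `RMSD_A = √E[(⟨A⟩_pred − ⟨A⟩_exp)²]`,
Ramachandran basin occupancies, bond/torsion distributions, Rg–RMSD
projections and k-medoids clustering.

## Worked example

`examples/04_sample_and_evaluate.py` substitutes the exact single-target
score for the network (the sampler accepts any score function) and runs
generation + evaluation end to end:

```
$ python examples/04_sample_and_evaluate.py
sampled 30 conformations; CA RMSD to target: mean 0.021 A, max 0.027 A
  -> the reverse integrator collapses the Gaussian/Haar prior onto the score's target
validity 1.00, mean Rg 5.75 A, epsilon_Rg +0.0001
Ramachandran: {'alpha': 1.0, 'beta_ppii': 0.0, 'other': 0.0}
  -> near-zero Rg error and pure alpha occupancy: the ensemble reproduces the helical target
```

The mean CA RMSD of 0.02 Å shows the reverse integrator is essentially
exact when the score is; validity 1.0 and ε_Rg ≈ 0 confirm the generated
ensemble matches the target's compactness and secondary structure. The
other examples cover the noise schedules and λ(t) normalization (`01`),
synthetic two-state ensembles and their recovered statistics (`02`), and
training a denoiser to overfit one conformation (`03`).

A thin CLI wraps the same library calls:

```bash
idpensemble fixtures --spec fixtures.yaml --out data/
idpensemble train    --data data/ --out weights.npz --preset desk --steps 2000
idpensemble sample   --fasta seq.fasta --weights weights.npz --n-conf 300 --out ens.pdb
idpensemble evaluate --ensemble ens.pdb --reference ref.pdb --exp-rg 25.0 --out report.json
```

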