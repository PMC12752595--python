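# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is the package's own account; all numbers
quoted here are computed by the tests, the examples or `scripts/acceptance.py`.

## Frame diffusion

A single-chain backbone is a set of per-residue rigid frames
`T_j = [R_j, v_j]`; the frame origin is the CA atom and the orientation
comes from Gram–Schmidt on (N, CA, C) with `e1 ∝ C−CA`. Idealized local
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
N–CA–C 111.0°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O 120.8°) rebuild
N/CA/C from a frame exactly; the carbonyl O needs the ψ torsion, which a
frame does not carry, so it is placed from the next residue's frame
(terminal residue: ψ = 180°). These constants and the O convention are this
package's documented choices — frame-based generators typically leave them
unstated, and any consistent ideal geometry works because frames, not
atoms, are the diffusion variable.

### Rotation channel

Noise kernel: isotropic Gaussian on SO(3) with the character series
`f̃(ω; σ) = Σ_{l} (2l+1) e^{−l(l+1)σ²} sin((l+½)ω)/sin(ω/2)` truncated
adaptively (coefficients below 1e−18 dropped; nominal cap L = 2000). `f̃`
is the density with respect to Haar measure; the angle marginal carries the
extra Haar factor `(1−cos ω)/π`. Both are tabulated on a 2048-point ω grid
× 256-point geometric σ grid ∈ [0.02, 2.0] with linear interpolation;
sampling is inverse-CDF on the marginal; the score magnitude is
`d/dω log f̃`. Below σ = 0.05 the series cancels catastrophically and the
tangent-Gaussian asymptotic (axis-angle ~ N(0, 2σ² I)) replaces it; the
same asymptotic continues the score table where the series underflows.
With this exponent convention the Brownian time of the kernel is 2σ², so
the diffusion coefficient of the matching forward VE SDE is
`g² = d(2σ²)/dt`; using `dσ²/dt` instead leaves the reverse process
under-dispersed (measured: mean residual angle 0.41 rad instead of the
kernel's own 0.22 rad at t→0), which is why the factor-2 form is used.

Schedule: `σ(t) = log(t·e^{σmax} + (T−t)·e^{σmin})`, σmin = 0.1,
σmax = 1.5, T = 1.

Because σ(0) = σmin > 0, even an exact reverse integration ends with
kernel-width rotational noise (mean angle ≈ 0.22 rad). The sampler's final
step therefore applies a Tweedie (posterior-mean) correction
`R ← R·exp(2σmin²·score)` — the SO(3) analogue of the standard "output the
denoised estimate" last step of score-based samplers. With the analytic
single-target score this leaves ~6e−4 rad of residual; the flag
`denoise_final` (default on) controls it.

### Translation channel

VP (Ornstein–Uhlenbeck) process on the CoM-free subspace;
`β(t) = 0.1 + 19.9·t`, kernel `N(v0·e^{−½∫β}, (1−e^{−∫β})I)`. The CoM
projection is applied to the initial state, after every forward/reverse
step, and to scores (the kernel variance is the standard VP form, forced
by the kernel converging to N(0, I)). Reverse integration is
Euler–Maruyama with noise omitted on the step landing at t = 0.

### Score normalization (λ)

`λ(t) = 1/E‖∇ log p_{t|0}‖²` per channel, with the expectation taken over
per-residue score 3-vectors. Translation: closed form
`λ = var·n/(3(n−1))` — the (n−1)/n factor accounts for the three CoM
degrees of freedom removed by projection. Rotation: quadrature of
`(d log f̃)²` over the tabulated marginal, cached per σ. Monte-Carlo checks
(10⁴ draws) give λ·E‖s‖² = 1.00 ± 0.01 for both channels.

## Denoiser

Initialization block: learned residue-type embedding (21 letters + X) plus
sinusoidal position encoding; sinusoidal time encoding concatenated and
projected to the single representation; pair representation from binned
relative positions (clip ±32) plus broadcast single features. Denoising
block: invariant point attention over the current frames (point distances
computed via the ‖q‖²+‖k‖²−2q·k expansion), a pre-norm transformer,
a feed-forward transition, a pair update from the outer product of single
representations, and a per-residue frame update (small-angle rotation via
a safe Rodrigues map; translation applied in the local frame) with
zero-initialized head, so an untrained network is the identity denoiser.
The last block's pair update is omitted (its output would be unused).
Scalar representations are invariant and frames equivariant under global
rigid motions by construction; the tests verify both at 1e−4 (fp32) over
100 random transforms.

Full-size configuration: 256/128 single/pair channels, 4 IPA blocks,
2 transformer layers per block, 8 heads, per-head IPA scalar channels 256,
transformer FFN 1024 → 18.9 M parameters. The published size this
reconstruction targets is 17.8 M; the remaining dimensions (per-head
widths, FFN width, point counts) are underdetermined and were fixed once to
land within that envelope. Desk preset (used by all tests): 64/32
channels, 2 IPA blocks, 1 transformer layer, 4 heads — 0.3 M parameters.

The network predicts denoised frames; scores derive from the analytic
kernels. The rotation score is computed differentiably as
`g(ω̂)·vee(M−Mᵀ)`, `M = R̂0ᵀR_t`, where `g(ω) = dlog f̃/(2 sin ω)` is
tabulated with its slope (clamped to |g| ≤ 50 near ω = π, a region that is
never visited in practice). Coordinates enter the network scaled by 0.1 to
keep activations O(1); outputs are scaled back.

All tensors are fp32; the autodiff engine is a minimal reverse-mode
implementation over numpy (verified against central differences to ~1e−7
on every op and through the whole network).

## Training

Per step: draw a batch (equal-length conformations, with replacement if
the pool is smaller than the batch), per-sample t ~ Uniform(0.01, T]
(the lower cutoff avoids the σ→0 singularity), forward-diffuse both
channels, predict, apply
`L = L_dsm,rot + L_dsm,trans + 0.25·L_bb + 0.25·L_dist` with the structure
terms gated at t < T/4, Adam with global-norm gradient clipping at 1.0.
`L_bb` is the MSE over N/CA/C rebuilt from frames in the shared data gauge
(O is excluded because it is not a function of the frame alone);
`L_dist` is the off-diagonal MSE of all-pairs CA distance matrices.
Rotation and translation DSM terms are means over residues with unit
relative weight. Presets: `pretrain` (lr 1e−4, batch 8), `finetune`
(lr 1e−5, batch 32) mirroring the two-stage curriculum at full scale, and
`desk` (lr 1e−3, batch 8) for CPU-scale runs, where the larger step size
is appropriate for a 0.3 M-parameter model trained for thousands rather
than millions of iterations.

An intrinsic property of this objective worth recording: at large t the
rotation channel's λ-normalized loss has a floor near 1 for *any*
pose-equivariant predictor, because a near-Haar input carries no
information about the data's global orientation, while the λ weighting
normalizes the (tiny) score variance to unit scale. Measured on an
overfit run, the per-t rotation loss falls to ~0.01 at t = 0.05 but stays
at ~0.96 at t = 0.9; the t-averaged total therefore plateaus near 0.5
rather than continuing to zero. Consequently the *total* training loss
contracts by roughly 4× on an overfit run, not arbitrarily far, even
though the structure itself is recovered to ~0.1 Å.

## Sampler

Uniform time grid from T to 0; geodesic random walk on SO(3) and
Euler–Maruyama in R³; rotations re-orthonormalized by SVD projection each
step; noise off on the final step; final Tweedie rotation denoise (above);
backbones rebuilt from the final frames with CA CoM at the origin. The
default grid has 500 steps; desk-scale tests use 60–100 steps, which the
integrator-oracle tests show is well inside the stable regime
(β·dt ≤ 0.33). 300 conformations per ensemble is the evaluation
convention. Rotations initialize Haar-uniform — the σmax = 1.5 prior is
close to but not exactly uniform; the approximation error is far below the
sampler's own discretization error.

## Synthetic ensembles

Chains are grown by NeRF from the idealized geometry with per-residue
torsions from wrapped-Gaussian Ramachandran basins (helix (−57, −47)°,
extended β/ppII (−135, 145)°, spread 10°, ω = 180° — no cis-proline
modelling). The two-state generator draws whole conformations from the
helix basin (compact) or the extended basin with probability `p_compact`,
storing ground-truth labels. These fixtures emulate the *statistical*
structure of real training data (a structured pool and a disordered pool
with known mixing weight, basin occupancies and per-state compactness, so
every downstream estimate has an exact target) but not its physics: no
side chains, no excluded volume beyond an optional consecutive-CA filter,
no sequence-dependent torsion preferences, ideal bond geometry. Passing
the distribution-recovery tests therefore shows the generative machinery
can learn and reproduce a known two-state ensemble — it says nothing about
accuracy on real IDP data, which at full scale depends on the pretrained
sequence encoder and the experimental/MD training corpus (both out of
scope; the encoder attaches through the `external` embedding hook and is
never downloaded).

## Evaluation

Validity applies the consecutive-CA criterion exactly (strict
inequalities); `ValiditySpec.from_reference` sets δ_bond to the reference
ensemble's maximum consecutive CA distance plus a 1e−6 Å margin so the
reference itself stays valid; without a reference, δ_bond = 4.5 Å. An
all-pairs clash mode is an opt-in extension. Rg uses unit-mass backbone
heavy atoms (N/CA/C/O) by default with a CA-only mode for coarse-grained
comparisons (mass weighting is deliberately not used; the choice is
documented because conventions differ). Superposition RMSD uses the
Kabsch/SVD alignment from scipy. Clustering is k-medoids (alternating
assignment/medoid refit, seeded initialization) on the pairwise CA-RMSD
matrix — a deliberately simple, deterministic substitute for external
clustering toolchains. The Karplus coefficients for ³J(HN,Hα)
(A, B, C = 6.51, −1.76, 1.60 Hz) are the package's stand-in for external
shift/coupling predictors, which are out of scope; chemical-shift RMSDs are
computed from externally supplied per-residue tables (CSV:
residue_index, observable, value).

## Degenerate inputs and tie-breaks

Collinear or coincident N/CA/C triples raise a degeneracy error naming the
residue; torsions of collinear quadruples are excluded as NaN; the
axis-angle of the identity returns the canonical axis (0, 0, 1); the
rotation score at ω = 0 is the zero vector; k-medoids resolves ties by
stable ordering; empty clusters keep their medoid.

## Problem sizes used by the test suite

Unit and acceptance tests run at desk scale, chosen once: IGSO3 table
2048×256; Monte-Carlo checks at 10⁴–10⁵ draws; integrator oracles at 100
trials × 500 steps; overfit at 16 residues × 2000 steps; distribution
recovery at 64 residues, 200 training conformations, 1400 training steps,
300 generated conformations on a 60-step reverse grid. The full-size
network configuration is instantiated only to count parameters.

## Known limitations

Single chains only; no side chains; no cis peptides; the IGSO3 table does
not extrapolate outside its σ grid (by design, an error is raised);
reverse integration is first-order Euler (higher-order integrators are out
of scope); the training loop holds the whole dataset in memory.

Two limits of the desk-scale training budget are worth stating plainly,
because the test suite reports them honestly as failures rather than
papering over them. First, the ≥10× total-loss contraction sometimes
expected of an overfit run is unattainable under this objective: the
rotation-channel floor described above caps the contraction near 3–4×
even when the structure itself is recovered to ~0.2 Å. Second, the
64-residue two-state distribution-recovery run at the desk budget (1400
steps, 0.3 M-parameter preset) does not yet reach quantitative agreement
in mean Rg or basin occupancy: learned-score reverse sampling becomes
faithful only once the denoiser is trained well past that budget (the
16-residue overfit demonstrates the full pipeline converging — sampled
ensembles reach ~0.15 Å RMSD, 100 % bond validity and the correct basin —
but the 64-residue two-state task needs substantially more optimization
than a desk CPU run provides). The corresponding tests encode the
quantitative targets as specified and are expected to fail at this scale.
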