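"""Sample an ensemble with an analytic score oracle and evaluate it.

Substitutes the exact single-target score for the network (the sampler
accepts any score function), integrates the reverse SDE, and runs the full
evaluation report on the generated ensemble -- a network-free demonstration
of the generation + evaluation pipeline.
"""

import numpy as np

from idpensemble import fixtures as fx
from idpensemble import metrics as mx
from idpensemble import r3, so3
from idpensemble import sampler as smp
from idpensemble.geometry import frames_from_backbone

target = fx.ideal_helix(12, sequence="ACDEFGHIKLMN")
frames = frames_from_backbone(target)
v0 = r3.com_project(frames.translations)
table = so3.default_table()
ssched, rsched = so3.SO3Schedule(), r3.VPSchedule()


def oracle(R, v, t):
    s_rot = so3.score_so3(R, frames.rotations[None], t, ssched, table)
    s_tr = r3.score_r3(v, v0[None], t, rsched) if t > 0 else np.zeros_like(v)
    return s_rot, s_tr


cfg = smp.SamplerConfig(n_conformations=30, n_steps=200, seed=3)
ens = smp.sample_ensemble(target.sequence, None, cfg, score_fn=oracle, table=table)
rmsds = [mx.kabsch_rmsd(c.coords_CA, target.coords_CA) for c in ens]
print(f"sampled {len(ens)} conformations; CA RMSD to target: "
      f"mean {np.mean(rmsds):.3f} A, max {np.max(rmsds):.3f} A")
print("  -> the reverse integrator collapses the Gaussian/Haar prior onto "
      "the score's target")

report = mx.evaluate_ensemble(
    ens, mx.ValiditySpec.from_reference(ens),
    rg_exp=mx.radius_of_gyration(target), n_clusters=2)
print(f"validity {report.validity:.2f}, mean Rg {report.rg_mean:.2f} A, "
      f"epsilon_Rg {report.epsilon_rg:+.4f}")
print("Ramachandran:", {k: round(v, 3) for k, v in report.ramachandran_occupancy.items()})
print("  -> near-zero Rg error and pure alpha occupancy: the ensemble "
      "reproduces the helical target")
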