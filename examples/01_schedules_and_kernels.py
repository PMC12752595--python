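"""Noise schedules and forward-kernel sanity checks.

Prints the rotation (VE, logarithmic) and translation (VP, linear-beta)
schedule endpoints, then verifies by Monte Carlo that the score-matching
weight lambda(t) makes the expected squared score equal one.
"""

import numpy as np

from idpensemble import r3, so3, training as tr

ssched = so3.SO3Schedule()
rsched = r3.VPSchedule()
table = so3.default_table()

print("rotation schedule sigma(t):  sigma(0) =", float(so3.sigma(0.0, ssched)),
      " sigma(T) =", float(so3.sigma(1.0, ssched)))
print("translation schedule beta(t): beta(0) =", float(r3.beta(0.0, rsched)),
      " beta(T) =", float(r3.beta(1.0, rsched)))
print("accumulated rate int_0^T beta =", float(r3.int_beta(1.0, rsched)))

rng = np.random.default_rng(0)
n = 10
v0 = r3.com_project(rng.normal(size=(n, 3)) * 5)
for t in (0.1, 0.5, 0.9):
    sq = []
    for _ in range(2000):
        v_t, _ = r3.forward_sample_r3(v0, t, rsched, rng)
        s = r3.score_r3(v_t, v0, t, rsched)
        sq.append((s**2).sum(-1).mean())
    lam = tr.lambda_weight(t, "translation", r3_sched=rsched, n_res=n)
    print(f"t={t}: lambda * E||score||^2 = {lam * np.mean(sq):.4f}  (target 1; "
          "the weight equalizes every diffusion time's loss contribution)")
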