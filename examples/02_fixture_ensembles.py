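"""Generate a synthetic two-state ensemble and measure it.

Builds 100 conformations of a 32-residue chain that is helical (compact)
half the time and extended otherwise, then reports the statistics the
evaluation suite recovers: mean radius of gyration per state, Ramachandran
basin occupancies, and validity under the consecutive-CA criterion.
"""

import numpy as np

from idpensemble import fixtures as fx
from idpensemble import metrics as mx

ens = fx.two_state_ensemble(n_res=32, p_compact=0.5, n_conf=100, seed=42)
rgs = np.array([mx.radius_of_gyration(c) for c in ens.conformations])
labels = np.array(ens.labels)

print(f"mean Rg: {rgs.mean():.2f} A  (compact {rgs[labels == 'compact'].mean():.2f}, "
      f"extended {rgs[labels == 'extended'].mean():.2f})")
print("  -> the two states are well separated in compactness")

occ = mx.ramachandran_occupancy(ens.conformations)
frac = float(np.mean(labels == "compact"))
print("Ramachandran occupancy:", {k: round(v, 3) for k, v in occ.items()})
print(f"  -> alpha fraction tracks the realized compact fraction ({frac:.2f})")

spec = mx.ValiditySpec.from_reference(ens.conformations)
print(f"validity (consecutive CA-CA in ({spec.delta_vdw:.1f}, "
      f"{spec.delta_bond:.2f}) A): {mx.validity(ens.conformations, spec):.3f}")
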