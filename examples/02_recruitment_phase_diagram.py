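"""Competition between PRC2 and p300/UTX recruitment.

Scans a small grid of recruitment scales (alpha: PRC2 peak, beta: p300/UTX
peaks) and prints the methylation valency of each condition: strong PRC2
with weak activators is PcG-like, the opposite corner active-like, and the
middle ground (bivalent-like) is intermediate.
"""

import numpy as np

from h3k27sim import ModelParams, phase_diagram

table = phase_diagram(
    ModelParams(),
    alphas=np.array([0.0, 0.4, 1.0]),
    betas=np.array([0.3, 0.5, 1.0]),
    n_traj=12,
    burn_in_cycles=10,
    sample_cycles=3,
    seed=2,
)

print(table[["alpha", "beta", "P_me1", "P_me2", "P_me3", "P_ac", "label"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# (alpha, beta) = (1, 0.3) reproduces a wild-type Polycomb target and
# (0, 1) an active gene; moving beta up at fixed alpha erodes me3 —
# activators must rise severalfold to flip a PcG target without losing PRC2.
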