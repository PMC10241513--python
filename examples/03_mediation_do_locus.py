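"""Mediation and founder allele effects at a simulated diversity-outbred locus.

An 8-founder locus drives a mediator transcript, which drives 14 targets; the
founder effects split 4-high/4-low. The LOD-drop scan should rank the true
mediator first for each target, and the target/mediator founder-effect
vectors should be strongly concordant.
"""

import numpy as np
import pandas as pd

from pqtlmap import mediation, simdata

dosages, mediator, targets = simdata.simulate_do_locus(n_mice=500, seed=3)
L = mediation.dosage_design(dosages)
X1 = np.hstack([np.ones((500, 1)), L])
lod_med = mediation.lod_linear(mediator.to_numpy(), X1, np.ones((500, 1)))
print(f"mediator locus LOD = {lod_med:.1f} (8-founder, 7 d.f. test)")

target = "target00"
cands = pd.concat([targets, mediator.to_frame().T]).drop(index=target)
scan = mediation.mediation_scan(targets.loc[target], L, cands)
print(f"top mediation candidates for {target}:")
print(scan.head(3).to_string(index=False))

e_med = mediation.founder_effects(mediator, dosages)
e_tgt = mediation.founder_effects(targets.loc[target], dosages)
print("founder effects (mediator):", np.round(e_med.effects, 2), "for", e_med.founders)
print("founder effects (target):  ", np.round(e_tgt.effects, 2))
print(f"allele-effect concordance = {mediation.effect_concordance(e_med, e_tgt):.3f}")
print(
    "conditioning on the true mediator drives the target's locus LOD to ~0 "
    "(large delta_lod), and both loci show the same 4-high/4-low founder split."
)
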