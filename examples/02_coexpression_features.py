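"""Score co-expression of proteins and complexes.

Normalises expression time courses, computes pairwise E_co values, the
network-wide average E_co(avg), and the three complex-level triage features
Den(C,2), E_co(C), CoRatio(C) for a planted complex versus a random set.
"""

import numpy as np

import ppimcl as pm
from ppimcl.features import co_ratio, density, eco_complex

spec = pm.SyntheticSpec(seed=11)
g, truth, expr = pm.simulate_dataset(spec)

model = pm.CoexpressionModel.build(g, expr)  # normalises + fixes E_co(avg)
print(f"E_co(avg) over all protein pairs: {model.e_avg:.2f}")

C = sorted(max(truth, key=len))
u, v = C[0], C[1]
print(f"E_co({u}, {v}) (same complex): {model.eco(u, v):.2f}  Co={model.co(u, v)}")

rng = np.random.default_rng(0)
w = rng.choice([p for p in g.vertices if p not in C])
print(f"E_co({u}, {w}) (background):   {model.eco(u, w):.2f}  Co={model.co(u, w)}")

for label, S in [("planted complex", set(C)),
                 ("random protein set", set(rng.choice(g.vertices, 6, replace=False)))]:
    print(
        f"{label:18s} Den(C,2)={density(g, S, 2):.3f}  "
        f"E_co(C)={eco_complex(S, model):.1f}  CoRatio(C)={co_ratio(S, model):.3f}"
    )
print(
    "Complex members share the latent periodic signal, so their pairwise "
    "E_co exceeds E_co(avg) and all three complex-level features are high."
)
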