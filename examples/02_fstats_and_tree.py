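"""f4-statistics, coancestry, neighbour joining and the tree fit ratio.

On a simulated star panel: computes an f4 test for treeness, the outgroup
coancestry matrix, a BioNJ tree from raw distances and the per-sample
patristic/raw distance ratio (1.0 = the tree places the sample perfectly).
"""

import numpy as np

from paleodrift.njtree import neighbor_joining, phylo_fit_ratio
from paleodrift.simulate import star_scenario
from paleodrift.stats import coancestry, f4, pairwise_distances

panel = star_scenario(n_per_pop=8, n_admixed=8, n_sites=20_000, seed=3)
calls = panel.calls

# f4(A,B;C,Outgroup) ~ 0: A and B split from C before drifting apart, so
# no branch is shared between the two pairs
res = f4(calls, "A000", "B000", "C000", "Outgroup", n_blocks=50)
print(f"f4(A,B;C,O)  = {res.estimate:+.5f}  (Z = {res.z:+.2f}, {res.n_sites} sites)")
# f4(A,O;B,O) > 0: measures the drift shared by A and B relative to O
res2 = f4(calls, "A000", "Outgroup", "B000", "Outgroup", n_blocks=50)
print(f"f4(A,O;B,O)  = {res2.estimate:+.5f}  (Z = {res2.z:+.2f})")

c = coancestry(calls, "Outgroup")
print(f"coancestry: mean within-A {np.mean([c.values[i, j] for i in range(8) for j in range(i + 1, 8)]):.4f}, "
      f"A-vs-C {np.mean(c.values[:8, 16:24]):.4f}")

d = pairwise_distances(calls)
tree = neighbor_joining(d)
fit = phylo_fit_ratio(tree, d)
dev = (fit.ratios - 1.0).abs()
print("fit-ratio deviation |patristic/raw - 1| (0 = perfect placement):")
print(f"  pure individuals : {dev[[s for s in dev.index if not s.startswith('M')]].mean():.4f}")
print(f"  admixed          : {dev[[s for s in dev.index if s.startswith('M')]].mean():.4f}")
# Admixed individuals violate treeness, so their ratios deviate further
# from one than unadmixed ones.
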