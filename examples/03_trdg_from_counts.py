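"""Build a transition disconnectivity graph from a transition-count matrix.

Uses a hand-written 4-state count matrix (as would come out of a state
sequence) to compute state free energies, max-flow/min-cut barrier free
energies, and the disconnectivity tree in Newick form.
"""

import numpy as np

from scism import CountMatrix, ThermoParams, build_trdg, state_free_energies, to_newick

# visits dominate the diagonal; off-diagonal entries are observed transitions
n_ij = np.array(
    [
        [900, 25, 3, 1],
        [24, 1400, 18, 2],
        [4, 17, 700, 9],
        [1, 3, 10, 300],
    ]
)
counts = CountMatrix(n_ij, n_ij.sum(axis=1))
params = ThermoParams(temperature=298.0, tau0=1e-6, tau_seg=0.099)

fe = state_free_energies(counts, params)
tree = build_trdg(fe, counts, params)

print("state free energies (kcal/mol, most populous = 0):")
for k, f in sorted(fe.items()):
    print(f"  state {k}: F = {f:.2f}")
print("barrier free energies at the min-cut dividing surfaces:")
for (i, j), b in sorted(tree.barriers.items()):
    print(f"  {i} <-> {j}: F_barrier = {b:.2f} kcal/mol")
print("disconnectivity tree:", to_newick(tree))
# Barriers follow Kramers' relation: more transitions across a cut means a
# lower barrier; the tree merges states from the lowest barrier upward, so
# the root is the hardest dividing surface to cross.
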