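"""Grow modular, anti-modular and lattice-constrained networks.

The assortativity matrix gates which color pairs may connect.  The
equal-opportunity model dials between perfectly modular (pi = 1) and
k-partite (pi = 0); a lattice matrix with one module per site restricts
edges to a fixed geometry.
"""

import numpy as np

from grownet import (
    GrowthParams,
    equal_opportunity,
    functional_modularity,
    grow,
    kpartite,
    lattice_matrix,
    mixing_matrix,
)

for pi in (1.0, 0.5, 0.0):
    params = GrowthParams(pn=0.5, pe=1.0, n_colors=4,
                          e_matrix=equal_opportunity(4, pi), max_nodes=400)
    g = grow(params, initial="one-per-module", seed=2)
    tr = np.trace(mixing_matrix(g, 4))
    print(f"pi={pi}: measured within-module edge fraction={tr:.3f} "
          f"Q_H={functional_modularity(g, 4):+.3f}")
# Tr e tracks the generating pi; Q_H goes from +1 (modular) to -1/3
# (4-partite floor is -1/(N_c-1) scaled; exactly -1/3 here at Tr e = 0).

params = GrowthParams(pn=0.0, pe=1.0, q=1.0, n_colors=4,
                      e_matrix=lattice_matrix(4, [(0, 1), (1, 2), (2, 3), (3, 0)]),
                      max_iterations=200)
g = grow(params, initial="one-per-module", seed=3)
print(f"\n2x2 lattice percolation: n={g.number_of_nodes()} m={g.number_of_edges()} "
      f"(the 4-cycle: every allowed edge filled)")

bi = grow(GrowthParams(pn=0.3, pe=1.0, p=0.85, q=0.75, n_colors=2,
                       e_matrix=kpartite(2), max_iterations=1000),
          initial="one-per-module", seed=4)
print(f"bipartite growth: Q_H={functional_modularity(bi):+.1f} "
      f"(no like-color edge is ever placed)")
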