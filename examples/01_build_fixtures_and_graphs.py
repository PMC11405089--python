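"""Generate paired 2D/3D toy molecules and inspect the two graph modalities.

Each sample couples a topological bond graph with a 3D conformation whose
bonded distances are drawn around type-specific means (single 1.54 Å,
double 1.34 Å, triple 1.20 Å, aromatic 1.39 Å), so bond type is readable
from geometry and vice versa — the statistical link the cross-modal
objectives exploit.
"""

from gtam import FixtureSpec, bond_labels, make_fixture_set
from gtam.molio import BOND_TYPE_NAMES

pairs = make_fixture_set(FixtureSpec(n_molecules=6, seed=11))

for i, (g2d, g3d) in enumerate(pairs):
    labels = bond_labels(g2d, g3d)
    dm = g3d.distance_map
    kind = "ring" if g2d.n_bonds >= g2d.n_atoms else "chain"
    print(f"molecule {i}: {g2d.n_atoms} heavy atoms, {g2d.n_bonds} bonds "
          f"({kind})")
    for (u, v), t in zip(g2d.edge_index.T, g2d.edge_type):
        if u < v:
            print(f"  bond {u}-{v}: {BOND_TYPE_NAMES[t]:9s} "
                  f"d = {dm[u, v]:.3f} Å")
    n = g2d.n_atoms
    nb = [dm[u, v] for u in range(n) for v in range(u + 1, n)
          if labels[u, v] == 4]
    if nb:
        print(f"  non-bonded pairs: {len(nb)}, min distance {min(nb):.2f} Å")

# Bonded distances cluster tightly around the per-type means, while almost
# all non-bonded pairs sit beyond the 2.4 Å distogram ceiling.
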