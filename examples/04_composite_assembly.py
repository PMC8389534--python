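"""Composite assembly by domain-superposition grafting.

Chains four pairwise A-B complexes into a six-molecule composite: at each
step the incoming complex's shared chain is superposed (Cα) onto its
counterpart in the evolving composite and the partner chain is added under
a fresh chain id. This is how a multi-protein unit is assembled from
pairwise docking results when no experimental structure of the full
assembly exists.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from condock import GraftSpec, build_unit, make_toy_complex, write_pdb

scaffold = make_toy_complex(10, seed=5)
rng = np.random.default_rng(5)


def randomly_placed(st):
    rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    return st.with_coords(st.coords @ rot.T + rng.normal(size=3) * 15)


recipe = []
shared = "B"
for step in range(4):
    recipe.append(GraftSpec(
        incoming=randomly_placed(scaffold),
        scaffold_chain=shared, incoming_chain="A",
        keep_chains=("B",), name=f"graft-{step + 1}"))
    shared = "CDEF"[step]

composite = build_unit(scaffold, recipe)
print(f"molecules in composite: {len(composite.structure.chains)} "
      f"({', '.join(composite.structure.chains)})")
for i, entry in enumerate(composite.provenance, 1):
    renames = ", ".join(f"{a}->{b}" for a, b in entry.chain_renames.items())
    print(f"  step {i}: fit RMSD {entry.fit_rmsd:.2e} Å over "
          f"{entry.n_fit_atoms} Cα, chains {renames}")
print(f"inter-unit clashes (< 2 Å): {len(composite.clashes)}")

write_pdb(composite.structure, "composite_unit.pdb")
print("wrote composite_unit.pdb")

# Each graft is rigid, so fit RMSDs near zero mean the shared domains were
# identical; clashes are reported, never resolved.
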