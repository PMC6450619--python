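"""Map an atomistic DOPE lipid onto its 14-bead CG representation.

Builds the 129-atom DOPE fixture, validates the bead partition, maps a
conformation to bead centres of mass, and enumerates the CG bonded
topology and exclusions.
"""

import numpy as np

from cginverse.fixtures import make_dope_fixture
from cginverse.mapping import map_frame, validate_mapping

topo, scheme, cg = make_dope_fixture()
report = validate_mapping(scheme, topo)
print(f"scheme valid: {report.n_beads} beads cover {report.n_atoms} atoms")

counts = cg.interaction_type_counts()
print(f"interaction types: {counts['bond']} bond, {counts['angle']} angle, "
      f"{counts['torsion']} torsion, {counts['nonbonded']} non-bonded")
print(f"bead charges (e): {np.round(cg.charges, 2)}  (sum = {cg.charges.sum():+.1e})")

# a throwaway conformation: atom positions drawn near a line, then mapped
rng = np.random.default_rng(0)
box = np.array([10.0, 10.0, 10.0])
positions = np.linspace([1, 5, 5], [6, 5, 5], topo.n_atoms) + rng.normal(
    scale=0.05, size=(topo.n_atoms, 3))
frame = map_frame(positions, box, scheme, topo)
print(f"first three bead positions (nm):\n{np.round(frame.positions[:3], 3)}")
print(f"{len(cg.exclusions)} intramolecular bead pairs excluded from "
      "non-bonded interactions (1-2, 1-3 and 1-4 neighbours)")
# The counts above are the full bookkeeping of the 14-bead DOPE model:
# every bonded term type gets its own tabulated potential, and each of the
# 21 type pairs gets a short-range pair table.
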