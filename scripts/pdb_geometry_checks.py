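#!/usr/bin/env python
"""Geometry checks against the deposited fibril template (PDB entry 2M4J).

Usage:
    python scripts/pdb_geometry_checks.py path/to/2m4j.pdb

Needs the experimental entry (download it from the PDB; it is not bundled
with the package).  Reports, for model 1:

* the layer-averaged intra-layer Met35 side-chain distance (the initial
  pore dimension, expected ~23 Å),
* the minimum Asp7-Asp7 side-chain distance over chain pairs (the
  in-register stacking contact, expected ~3.85 Å),
* the mean inter-layer displacement norm (cross-beta spacing, ~4.8 Å).

Both chain-order conventions are tried because the deposition order of
the nine chains relative to the filament labels is not documented.
"""

import sys

import numpy as np

from trifibril import (
    assign_topology,
    mean_layer_displacement,
    pore_distance,
    read_structure,
    residue_pair_distance,
)


def main(path):
    model = read_structure(open(path).read())
    chains = model.chain_ids()
    print(f"{len(chains)} chains: {chains}")

    for order in ("layer_major", "filament_major"):
        topo = assign_topology(model, 3, 3, chain_order=order)
        pores = [pore_distance(topo.coord, topo, layer) for layer in (1, 2, 3)]
        spacing = mean_layer_displacement(topo).norm
        print(f"[{order}] mean Met35-Met35 pore: {np.mean(pores):.2f} A "
              f"(per layer: {['%.2f' % p for p in pores]}); "
              f"layer spacing |v|: {spacing:.2f} A")

    dmin = min(residue_pair_distance(model.coord, model, a, 7, b, 7,
                                     sidechain_only=True)
               for a in chains for b in chains if a != b)
    print(f"min Asp7-Asp7 side-chain distance over chain pairs: {dmin:.2f} A")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
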