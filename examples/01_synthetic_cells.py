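"""Generate synthetic cells and demonstrate what the CFOR representation
removes: size and orientation, but never shape."""

import dataclasses

import numpy as np

from cloudmorph import frames, synthgen

cells, table = synthgen.generate_dataset(5, rng=0)
print(f"generated {len(cells)} cells, each a "
      f"{cells[0].cloud.n_points}-point cloud")
print(f"parameter table: {table.shape[0]} rows x {table.shape[1]} columns "
      f"(the 17 generative parameters)")
print(table.round(2).to_string())

# Re-generate the first cell with doubled size and a new orientation: the
# cell-frame (CFOR) output must not change, because CFOR is size- and
# rotation-invariant by construction.
cell = cells[0]
altered = dataclasses.replace(cell.params,
                              size_scale=2 * cell.params.size_scale,
                              rotation_angles=(1.0, 2.5))
a = frames.cfor_pipeline(synthgen.generate_cell_cloud(cell.params,
                                                      cell.seed).cloud).rep
b = frames.cfor_pipeline(synthgen.generate_cell_cloud(altered,
                                                      cell.seed).cloud).rep
print(f"\nCFOR deviation after doubling size and rotating: "
      f"{np.abs(a - b).max():.2e}")
print("(a value at machine precision: size and orientation are gone, "
      "so any remaining variation between cells is pure shape)")
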