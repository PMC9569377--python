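"""Simulate morphogen random walks in a synthetic tissue geometry.

Builds a tissue-like extracellular mask, places receptors on the membranes,
and runs two agent-based simulations: one without binding and one with
strong receptor binding.  Prints the cavity-to-interface localization
density ratio for each: without binding, tissue geometry alone concentrates
molecules in extracellular cavities (ratio > 1); binding retains them at
cell-cell interfaces and pulls the ratio down.
"""

import numpy as np

from morphotrack import geometry as G
from morphotrack import simulator as S

geom = G.synthesize_tissue(
    n_cells=12, target_eta=8.0, cavity_fraction=0.45, seed=1,
    cell_area_um2=225.0, cavity_site_fraction=0.25,
)
print(f"geometry: {geom.shape[0]} x {geom.shape[1]} px at 10 nm, "
      f"eta = {G.compute_extracellular_fraction(geom):.1f}%")

receptors = G.place_receptors(geom, sigma=5.0)
print(f"receptors: {receptors.count} at sigma = 5 per um of membrane")

for tau in (0.0, 16.0):
    cfg = S.SimConfig(n_steps=2000, tau=tau, sigma=5.0, seed=7)
    result = S.run_simulation(geom, receptors if tau > 0 else None, cfg)
    ratio = S.localization_density_ratio(result, geom)
    bound = result.states[500:].mean()
    print(
        f"tau = {tau:4.0f} s: density ratio rho_c/rho_i = {ratio:.2f}, "
        f"bound fraction = {bound:.2f}"
    )
print(
    "ratio > 1 means accumulation in cavities (pure hindered diffusion); "
    "binding shifts weight toward interfaces."
)
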