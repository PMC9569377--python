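"""Per-movie cavity/interface spot-density ratios with cohort statistics.

Builds a small tissue geometry, simulates several short movies without
binding, and computes the per-movie localization density ratio between the
annotated cavity and interface polygons, summarized as median and
quartiles.  Without binding, hindered diffusion in the tissue geometry
yields ratios above 1 (accumulation in cavities).
"""

import numpy as np

from morphotrack import geometry as G
from morphotrack.density import cohort_summary, spot_density_ratio
from morphotrack.simulator import SimConfig, run_simulation

geom = G.synthesize_tissue(
    n_cells=8, target_eta=10.0, seed=5, pixel_pitch_um=0.02, cell_area_um2=100.0
)
print(f"regions: {sum(r.label == 'cavity' for r in geom.regions)} cavity / "
      f"{sum(r.label == 'interface' for r in geom.regions)} interface polygons")

ratios = []
for movie in range(6):
    cfg = SimConfig(n_steps=300, n_agents=40, tau=0.0, seed=movie)
    res = run_simulation(geom, None, cfg)
    detections = res.to_dataframe().rename(columns={"step": "frame"})
    out = spot_density_ratio(
        detections, geom.regions, movie_id=f"sim{movie}",
        pixel_pitch_um=geom.pixel_pitch_um,
    )
    ratios.append(out)
    print(f"movie {movie}: ratio = {out.ratio:.2f} (valid = {out.valid})")

table = cohort_summary({"no_binding": ratios})
row = table.iloc[0]
print(f"cohort median = {row['median']:.2f} "
      f"[Q1 {row['q25']:.2f}, Q3 {row['q75']:.2f}] over {row['n_movies']} movies")
print("median > 1: molecules are more likely found in cavities.")
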