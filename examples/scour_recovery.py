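"""How much the static scour cost overstates recycled carbon.

Simulates 80 years of giant-iceberg groundings on a 10 000 km2 shelf
grid (the same area, standing stock and grounding rate as the static
cost formula) under two placement rules, and compares steady-state
recycled carbon against the static 0.25 x 10 000 x 16 = 40 000 t C yr-1
figure.  Repeat scour of recovering seabed — especially in hotspots —
recycles far less than the formula assumes.
"""

import numpy as np

from bergcarbon import ArrivalModel, load_params, make_grid, run_simulation, scour_cost

params = load_params()
static = scour_cost(params.point("q"), params.point("A_g"), params.point("rho"))
years, burn = 80, 40

uniform = run_simulation(make_grid(), ArrivalModel(placement="uniform"),
                         years=years, seed=0, T_rec=params.point("T_rec"))
hot = run_simulation(
    make_grid(),
    ArrivalModel(placement="hotspot", hotspot_cells=np.arange(40)),
    years=years, seed=0, T_rec=params.point("T_rec"))

u = uniform.recycled_per_year[burn:].mean()
h = hot.recycled_per_year[burn:].mean()
print(f"static cost formula            : {static:>10,.0f} t C yr-1")
print(f"simulated, uniform placement   : {u:>10,.0f} t C yr-1 "
      f"({100 * u / static:.0f}% of static)")
print(f"simulated, hotspot placement   : {h:>10,.0f} t C yr-1 "
      f"({100 * h / static:.0f}% of static)")
print(f"carbon conservation residual   : {uniform.conservation_residual():.2e} t")
print()
print("Even with random grounding locations the benthos rarely stands at")
print("climax when hit; hotspot grounding re-scours barely recovered")
print("seabed and recycles a small fraction of the static figure.")
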