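"""Design a strain panel: which enzyme level makes parameters estimable?

Scans steady-state substrate concentration and conversion flux over a grid
of enzyme capacities (Vmax) and substrate-producing influxes (v_in) for the
influx -> Michaelis-Menten -> growth-dilution pathway.  High Vmax keeps the
substrate pool too low to ever saturate the enzyme; very low Vmax caps the
flux at a hard-to-measure trickle and is infeasible for most influxes.
"""

import numpy as np

from invivokinetics import PathwayModel, design_scan, reference_presets

scan = reference_presets()["design_scan_three_level"]
base = PathwayModel(v_in=0.01, vmax=0.7, k_half=scan.k_half, mu=scan.mu)
table = design_scan(base, scan.vmax_levels, scan.v_in_grid())

for vmax, grp in table.groupby("vmax"):
    feas = grp[grp.feasible]
    print(f"Vmax = {vmax} µM/h: {len(feas)}/{len(grp)} influxes feasible", end="")
    if len(feas):
        print(
            f"; S* spans {feas.s_star.min():.3g}-{feas.s_star.max():.3g} µM, "
            f"saturation reaches {100 * feas.saturation_fraction.max():.0f}%"
        )
    else:
        print()

# The medium enzyme level covers the widest well-measurable substrate span
# while still approaching saturation -- that is the design worth building.
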