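"""From raw omics numbers to intracellular concentrations, fluxes and kcat.

Metabolomics reports µmol per gram dry cell weight; proteomics reports fmol
per µg protein.  Both are converted to intracellular molar concentrations
through the cell count per gDCW (6.59e10), the single-cell volume (66 fL)
and the protein mass fraction (0.63 g/gDCW).  At steady state during
exponential growth, a stable product's synthesis flux is its concentration
times the growth rate.
"""

from invivokinetics import (
    amount_to_concentration,
    dilution_flux,
    protein_to_concentration,
    turnover_number,
)

ggpp_amount = 0.0904  # µmol/gDCW measured for one strain
ggpp_uM = amount_to_concentration(ggpp_amount)
print(f"GGPP: {ggpp_amount} µmol/gDCW  ->  {ggpp_uM:.2f} µM intracellular")

enzyme_fmol_per_ug = 0.29  # phytoene synthase, absolute proteomics
enzyme_nM = protein_to_concentration(enzyme_fmol_per_ug)
print(f"enzyme: {enzyme_fmol_per_ug} fmol/µg protein  ->  {enzyme_nM:.1f} nM")

phytoene_uM, mu = 1641.0, 0.40
flux = dilution_flux(phytoene_uM, mu)
print(f"phytoene flux = [P]*µ = {phytoene_uM}*{mu} = {flux:.1f} µM/h")

vmax = 849.0  # fitted maximal rate, µM/h
kcat = turnover_number(vmax, enzyme_nM * 1e-3)
print(f"kcat = Vmax/[E] = {kcat:.1f} per second (~{round(kcat)} 1/s)")
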