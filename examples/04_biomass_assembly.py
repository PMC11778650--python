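"""Assemble a biomass pseudo-reaction normalized to 1,000 g/mol.

Starts from macromolecular mass fractions (g/g) and per-class precursor
tables, applies a sulfur-enrichment factor to the S-containing precursors
(desulfurizing organisms carry elevated S-amino-acid and cofactor levels),
and rescales coefficients in closed form so the mass-weighted coefficient
sum is exactly the target molecular weight.
"""

from sulfurflux import assemble_biomass, biomass_molecular_weight
from sulfurflux.synth import default_composition

for enrichment in (1.0, 1.2, 2.0):
    comp = default_composition(sulfur_enrichment=enrichment)
    rxn = assemble_biomass(comp, target_mw=1000.0)
    mw = biomass_molecular_weight(rxn, comp.molar_masses())
    print(f"sulfur enrichment x{enrichment:.1f}: "
          f"MW = {mw:.6f} g/mol, "
          f"S content = {comp.sulfur_per_gram():.4f} mmol S/gDW")

comp = default_composition()
rxn = assemble_biomass(comp, target_mw=1000.0)
print("\nbiomass coefficients (mmol per gDW, negative = consumed):")
for met, coef in sorted(rxn.stoichiometry.items()):
    print(f"  {met:10s} {coef:+10.4f}")
print("ATP/ADP/Pi/H2O rows are maintenance turnover and are excluded from "
      "the molecular-weight sum.")
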