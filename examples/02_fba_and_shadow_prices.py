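"""FBA growth and LP-dual shadow prices with DBT as the sole sulfur source.

Closes sulfate and sulfide uptake, opens dibenzothiophene generously, and
maximizes growth on 1 mmol/gDW/h glucose.  The shadow price of a metabolite
is dZ*/db for its mass-balance row (b > 0 forces net production), so a
costly-to-make metabolite prices negative.  Because every 4S oxidation
burns one FMNH2, the intermediates price at exact 1:2:3 multiples, and the
end product 2-HBP — whose only disposal route consumes a reducing
equivalent — prices at exactly minus the first step.
"""

from sulfurflux import build_desulfurization_toy, solve_fba

model = build_desulfurization_toy()
model.set_bounds("EX_so4", 0, 1000)    # no sulfate
model.set_bounds("EX_h2s", 0, 1000)    # no sulfide
model.set_bounds("EX_dbt", -10, 0)     # DBT freely available

result = solve_fba(model)
print(f"status: {result.status}   growth: {result.objective_value:.6f} /h")
print(f"DBT uptake: {-result.fluxes['EX_dbt']:.4f} mmol/gDW/h "
      "(= the chain flux = biomass sulfur demand)")

price = result.shadow_prices
p = price["dbto[c]"]
print("\nshadow prices along the 4S chain (objective units per unit drain):")
for met, label in [("dbto[c]", "DBTO  (sulfoxide)"),
                   ("dbto2[c]", "DBTO2 (sulfone)"),
                   ("hbps[c]", "HBPS  (sulfinate)"),
                   ("hbp[c]", "2-HBP (end product)"),
                   ("slf[c]", "sulfite")]:
    print(f"  {label:22s} {price[met]:+.9f}   ratio to DBTO: "
          f"{price[met] / p:+.3f}")
print("\nThe 1 : 2 : 3 : -1 progression is the structural signature of a "
      "linear pathway with a uniform per-step cofactor cost.")
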