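"""Build the synthetic desulfurization model and inspect its structure.

Generates the bundled toy network (four carbon sources, sulfate
assimilation, the 4S DBT chain, a 1,000 g/mol biomass reaction), prints the
reconstruction-style summary, and runs the QC checks.  Balanced counts and
zero dead ends are generator contracts: the toy's simplified formulas are
self-consistent by construction.
"""

from sulfurflux import build_desulfurization_toy
from sulfurflux.qc import balance_model, connectivity_profile, find_dead_ends

model = build_desulfurization_toy()

print(f"model: {model.name}")
for key, value in sorted(model.summary().items()):
    print(f"  {key:24s} {value}")

reports = balance_model(model)
balanced = sum(1 for r in reports if r.verdict == "balanced")
print(f"\nmass/charge balance: {balanced}/{len(reports)} chemical reactions "
      "balanced (exchanges and biomass are exempt drains)")

profile = connectivity_profile(model)   # metabolic reactions only
print("connectivity (reactions per metabolite):",
      dict(sorted(profile.degree_counts.items())),
      f"| >{profile.cutoff}: {profile.more_than_cutoff}")

print("dead-end metabolites:", find_dead_ends(model) or "none")
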