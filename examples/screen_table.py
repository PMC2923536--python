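"""Re-derive the screen summary table from the packaged raw assay rows.

The packaged fixture holds only the raw observations of eight B. rapa
TILLING assays (amplicon length, GC%, mutations detected, plants
screened).  Everything else — 1/X kb densities, GC-normalized densities,
per-plant loads and expected yields — is recomputed here.
"""

from tillingkit import PopulationConstants, summarize_assays
from tillingkit.io import load_brapa_assays

assays = load_brapa_assays()
print(f"{len(assays)} assays, {sum(a.mutations_detected for a in assays)} "
      "mutations detected in total\n")

table = summarize_assays(assays, PopulationConstants())
cols = ["gene", "ems_pct", "mutations", "load_per_plant",
        "load_per_plant_norm", "density_kb", "density_kb_norm"]
print(table[cols].to_string(index=False))
print()
print("'norm' columns are rescaled to the 35% genome GC level (EMS hits only")
print("G/C, so density scales with GC).  The 0.3% population averages one")
print("mutation per 44 kb raw, 1/56 kb normalized — roughly 9,700 mutations")
print("per plant over a 500 Mbp genome.")
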