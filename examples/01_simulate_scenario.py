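"""Generate the default drought-timing scenario and look at its structure.

Builds the four-treatment greenhouse experiment (control, early, late,
early-late hot drought) as half-hourly environmental, dendrometer and
sap-flow records plus weekly needle lengths and end-of-season biomass.
"""

import pinedrought as pdr

design = pdr.ExperimentDesign(rng_seed=1)
data = pdr.simulate_scenario(design)

env = data["env"]
stress = env[env["compartment"] == "stress"]
for i, (s, e) in enumerate(design.stress_windows, start=1):
    w = stress[(stress["doy"] >= s) & (stress["doy"] <= e)]
    print(
        f"stress window {i} (DOY {s}-{e}): "
        f"T max {w['T_air'].max():.1f} C, VPD max {w['VPD'].max():.2f} kPa, "
        f"SWC min {w['SWC'].min():.1f} %"
    )

needles = data["needles"]
finals = needles[needles["doy"] == needles["doy"].max()]
print("\nfinal needle length (mm) by treatment:")
print(finals.groupby("treatment")["length_mm"].mean().round(1).to_string())

print(f"\ntables generated: {sorted(data)}")
print(
    "The stress compartment ramps to the configured maxima while soil dries to"
    " ~22%; early-stressed needles end ~2 cm shorter because elongation stops"
    " ~3 weeks earlier."
)
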