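"""Per-plot mass densities from a field census and debris transects.

Builds a small 10 x 10 m mangrove plot census (species, DBH, live/dead
status) plus two line-intercept woody-debris transects, and converts them
to aboveground biomass (AGB, live), necromass (AGN, standing dead), total
mass (AGTM = AGB + AGN), and downed-wood (WD) densities in Mg/ha.
"""

from necroscan import PlotRecord, TreeRecord, WDTransect, aggregate_plot_mass

plot = PlotRecord(
    "DEMO-1",
    trees=[
        TreeRecord("red", 18.0, "live"),
        TreeRecord("red", 12.5, "live"),
        TreeRecord("white", 25.0, "dead"),
        TreeRecord("black", 9.0, "live"),
        TreeRecord("red", 31.0, "dead"),
    ],
    wd_transects=[
        WDTransect([10.0, 3.2, 8.1], length_m=10.0),
        WDTransect([5.5], length_m=10.0),
    ],
)

masses = aggregate_plot_mass(plot)
print(f"plot {masses.plot_id}")
print(f"  AGB  {masses.agb:7.1f} Mg/ha   (standing live trees)")
print(f"  AGN  {masses.agn:7.1f} Mg/ha   (standing dead trees)")
print(f"  AGTM {masses.agtm:7.1f} Mg/ha   (AGB + AGN, exact)")
print(f"  WD   {masses.wd:7.1f} Mg/ha   (downed wood, line-intercept)")
print()
print("AGN is the damage currency: mass moved from the live to the dead")
print("pool; WD is what already fell to the forest floor.")
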