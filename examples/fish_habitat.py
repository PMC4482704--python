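"""Weighted Usable Area for two fish species on synthetic hydraulic grids.

Builds depth/velocity rasters for a range of discharges, evaluates two
contrasting fuzzy habitat rule bases (a shallow-water minnow and a
pool-dwelling roach) on every wet cell, and standardizes the WUA by the
bankfull wetted area.
"""

from riverscape import SynthConfig, example_fish_species, synth_hydraulic_grid, wua

cfg = SynthConfig(seed=3)
species = example_fish_species()
bankfull = synth_hydraulic_grid(cfg, 6.4)

print(f"bankfull wetted area: {bankfull.wetted_area:.0f} m2 "
      f"({bankfull.depth.shape[0]}x{bankfull.depth.shape[1]} cells of "
      f"{cfg.cell_size**2} m2)\n")
print(f"{'Q (m3/s)':>9} " + " ".join(f"{name:>15}" for name in species))
for q in (0.8, 1.5, 3.0, 6.0):
    grid = synth_hydraulic_grid(cfg, q)
    shares = []
    for system in species.values():
        share = 100 * wua(grid, system) / bankfull.wetted_area
        shares.append(share)
    print(f"{q:9.1f} " + " ".join(f"{s:14.1f}%" for s in shares))

print("\nValues are WUA as a share of the bankfull wetted area (100% = the")
print("whole bankfull channel is perfectly suitable). The deep-pool roach")
print("loses habitat as discharge drops and pools shrink; the shallow-margin")
print("minnow keeps a higher share across the whole flow range.")
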