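"""Substrate-based abundance for macroinvertebrates in a degraded reach.

Predicts abundance from substrate-specific densities for a pure-sand
baseline (a typical degraded lowland bed), corrects it for nitrate via a
dose-response curve, and standardizes it against abundances predicted for
natural reference substrate ranges (e.g. 5-20% gravel).
"""

from riverscape import (SubstrateComposition, apply_water_quality,
                        example_invert_species, example_reference_ranges,
                        predict_abundance, relative_abundance)

present = SubstrateComposition({"sand": 1.0, "silt": 0.0, "fine_gravel": 0.0,
                                "macrophytes": 0.0, "wood": 0.0, "cpom": 0.0})
ref = example_reference_ranges()
reach_area = 2800.0   # m2, a ~260 m reach of ~11 m width

for name, params in example_invert_species().items():
    raw = predict_abundance(params["preference"], present, reach_area)
    corr = apply_water_quality(raw, params["dose_response"], {"nitrate_mg_l": 3.0})
    med, lo, hi = relative_abundance(params["preference"], present, ref,
                                     reach_area=reach_area, seed=4)
    print(f"{name}:")
    print(f"  predicted abundance (pure sand): {raw:8.0f} individuals")
    print(f"  nitrate-corrected (3 mg/l):      {corr:8.0f} individuals")
    print(f"  relative to natural reference:   {med:6.1f}% ({lo:.0f}-{hi:.0f}%)")

print("\nA relative abundance near 100% means the present sand bed suits the")
print("species as well as the natural substrate mosaic; a low value flags a")
print("species whose gravel/organic habitat is missing from the reach.")
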