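"""Back-calculate dissolved N2O from a headspace-equilibrated bottle.

A 1.2 L serum bottle is filled with reservoir water, 60 mL of ambient air
is added, and the shaken headspace is measured by GC.  The mole balance
recovers the original dissolved concentration; replicate spread gives the
analytical uncertainty used later to classify sites.
"""

from pondn2o import DissolvedGasSample, WaterState, back_calculate

sample = DissolvedGasSample(
    site_id="demo-pond",
    gas="N2O",
    headspace_ppm_replicates=(0.271, 0.266),  # GC dry molar fractions, ppm
    air_ppm=0.330,                            # ambient air at the site
    equilibration_state=WaterState(temperature=19.5),
)

result = back_calculate(sample)
print(f"dissolved N2O     : {result.concentration_nm:6.2f} nM")
print(f"replicate sigma   : {result.uncertainty_nm:6.2f} nM")
print(f"equilibrium value : {result.equilibrium_nm:6.2f} nM")
print(f"saturation ratio  : {result.saturation_ratio:6.2f}")

# A ratio below 1 means the water holds less N2O than the overlying
# atmosphere supports: this pond is a candidate atmospheric N2O sink.
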