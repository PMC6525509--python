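"""Water-column stability from a temperature profile.

The squared Brunt-Vaisala frequency N^2 = (g/rho) d(rho)/dz measures how
strongly a density step resists vertical mixing; its per-site maximum is
the stratification covariate of the driver model.
"""

from pondn2o import DepthProfile, buoyancy_frequency

profile = DepthProfile(
    site_id="demo-pond",
    depths_m=(0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    temperatures_c=(23.8, 23.6, 22.9, 18.4, 15.2, 14.6, 14.5),
)

result = buoyancy_frequency(profile)
for z, n2 in zip(result.interface_depths_m, result.n_squared_s2):
    print(f"  {z:4.2f} m  N^2 = {n2: .5f} s^-2")
print(f"max buoyancy frequency: {result.max_buoyancy_frequency_s2:.5f} s^-2")
# Values near 0.01 s^-2 indicate the sharp mid-column thermocline typical
# of a stratified prairie pond in late summer; 0 means fully mixed.
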