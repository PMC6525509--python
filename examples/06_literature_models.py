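"""Compare observed fluxes against literature emission models.

The IPCC EF(B) method predicts dissolved N2O-N as 0.0025 x NOx-N; routed
through the bulk flux relation it gives a per-site predicted flux that can
be compared with the measured one.  Linear literature models are supported
via configured coefficients (none are shipped).
"""

from pondn2o import EmissionModel, EmissionModelName, co2_equivalent, compare, predicted_flux
from pondn2o.fluxes import estimate_site_flux

k, sigma = 1.64, 1.25
observed = [
    estimate_site_flux("pond-a", 4.0, 9.0, k, sigma),    # undersaturated
    estimate_site_flux("pond-b", 7.0, 9.0, k, sigma),    # undersaturated
    estimate_site_flux("pond-c", 30.0, 9.0, k, sigma),   # supersaturated
]
nox = {"pond-a": 900.0, "pond-b": 2500.0, "pond-c": 4200.0}  # ug N/L

model = EmissionModel(EmissionModelName.IPCC_EF)
preds = {
    e.site_id: predicted_flux(model, {"nox": nox[e.site_id]}, k, e.c_eq_nm)[
        "flux_umol_m2_d"
    ]
    for e in observed
}
result = compare(observed, preds, model_name="ipcc_ef")
print(result.table.round(2).to_string(index=False))
print(f"fold overestimate (|pred|/|obs|): min {result.fold_min:.1f} "
      f"mean {result.fold_mean:.1f} max {result.fold_max:.1f}")

mass_n = 1.0  # kg N2O-N per day, say
print(f"\n1 kg N2O-N/d as CO2-equivalent (GWP 273): {co2_equivalent(mass_n, 273.0):.0f} kg/d")
# Emission-factor predictions scale with NOx and ignore in-situ uptake, so
# they overshoot real fluxes wherever ponds are undersaturated.
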