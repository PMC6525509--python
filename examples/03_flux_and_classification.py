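"""Air-water N2O flux and sink/source classification for a small fleet.

Flux is k * (C_water - C_eq) in umol m-2 d-1; sites within the replicate
uncertainty band of equilibrium are not called either way.
"""

from pondn2o import WaterState, equilibrium_concentration, estimate_site_flux, summarize_fleet

k = 1.64       # fleet-mean transfer velocity, m/d
sigma = 1.25   # fleet-average replicate uncertainty, nM

sites = {           # site -> (dissolved N2O nM, water temperature C)
    "pond-a": (3.1, 21.0),
    "pond-b": (6.55, 20.0),
    "pond-c": (9.4, 22.5),
    "pond-d": (41.0, 18.5),
}

estimates = []
for site, (c_water, temp) in sites.items():
    c_eq = equilibrium_concentration("N2O", WaterState(temperature=temp), 0.33)
    est = estimate_site_flux(site, c_water, c_eq, k, sigma_nm=sigma)
    estimates.append(est)
    print(f"{site}: C={c_water:5.2f} nM  C_eq={c_eq:5.2f} nM "
          f"flux={est.flux_umol_m2_d:7.2f} umol/m2/d  -> {est.label.value}")

summary = summarize_fleet(estimates)
counts = {k: v["count"] for k, v in summary["labels"].items()}
print(f"\nmedian flux {summary['median_flux_umol_m2_d']:.2f} umol/m2/d; counts {counts}")
# Negative flux = atmospheric uptake.  Undersaturated ponds dominate this
# little fleet, mirroring the sink behaviour of eutrophic farm reservoirs.
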