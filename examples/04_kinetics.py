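"""Simulate initial-rate data and fit the Michaelis-Menten model.

Draws rates at nine substrate concentrations (0.25-10 mM) from the
reference kojibiose-hydrolase parameters (K_M 0.77 mM, k_cat 9.9 1/s,
73.7 kDa) with 3% multiplicative noise in triplicate, then re-fits.
The printed estimates recover the generating parameters to within a
few percent; the catalytic efficiency k_cat/K_M rounds to 13 1/(mM s).
"""

from specmap import catalytic_efficiency, fit_michaelis_menten, generate_mm_data

data = generate_mm_data(
    km_mM=0.77, kcat_per_s=9.9, noise_cv=0.03, replicates=3, seed=7
)
fit = fit_michaelis_menten(data)
raw, rounded = catalytic_efficiency(fit)

print(f"n = {fit.n_points} rate measurements")
print(f"K_M   = {fit.km_mM:.3f} +- {fit.se_km:.3f} mM")
print(f"V_max = {fit.vmax_U_per_mg:.2f} +- {fit.se_vmax:.2f} U/mg")
print(f"k_cat = {fit.kcat_per_s:.2f} +- {fit.se_kcat:.2f} 1/s")
print(f"k_cat/K_M = {raw:.2f} 1/(mM s)  (2 s.f.: {rounded:g})")
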