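"""From chemostat measurements to exchange fluxes and uptake bounds.

Generates a noisy synthetic measurement table (supernatant and medium
concentrations at six dilution rates), converts it to fluxes with
q = D (C_supernatant - C_medium) / X, and fits the growth-rate-dependent
uptake bounds used by the simulation layer.
"""

from pcfba.fixtures import fit_uptake_bounds, flux_from_chemostat, make_chemostat_dataset

records, provenance = make_chemostat_dataset(seed=7, n_rates=6, noise_sd=0.05)

print("example fluxes at D = 0.5/h (mmol/gCDW/h, uptake negative):")
for r in records:
    if abs(r.D - 0.5) < 0.01 and r.compound in ("ala", "arg", "orn"):
        print(f"  {r.compound}: q = {flux_from_chemostat(r):+.3f}")

fits = fit_uptake_bounds(records)
print("\nfitted uptake bounds q_ub = slope * mu + intercept:")
print(f"{'compound':<10} {'slope':>8} {'intercept':>10} {'true slope':>11}")
for compound, fit in sorted(fits.items()):
    true = provenance.slopes.get(compound)
    true_s = f"{true[0]:.2f}" if true else "(nonlinear)"
    print(f"{compound:<10} {fit.slope:>8.3f} {fit.intercept:>10.3f} {true_s:>11}")

# Secreted compounds (ornithine) get no bound; aspartate/glutamate are
# consumed non-linearly and their linear fits are correspondingly poor.
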