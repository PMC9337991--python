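"""Estimate a riboswitch aptamer's dissociation constant from a titration.

Generates one synthetic in-line probing titration (12 log-spaced Na+
concentrations from 10 uM to 100 mM plus a no-ligand anchor lane, 10%
multiplicative band noise), scales the two modulated sites to fraction
bound, and fits the one-to-one sigmoidal dose-response.
"""

from riboquant import (
    NoiseModel,
    default_probing_sites,
    fit_kd,
    simulate_titration,
    titration_concentrations,
)

TRUE_KD_MM = 2.2  # generating truth, low-mM like a Na+ aptamer

series = simulate_titration(
    true_kd=TRUE_KD_MM,
    sites=default_probing_sites(),
    concentrations=titration_concentrations(),
    noise=NoiseModel(cv=0.10, seed=7),
)
fit = fit_kd(series)  # hill pinned at 1: one-to-one binding

print(f"generating K_D : {TRUE_KD_MM:.2f} mM")
print(f"fitted K_D     : {fit.kd_mM:.2f} mM  (hill = {fit.hill:.1f})")
print(f"top plateau    : {fit.top:.3f}   (1 would mean the 100 mM anchor is fully saturating)")
print(f"residual norm  : {fit.residual_norm:.2f} over {fit.n_sites_used} sites")
print()
print("The fitted K_D is the Na+ concentration at which half the aptamer")
print("population is ligand-bound; with 10% band noise a single titration")
print("typically recovers the truth within a few tens of percent.")
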