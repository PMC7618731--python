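"""Decompose hold-phase stress relaxation into an offset plus fast and
slow exponentials, and derive the generalized-Kelvin moduli and their
calibration-free ratio metrics."""

import numpy as np

from fibremech import (
    Instrument,
    analyze_relaxation_trace,
    bin_by_strain,
    derive_moduli,
    generate_relaxation_trace,
    relaxation_recovery_preset,
)

instrument = Instrument()
# hold decays planted at tau1 = 7.3 s, tau2 = 90.4 s, elastic proportion 56.8 %
model = relaxation_recovery_preset(noise_sd=0.01)

trace = generate_relaxation_trace(model, instrument, seed=1)
print(f"incremental pull: {len(trace)} samples, 5 x 2 um steps with 120 s holds\n")

fits = analyze_relaxation_trace(trace, instrument.ke, instrument.cross_section,
                                instrument.well)
print("per-hold double-exponential fits:")
for f in fits:
    m = derive_moduli(f)
    print(f"  strain {f.strain:.2f}: tau1 = {f.tau1:5.2f} s, tau2 = {f.tau2:6.2f} s, "
          f"E0/Emax = {m.elastic_proportion:5.1f} %, "
          f"fast contribution = {m.fast_contribution:.2f}")

usable = [f for f in fits if f.usable]
ep = [100 * f.sigma0 / (f.sigma0 + f.sigma1 + f.sigma2) for f in usable]
print(f"\ncohort means: tau1 = {np.mean([f.tau1 for f in usable]):.2f} s "
      f"(planted 7.3), tau2 = {np.mean([f.tau2 for f in usable]):.2f} s (planted 90.4), "
      f"elastic proportion = {np.mean(ep):.1f} % (planted 56.8)")
print("the remaining ~43 % of the peak stress relaxes away: viscous remodelling")

summary = bin_by_strain(fits)
print("\nper-strain-bin summary (0.5-strain bins):")
print(summary[["bin_lo", "bin_hi", "n", "tau1_mean", "tau2_mean",
               "elastic_proportion_mean"]].round(2).to_string(index=False))
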