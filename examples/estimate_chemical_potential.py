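"""Recover a TF's chemical potential from simulated ChIP peak data.

Simulates 200 peak sequences (200 bp each) carrying Boltzmann-sampled
binding sites of a strong 16 bp motif, with enrichment signals proportional
to the Fermi-Dirac occupancy at a known potential plus 10% noise, then fits
the occupancy model by profiled least squares over candidate potentials.
Background-anchored energies are used: the absolute energy scale must be
pinned for the potential to be identifiable.
"""

import numpy as np

from bindshift import estimate_mu, pwm_to_energy, random_pwm, simulate_chip_peaks

MU_TRUE = -12.0

rng = np.random.default_rng(21)
pwm = random_pwm(rng, 16, 1.9, id="chip_tf", tf_name="CHIP_TF")
energy = pwm_to_energy(pwm, reference="background")
print(f"motif: {pwm.consensus()}  consensus site energy {energy.site_energy():.1f} kT")

data = simulate_chip_peaks(rng, energy, MU_TRUE, n_peaks=200, noise_sd_fraction=0.10)
fit = estimate_mu(energy, data)

print(f"\ntrue potential   : {MU_TRUE:+.2f}")
print(f"estimated        : {fit.mu_hat:+.2f}")
print(f"signal = {fit.scale:.2f} * occupancy + {fit.offset:.2f}   (rss {fit.rss:.1f}, "
      f"n = {fit.n_peaks} peaks)")
print("\nThe estimate sits within a fraction of a kT of the truth; the residual")
print("profile over candidate potentials (fit.grid) dips sharply at the minimum.")
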