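"""Charge-envelope deconvolution round trip on a simulated intact spectrum.

Simulates four heavy-chain proteoforms 18 Da apart (a hydrolysis ladder) as
multiply charged electrospray envelopes with noise, then recovers their
neutral masses.
"""

from adcbiotx.deconvolution import deconvolve, preprocess
from adcbiotx.simulate import SpectrumSimConfig, simulate_spectrum

true_masses = [55455.2, 55473.2, 55491.3, 55509.3]
abundances = [0.3, 1.0, 0.9, 0.35]

spectrum = simulate_spectrum(true_masses, abundances, SpectrumSimConfig(snr=20), seed=6)
peaks = sorted(deconvolve(preprocess(spectrum)), key=lambda p: p.neutral_mass)

print(f"{'true':>10s} {'found':>10s} {'error':>7s} {'intensity':>9s} {'charges':>7s}")
for true, peak in zip(true_masses, peaks):
    print(f"{true:10.1f} {peak.neutral_mass:10.2f} {peak.neutral_mass - true:+7.2f} "
          f"{peak.intensity:9.1f} {peak.n_charges_supporting:7d}")
# Errors are well inside the 3 Da matching tolerance (typically < 0.2 Da),
# and intensities track the simulated abundances.
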