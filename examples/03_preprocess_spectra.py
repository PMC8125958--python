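"""Synthesize NIR spectra and remove scatter with SG + SNV.

Two spectra of the same sample differ only in multiplicative/additive
scatter (packing density, particle size). Savitzky-Golay smoothing plus
the standard normal variate transform makes them coincide, while spectra
of different fatty acid levels stay distinguishable.
"""

from dataclasses import replace

import numpy as np

import ricefusion as rf

sig = replace(rf.default_signature(), noise_sd=0.0, sample_effect_sd=0.0)

s1 = rf.synth_spectrum(15.0, sig, seed=1)   # one scatter realization
s2 = rf.synth_spectrum(15.0, sig, seed=2)   # another
other = rf.synth_spectrum(9.0, sig, seed=3)  # different analyte level

raw_gap = np.abs(s1.intensities - s2.intensities).max()
p1, p2 = rf.preprocess(s1), rf.preprocess(s2)
proc_gap = np.abs(p1.intensities - p2.intensities).max()
analyte_gap = np.abs(p1.intensities - rf.preprocess(other).intensities).max()

print(f"spectrum length: {len(s1)} points, "
      f"{s1.wavelengths[0]:.0f}-{s1.wavelengths[-1]:.0f} nm")
print(f"same sample, different scatter:  raw gap {raw_gap:.4f} AU -> "
      f"after SG+SNV {proc_gap:.2e}")
print(f"different fatty acid (15 vs 9 mg/100 g) after SG+SNV: {analyte_gap:.3f}")
print("\nSNV removes affine scatter exactly; the analyte difference survives"
      "\nbecause the fixed water/starch bands anchor the spectrum's shape.")
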