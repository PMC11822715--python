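"""Estimate the spectral power-law exponent of a recording.

A 1/f^beta background is generated, its persistence spectrum computed,
and the logarithmic model y = a - b ln(x + c) fitted to the summary
curve.  In natural-log power units the slope coefficient b equals beta,
so the reported exponent -b recovers -beta: pink noise (beta = 1) gives
an exponent near -1, the signature of operation near criticality.
"""

import numpy as np

import protospike as ps

n = 100_000
for beta in (0.5, 1.0, 1.5):
    noise = ps.generate_pink_noise(n, beta=beta, rms=1.0, seed=42)
    trace = ps.VoltageTrace(np.arange(n) * 1.0, noise)
    exponent = ps.persistent_spectrum_exponent(trace, window_length=1024)
    print(f"beta = {beta:3.1f}  ->  fitted exponent {exponent:+.3f}  (expected {-beta:+.1f})")

# The dB-scale fit itself (as reported for lab recordings):
trace = ps.VoltageTrace(np.arange(n) * 1.0, ps.generate_pink_noise(n, 1.0, 1.0, seed=42))
_, curve = ps.persistence_spectrum(trace, window_length=1024, summary="mean")
keep = curve.frequency > 0
fit = ps.fit_log3p1(ps.SpectrumCurve(curve.frequency[keep], curve.magnitude_db[keep]))
print(f"dB-scale Log3P1 fit: a = {fit.a:.2f} dB, b = {fit.b:.3f} dB/ln(Hz), "
      f"R^2 = {fit.r2:.3f}")
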