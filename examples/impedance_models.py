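"""Model an impedance spectrum with Exp3P2 and the Randles circuit.

The empirical Exp3P2 magnitude model is solved exactly (it is linear in
its parameters after taking logs); the Randles equivalent circuit is
fitted by complex least squares with an analytic Jacobian.  The Nyquist
transform (Re Z, -Im Z) exposes the charge-transfer semicircle.
"""

import numpy as np

import protospike as ps

# --- Exp3P2: exact log-linear solve -------------------------------------
reported = ps.Exp3P2Params(a=9.16432, b=-1.13394e-6, c=-5.30867e-13)
f_lin = np.linspace(0.0, 1e6, 50)
z_mag = ps.exp3p2(reported, f_lin)
fit = ps.fit_exp3p2(f_lin, z_mag)
print(f"Exp3P2 recovered: a = {fit.params.a:.6f}, b = {fit.params.b:.5e}, "
      f"c = {fit.params.c:.5e} (R^2 = {fit.gof.r2:.6f})")

# --- Randles circuit ----------------------------------------------------
circuit = ps.RandlesParams(Rs=1.48e3, Cdl=6.95e3, Rct=9.95e4, Zw=1.23e4)
f = np.geomspace(1e-2, 1e5, 60)
spectrum = ps.generate_impedance_spectrum(circuit, f)
rfit = ps.fit_randles(spectrum)
print(f"Randles recovered: Rs = {rfit.params.Rs:.4g} ohm, "
      f"Cdl = {rfit.params.Cdl:.4g} F, Rct = {rfit.params.Rct:.4g} ohm, "
      f"Zw = {rfit.params.Zw:.4g} ohm s^-1/2")

# Nyquist points for a textbook semicircle (no diffusion, modest Cdl):
semi = ps.generate_impedance_spectrum(ps.RandlesParams(100.0, 1e-5, 500.0, 0.0),
                                      np.geomspace(1e-1, 1e5, 9))
for re, minus_im in ps.nyquist(semi):
    print(f"  Re Z = {re:8.2f}  -Im Z = {minus_im:8.2f}")
# The locus is the semicircle of diameter Rct centred at Rs + Rct/2.
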