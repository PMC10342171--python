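"""Clonogenic survival vs irradiation depth: synthetic series, linear fit,
and the linear-quadratic dose-equivalent of the observed variation.

Emulates the measured design: 18 survival fractions over 15–33 mm at a fixed
5 Gy dose, with Gaussian measurement noise (SD 0.03) around a linear depth
response anchored at SF = 0.16 at the beam's R50 (24.2 mm).
"""
from iortmc import survival

series = survival.generate_synthetic_sf(seed=11)
fit = survival.fit_depth_response(series)

print(f"fitted slope     : {fit.slope:+.4f} SF/mm (truth -0.0070)")
print(f"Pearson r        : {fit.pearson_r:.3f} (p = {fit.p_value:.2g})")
print(f"SF at 15 mm      : {fit.predict(15.0):.2f}")
print(f"SF at 33 mm      : {fit.predict(33.0):.2f}")

lq = survival.LQParams(alpha=0.30, beta=0.02)
print(f"LQ survival at 5 Gy: {survival.lq_survival(5.0, lq):.3f}")
for sf in (0.22, 0.10):
    d = survival.lq_equivalent_dose(sf, lq)
    print(f"  SF {sf:.2f} corresponds to an LQ dose of {d:.2f} Gy")
print(
    "The measured SF drop across the depth range is equivalent to raising"
    " the dose by roughly 1.5 Gy at fixed depth: spectral degradation alone"
    " changes the biological effect even at constant absorbed dose."
)
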