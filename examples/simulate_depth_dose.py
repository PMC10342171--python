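"""Simulate the depth-dose curve of the nominal 6 MeV beam and read off R50.

The bundled source spectrum (main peak near 6.5 MeV plus a broad ~4 MeV
component) is transported through a water phantom with the condensed-history
engine; the resulting percentage depth dose is normalized to 100% at its
maximum and the distal 50% depth (R50, the standard electron-beam energy
index) is interpolated.
"""
from iortmc import beamfit, transport

spectrum = beamfit.nominal_6mev_spectrum()
curve = transport.compute_pdd(spectrum, n_primaries=6000, seed=1)
r50 = transport.r50(curve)

print(f"source: {spectrum.label}, mean energy {spectrum.mean_energy:.2f} MeV")
for d in (9.0, 15.3, 24.0, 30.0):
    dose = float(curve.dose_percent[abs(curve.depth_mm - d).argmin()])
    print(f"  dose at {d:5.1f} mm: {dose:6.1f} % of maximum")
print(f"R50 = {r50:.2f} mm")
print(
    "R50 is the depth where the dose falls to half its maximum; for this"
    " clinical beam it sits near 24 mm, so cells placed between 15 and 33 mm"
    " span the steep distal gradient."
)
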