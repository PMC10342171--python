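"""The full two-step experiment in silico: transport the nominal beam to the
three cell positions, resolve collision-level detail in the cell layer,
scale every position to the same 5 Gy absorbed dose and compare the
molecular damage.
"""
from iortmc import pipeline

config = pipeline.RunConfig(
    positions_mm=(15.3, 24.0, 30.0),
    dose_gy=5.0,
    n_primaries_transport=4000,
    seed=1,
    outdir="pipeline_output",
)
report = pipeline.run_pipeline(config)

print("position  E(cell)/primary  dissociations/primary  relative damage @5 Gy")
for res, summary in zip(report.positions, report.relative_damage):
    e = res.dose_report.energy_per_primary_mev["cell_layer"]
    print(
        f"{res.position_mm:7.1f}   {e:12.5f}     {res.summary.counts_per_primary:16.1f}"
        f"     {summary.relative_damage:14.4f}"
    )
print(
    "\nDeeper positions need more electrons for the same 5 Gy (the beam is"
    " attenuated), and each deposited eV produces slightly more dissociative"
    " events (the spectrum is softer), so the damage at fixed dose rises"
    " with depth — the same trend the clonogenic assay shows."
)
print(f"reports written to {config.outdir}/")
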