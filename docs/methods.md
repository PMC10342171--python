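# Methods

## The model in one paragraph

A clinical "nominal 6 MeV" electron beam is represented by an energy
spectrum on a 0.5–7.5 MeV grid. A condensed-history engine transports it
through a layered water phantom (water / 10 nm interface water / 20 µm cell
layer / 3.8 mm methacrylate insulator / chamber region), scoring depth dose
and per-region energy deposits; an event-by-event engine resolves every
collision of electrons below 10 keV in liquid water. Molecular damage is
the count of dissociative inelastic events (ionization, electronic
excitation incl. neutral dissociation, vibrational excitation, attachment)
induced in the cell layer per incident electron, scaled to the number of
electrons needed to deliver a fixed 5 Gy there, and compared across
irradiation depths and against the depth response of clonogenic survival.

## The cross-section dataset

The per-channel integral cross sections bundled with the package are an
analytic stand-in, not a measured compilation. Shapes are the standard
families for each process — screened-Rutherford elastic with an
energy-dependent screening parameter, Born-type tails
(1 − E_th/E)^p · ln(1 + E/b)/(E/b) for the inelastic channels, a bounded
Gaussian resonance (5–12 eV, peak 8.2 eV) for dissociative attachment —
anchored at the channel thresholds: rotational ≈0 (0.015 eV quantum),
vibrational 0.2 eV, electronic excitation 4.5 eV, neutral dissociation
8 eV, single ionization at the liquid-phase IP 10.79 eV (the gas-phase
value is 12.8 eV), double ionization 2·IP, K-shell 540 eV.

The free normalizations were calibrated once, with the deterministic
estimator described below, against four independent anchors and then
frozen:

1. the implied collision stopping power n·Σσᵢ⟨ΔEᵢ⟩ at 10 keV matches the
   Bethe value for water (22.6 vs 22.56 MeV/cm);
2. a full 6 MeV slowdown produces ≈2×10⁵ electronic-level inelastic
   collisions (model: 2.1–2.5×10⁵ depending on estimator detail);
3. ≈80% of those are ionizing (model: 0.80–0.83);
4. the mean initial energy of ionization secondaries is ≈10 eV
   (model: 12.5 eV, the mean of the offset-exponential loss continuum).

Tests that depend on the dataset are designed to be robust to this
substitution; any dataset in the documented text exchange format
(metadata block + `channel,energy_eV,sigma_1e-16cm2` table) can replace it.

Per-channel energy-loss models: rotational loses a constant 0.015 eV (the
300 K average; a 0.012 eV literature average is kept as metadata only);
vibrational and electronic excitation use discrete weighted lines (0.2/0.45
eV and 7.4/9.5/11.5 eV); single ionization loses IP + W with W exponential
(mean 12.5 eV) truncated at (E − IP)/2; double ionization draws a Gaussian
near 70 eV and shares the pool above 2·IP uniformly between two ejected
electrons; the K-shell channel draws a Gaussian centred at 535 eV and
ejects a secondary only when the loss exceeds the 540 eV binding (draws
below it are scored as inner-shell excitation — the channel models
excitation and ionization jointly, and no Auger relaxation follows);
attachment captures the electron and deposits its kinetic energy.

Angular sampling: elastic deflections follow the screened-Rutherford shape
with η(E) = 5/E + 10⁻⁵ (quasi-isotropic at eV energies, forward-peaked at
keV). Inelastic deflections raise that density to the power 1 − ΔE/E, so a
glancing loss scatters like an elastic collision and a full-energy loss is
isotropic; the inverse CDF is closed-form in cos θ. Ejected electrons
leave at the azimuth opposite the scattered primary with the polar angle
that balances the two outgoing transverse momenta (non-relativistic
binary-encounter convention; the molecule absorbs the longitudinal
remainder).

## Event-by-event engine

Free paths are exponential in 1/(nσ_tot); channels are selected with
probability σᵢ/σ_tot; electrons terminate by attachment, by escape from the
scoring slab, or by thermalization below 25 meV (the residual is deposited
locally). A scalar `step` advances one electron per event; `run_tracks`
advances the whole alive population per iteration with array operations and
is bit-reproducible for a fixed seed. Energy is conserved exactly per step
(checked to 10⁻⁹ relative) and per completed cascade (10⁻⁶), and electron
number closes exactly (thermalized + attached + escaped = primaries +
secondaries).

### Degradation-spectrum estimator

`CollisionDensity` computes expected per-channel event counts for a full
slowdown without sampling. It is a hybrid Spencer–Fano-style recursion on a
log energy grid: channels whose mean loss is small against the local grid
slice are integrated continuously (events per slice = σᵢΔE/Σσⱼ⟨ΔEⱼ⟩), while
larger discrete losses are treated as point events with explicit landing
energies, which respects jumps across structured regions (the attachment
window) and terminal events (attachment, landings below the thermal
cutoff). Secondary cascades enter through quantile-quadrature averages of
the already-computed counts at the secondary energies. Above the 10 keV
table ceiling, channel-to-stopping ratios are frozen at their first-Born
values except the K-shell/valence ratio, which keeps its Born
ln(E/B_K)/ln(E/B_val) growth. The estimator agrees with both transport
engines within ~5% per channel at 0.003–1 keV; the suite asserts 10%.

That K-shell growth is also the mechanism behind the damage-vs-depth trend:
a K-shell event converts ~540 eV into a single event where valence
ionization would convert it into ~25, so faster electrons produce slightly
fewer dissociative events per eV deposited, and a depth-softened spectrum
produces more. The effect is small (≈+1–4% at 30 mm vs 15.3 mm at equal
dose in this model) but strictly monotone in the spectrum's softness.

## Condensed-history engine

Steps are capped at 2% fractional energy loss. Continuous loss uses
restricted Bethe collision stopping (losses above the 10 keV δ-threshold
removed; Sternheimer density correction with the standard water
parameters); δ-rays are sampled from the leading 1/W² Møller term between
10 keV and E/2, stacked, and transported by the same scheme. Straggling is
Gaussian (Bohr variance) clipped symmetrically to [0, 2·mean] — the
symmetric clip keeps the mean loss unbiased even where the per-step width
rivals the mean, which matters: a one-sided clip shortens the 2 MeV range
by ~16%. Multiple scattering is Highland's θ₀ applied at a random hinge
inside each step, with the logarithmic term evaluated at the electron's
residual-range scale rather than per substep (per-substep evaluation
systematically under-scatters). Radiative loss (≈S_col·E·Z/800) is scored
as lost but not transported; the insulator is density-scaled water at
1.19 g/cm³. Electrons below 10 keV deposit their residual where they stop,
scored separately as track-end energy.

This scheme reproduces the water CSDA range (3.04 cm at 6 MeV), stopping
power at 1 MeV within 1%, and monoenergetic R50 values within ~2% of the
ICRU E = 2.33·R50 rule over 4–7.5 MeV (2 MeV is ~8% short); the overall
accuracy claim is ~5%, and tests use windows consistent with that.

## Bundled beam spectrum

The accelerator spectrum is not measurable directly, so — exactly as in the
source experiment — it is *fitted*: here a two-Gaussian family, a main
peak at 6.5 MeV (σ 0.35) and a broad component at 4.0 MeV (σ 0.8), with
the mixture weight (0.49/0.51) calibrated once so that the simulated curve
reproduces the two measured observables: R50 = 24.2 mm and the ~0.0039 MeV
per-primary deposit in the 20 µm cell layer at 15.3 mm. These parameters
are study conditions shared by tests, examples and the acceptance script.
`beamfit.fit_source_spectrum` performs the general unfolding (NNLS on
simulated monoenergetic columns, optional second-difference smoothing for
grids finer than 0.5 MeV, full-curve or three-depth calibration modes);
refitting this package's own simulated curve recovers a dominant component
at 6.5 MeV with a low-energy shoulder.

## Two-step pipeline

Step one transports the spectrum to each position of interest, scoring
region deposits and the degraded primary spectrum. Step two resolves
collision detail in the scoring layers: ionization secondaries born in the
10 nm interface layer (rate = interface deposit × ionizations-per-eV;
energies from the W continuum) are transported event by event through the
interface and cell layers, while events induced by fast electrons crossing
the 20 µm layer are accounted by the collision density — events per eV
degraded, cascades included — weighted over the depth spectrum's dose
contribution, with track-end deposits weighted at a 5 keV reference. This
bridge keeps the event-by-event engine inside its ≤10 keV validity; fully
event-by-event treatment of MeV primaries is out of scope at desk scale.

The 5 Gy condition is applied as post-hoc scaling: dose per primary in the
cell layer (mass = thickness × density over a 1 cm² reference area; the
per-primary results are area-independent) gives
n_required = D·m/(E·1.602×10⁻¹³), and damage counts scale linearly.
Reported uncertainty combines MC statistics with a cross-section systematic
in quadrature.

## Synthetic data

No measured datasets ship with the package; `iortmc.fixtures` generates
stand-ins:

* **survival series** — SF(d) = 0.16 − 0.007·(d − 24.2) + N(0, 0.03²),
  18 depths evenly spaced over 15–33 mm (optionally grouped into sessions
  sharing a common depth, with optional multiplicative session factors,
  default off). This emulates the assay's depth design and reproducibility
  scatter but not plating-efficiency drift, colony-counting bias or
  dose-delivery errors — parameter-recovery results show the fitting
  machinery is unbiased at the study's noise level, not that real assays
  are.
* **measured-like PDD** — the simulated nominal-beam curve with a single
  affine depth rescale pinning the interpolated R50 to exactly 24.2 mm
  (synthetic; emulates a scanned ionization-chamber curve for a beam of
  known R50).
* **toy cross-section table** — a coarsened copy of the bundled set for
  fast I/O tests.

## Numerical choices and edge cases

Cross-section interpolation is log–log linear (the tables span decades),
bit-exact at grid nodes, zero below threshold, and refuses extrapolation
above the tabulated range unless the channel is closed there (trailing
zero, e.g. the attachment window). Channel probabilities renormalize to 1
within 10⁻¹²; an energy above the track-structure range raises an error
directing the caller to the condensed-history stage. Neutral dissociation
built by difference clips negative remainders to zero with a logged
warning. R50 uses the distal linear interpolation of the 50% crossing and
fails loudly if the curve never crosses. The survival normalization
requires every session to contain a record within ±0.3 mm of the common
depth and preserves Pearson r exactly (positive scaling). Degenerate LQ
inversions (SF ≤ 0 or > 1, α = β = 0) raise.

## Problem sizes

Defaults are desk-scale: 4–10×10³ condensed-history primaries per transport
(statistical noise ~1–2% on region deposits; R50 jitter < 0.3 mm), 10³–10⁴
event-by-event primaries below 10 keV, 200 replicates for survival
parameter recovery. All randomness flows from a single seed per run;
outputs carry a manifest (seed, configuration hash).

## Known limitations

No photon transport (bremsstrahlung is scored, not followed), no chemical
stage or DNA-geometry damage model, no lateral dose profiles or
applicator/collimator modelling, no ionization-chamber response. "Molecular
damage" counts dissociative *events*, not confirmed dissociations — a
per-channel dissociation-probability hook exists with default 1, so only
relative comparisons across positions are meaningful. The K-shell channel
carries the spectral-softening mechanism in stylized form; its
non-monotone behaviour across positions mirrors the underlying physics but
its absolute share of the stopping power (several percent) is a stand-in
choice. Position 2 (24 mm) sits so close to position 1 in damage-per-dose
(< 1%) that desk-scale statistics cannot resolve its ordering; only the
15.3 → 30 mm contrast is statistically meaningful.
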