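# Methods

This note documents the model behind `pefros`: what is simulated, which
parameters matter, what the defaults are and why, what the synthetic data do
and do not emulate, and the numerical choices.

## System and scope

The modelled system is a parallel-plate treatment chamber (2.00 mm gap, 26 mm
electrode diameter, 5.31 cm² cross-section, 1.06 mL) filled with either
phosphate buffer (PB) or 0.6 mM bovine serum albumin (BSA), both at
conductivity 0.033 S m⁻¹ and pH 7.2, optionally with H₂O₂ (0.1–10 mM),
catalase (3.2×10⁻⁸ M) or superoxide dismutase (9.9×10⁻⁸ M), with 0.3 mM
dissolved O₂ and, in albumin samples, ~4 µM protein-bound iron. The pulse
protocol is 30 rectangular 1470 V pulses of 100 µs at 1 Hz, applied from 60 s
to 90 s of a monitored luminescence time course.

Out of scope by design: spatially resolved field maps, ozone chemistry and
¹O₂ + protein reactions, residue-resolved protein chemistry, pH dynamics,
gas-bubble nucleation, electrode passivation/dissolution, and PMT dead-time
effects.

## Reaction network

The default table (`src/pefros/data/reactions.tsv`) holds 29 labelled
reactions over 21 species in six groups: anodic electrooxidation (stepwise
water oxidation 1–4 with HO· and HO₂· intermediates, H₂O₂ electrooxidation
10, protein electrooxidation 14), bulk ROS chemistry (disproportionations
5a/5b/6/7, Haber–Weiss 12/13), emission steps (8, 9, 18), protein oxidation
(15–17), Fenton cycling (19/20), enzymatic removal (21/22) and cathodic
electroreduction (23–29). Every row carries a provenance string; rate
constants for well-characterised aqueous radical reactions come from the
standard radiation-chemistry compilations (e.g. HO· self-recombination
5.5×10⁹ M⁻¹s⁻¹, HO· + H₂O₂ 2.7×10⁷ M⁻¹s⁻¹, Fenton 76 M⁻¹s⁻¹, SOD
2×10⁹ M⁻¹s⁻¹, CAT 1.7×10⁷ M⁻¹s⁻¹, ¹O₂ decay 2.9×10⁵ s⁻¹). Steps whose
stoichiometry or rate is not established — the ¹O₂-forming branches of the
radical disproportionations, the protein peroxyl fragmentation (17) and its
carbonyl/¹O₂ branching, the dimol emission constant, the protein + HO· rate —
are flagged `assumed` and are plain rows a user can edit; no quantitative
claim of the package rests on them beyond orderings.

Choices that deserve justification:

- **Buffered species.** H₂O, H⁺ and OH⁻ are fixed; they are excluded from
  mass-action products, so all shipped constants are effective constants at
  pH 7.2 (reaction 27 carries an explicitly pH-effective first-order k).
- **Superoxide acid–base pair.** HO₂·/O₂·⁻ (pKa 4.8) is held at its
  equilibrium partition (0.4 % protonated at pH 7.2). The right-hand side
  computes rates from the partitioned pool and redistributes the pair's
  combined derivative with the same fractions, so the states never leave the
  equilibrium ray. This avoids stiff protonation kinetics; an explicit
  kinetics mode can be emulated by adding the two protonation reactions to
  the table.
- **Enzymes.** SOD and CAT operate far below saturation at these loadings, so
  reactions 21/22 use linear k·[E]·[S] laws (kcat/KM regime) — doubling the
  substrate doubles the flux, which the tests assert. The stoichiometry is
  written per substrate event (fractional products) so the rate law equals
  the substrate consumption flux exactly.
- **Haber–Weiss (reaction 12).** The uncatalysed O₂·⁻ + H₂O₂ → HO· rate
  (0.13 M⁻¹s⁻¹) renders the superoxide branch numerically invisible, which
  contradicts the observed protective effect of SOD in iron-bearing protein
  samples. The default is therefore a trace-metal-catalysed effective value
  (10³ M⁻¹s⁻¹, flagged `assumed`); the uncatalysed constant is one
  `network.with_rate("12", 0.13)` away.
- **Emission.** Reaction 8 (¹O₂ monomolecular decay, 1278 nm) lies outside
  the detector's response and never produces counts; reaction 9 (dimol,
  634 nm) and 18 (triplet carbonyl, 425 nm) carry placeholder photon yields
  (φ = 1 and 10⁻², configurable). Because absolute photon yields per event
  are unknown, **only relative and ordering statements about simulated counts
  are supported**; absolute count calibration is explicitly not.

## Compartments, sources and transport

Three well-mixed boxes: anode layer (thickness δ = 100 nm, motivated by the
sub-microsecond lifetime and tens-of-nanometres diffusion length of HO·),
bulk, cathode layer. Small species exchange between each layer and the bulk
with first-order coefficient k_ex = D/(δ·L_d), where L_d = 30 µm is a
boundary-layer length of order √(D·1 s): the concentration gradient driving
escape from a nanometric reaction layer develops over the diffusion length to
the bulk, not over δ itself (using D/δ² would flush every layer species into
the bulk within microseconds and erase the confinement the three-box model
exists to express). Macromolecular species do not exchange: protein carried
to the anode is treated as retained there (adsorbed multilayer), entering the
layer only through the explicit electromigration flux μEc_bulk, whose
integral reproduces the 1.85×10⁻⁵ mol m⁻² accumulated over the pulse train
(~470 close-packed monolayers). A single-box mode exists for oracle tests.

The pulse current is rectangular with ohmic amplitude σAU/d (12.9 A;
a measured-current constant mode is available). At each electrode it is
partitioned among parallel channels with competition weights; Faraday's law
converts each channel's share into a molar source confined to its layer. The
weights are the model's genuinely free parameters — the interfacial partition
is not identifiable from photon counts — and the defaults were fixed once,
on mechanistic grounds, at: water→O₂ channel weight 1 (a steel anode converts
almost all charge to ground-state O₂), ROS-escape channel (HO· release)
0.005, H₂O₂ electrooxidation weight 300·[H₂O₂] M⁻¹, protein electrooxidation
0.1·[BSA]ₗₐᵧₑᵣ M⁻¹. Cathodic channels (H₂ evolution, O₂ and H₂O₂ reduction)
are simulated but their products are never photon-visible (the cathode faces
away from the detector). Every trajectory's metadata records the weights used.

With these defaults the simulator reproduces the qualitative experimental
fingerprint: buffer-only runs give a small flat pulsing-phase signal (dimol
emission from electrogenerated radicals); adding H₂O₂ to buffer raises it
severalfold; albumin alone gives a rising pulsing-phase signal (protein
accumulation); albumin + H₂O₂ shows elevated pre-pulse emission (Fenton),
a pulsing signal exceeding the sum of the albumin-only and buffer+H₂O₂
signals (synergy of electrogenerated ROS with accumulated protein), a strong
post-pulse residual, monotone nonlinear H₂O₂ dose–response, reduction by
catalase, and a superoxide-dismutase effect concentrated in the pulsing and
early post-pulsing periods. These orderings, not absolute magnitudes, are
what the acceptance checks assert.

## Detection and analysis

Expected counts per 1 s bin are bin·(dark + collection·Σ QE_band·rate_band)
with dark = 21 counts/s, collection = 0.01 (a single scalar absorbing solid
angle and cathode-perforation transmission; not fitted), QE = 12.2 % in
300–550 nm and 0.55 % in 550–650 nm. The quantum-efficiency correction
inverts this map per band after dark subtraction and is exact by
construction. Window integrals sum raw counts (no dark subtraction) over the
first 30 s of each period; the default windows are pre [30, 60) s, pulsing
[60, 90) s, post [90, 120) s — the pre/post windows are placed symmetrically
around the pulsing block and are configurable. Replicate spread uses the
sample (n−1) standard deviation. The assay calculators are the inverse
Beer–Lambert maps with ε = 14150 M⁻¹cm⁻¹ (Ellman, 1 cm path) and
ε = 22 mM⁻¹cm⁻¹ (Brady, 0.2893 cm path).

## Synthetic data

The generator emulates the experiment's structure: 1 s bins over 0–150 s
(configurable to the full 0–500 s), pulsing at 60–90 s, a 21 counts/s dark
floor, Poisson counting noise, and replicates, all driven by one seeded
generator stream (fixed seed ⇒ byte-identical output). Expected curves come
either from the simulator (end-to-end tests) or from fast parametric
templates — piecewise shapes per scenario: flat (buffer) or saturating-rise
(albumin) pulsing segments, constant-or-decaying pre segments, exponential
post-pulse relaxation back to the pre-pulse baseline, with amplitudes ordered
bsa_h2o2 > bsa > pb_h2o2 > pb and enzyme modifiers that shrink the
H₂O₂-dependent components. The templates decouple analysis testing from
kinetics tuning. Not emulated: instrument drift, cosmic-ray spikes, dark-count
autocorrelation, afterpulsing. Passing tests on synthetic data therefore
validate the *pipeline arithmetic* and the *mechanism's qualitative
structure*, not quantitative agreement with any measured transient.

## Numerics

- Stiff integration at rtol 10⁻⁶, atol 10⁻¹⁵ M (counters get their own
  absolute tolerances). The time axis is split at pulse edges so the
  rectangular sources are exact; during pulses the step is capped at
  pulse_width/10. Source-free segments use BDF with an analytic Jacobian
  (mass-action + exchange + equilibrium redistribution, verified against
  finite differences); pulse segments use LSODA with finite differencing,
  because the channel-competition weights are only piecewise smooth in the
  local concentrations.
- Emission is integrated as cumulative event counters inside the ODE state,
  so per-bin expected counts are exact regardless of how spiky the emission
  is during 100 µs pulses.
- Negative concentrations: values are clipped to zero inside rate
  evaluations; after each segment the state is clipped, and the run aborts if
  any state undershoots below max(10⁻⁹ M, half its own historical peak) —
  stiffly decaying radicals legitimately undershoot by a fraction of their
  tiny scale, while true divergence still trips the guard.
- The water viscosity–temperature correlation used by the current-rise
  thermometer is a Vogel-type fit (A·exp(B/(T−C)), A = 0.02939 mPa s,
  B = 507.88 K, C = 149.3 K), valid 0–60 °C; conductivity is taken
  proportional to 1/η (Walden), and the inverse map is solved by bracketed
  root finding (round-trips to < 0.01 K).
- Electromigration displacement is capped at the electrode gap; the
  cumulative delivered protein is capped at c_bulk·gap.

## Problem sizes

The shipped study conditions simulate the full 30-pulse protocol over a
150 s time course for eight scenarios; a full mechanism study takes a few
minutes on a laptop core. Unit and oracle tests use reduced protocols
(≤3 pulses) and sub-networks of ≤3 reactions, where the stiff solver is
cross-checked against closed forms (to 10⁻⁶ relative) and a fixed-step RK4
reference (to 0.1 %). Poisson-statistics checks use 200 replicates (window
recovery within 2 %) and ≥10⁴ bins (variance/mean within 10 %).

## Known limitations

- Absolute photon counts are arbitrary to within the placeholder photon
  yields and collection factor; only orderings and ratios are meaningful.
- The electrode-channel weights and δ are assumptions, reported in trajectory
  metadata, not fitted to data.
- The three-box geometry cannot represent concentration profiles within the
  diffusion layer; the boundary-layer exchange length L_d is a single
  effective parameter.
- Pre-mixing history is not simulated: runs start at t = 0 with the nominal
  composition, whereas in a real protocol reagents are mixed minutes before
  monitoring starts, so early pre-period transients differ in shape.
- The acid–base equilibrium treatment of HO₂·/O₂·⁻ is exact only at fixed pH;
  pH excursions in the electrode layers are not modelled.
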