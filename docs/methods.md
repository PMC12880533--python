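# Methods

`thermoflow` is a desk-scale digital twin of a multilayer calorimetric
blood-flow sensor: a heated disk on the skin surface, pairs of
upstream/downstream thermistors in two vertically separated layers, and a
reference thermistor per layer placed off the vessel track.  Flow carries
heat downstream (an asymmetry that grows with flow rate), while vessel depth
controls how much of the injected heat the vessel absorbs and how the
pattern differs between the two layers.  A neural regressor inverts the six
temperatures for flow rate and vessel depth simultaneously; a second stage
fuses the recovered flow sequence with a PPG waveform for continuous blood
pressure estimation.

## Forward thermal model

The phantom is a PDMS block with an embedded cylindrical water channel
(2.5 mm bore), a copper actuator disk on the top surface, and a conducting
air gap above the surface containing the elevated sensing layer.  Steady
and transient heat transport are solved by a cell-centered finite-volume
method on a uniform voxel grid:

* diffusion with harmonic-mean face conductivities (exact for layered
  media, which is why the 1-D composite-slab oracle is matched to <0.5%);
* first-order upwind advection in the channel with a prescribed plug
  (default) or parabolic velocity profile — momentum is not solved;
* boundary conditions: insulated lateral faces, fixed bottom temperature
  (25 °C default), convective top surface (h = 15 W/m²K default), fixed
  inlet temperature with advective inflow, zero-diffusive-flux outflow.
  The inlet condition is upwind-consistent (applied only when fluid enters)
  so a zero-flow channel has mirror-symmetric ends; this makes the
  zero-flow upstream/downstream symmetry exact rather than approximate.
* the actuator is a volumetric source distributed uniformly over the
  copper cells.  The disk has a fixed physical thickness of 0.5 mm so that
  grid refinement does not move the heat source.

The linear systems are solved by ILU-preconditioned BiCGSTAB with a sparse
direct fallback; the relative residual is checked against 1e-8.  Because
the discretization is conservative, the global energy-closure check
(actuator power vs boundary losses plus net advected enthalpy) closes to
machine precision; the 2% tolerance in the energy-balance check is a
safety margin, not an observed error.

Material properties: PDMS k = 0.16 W/mK, c_p = 1460 J/kgK; water
k = 0.6 W/mK, c_p = 4184 J/kgK; copper k = 400 W/mK, c_p = 385 J/kgK.
Densities (not part of the benchtop description) use handbook values
965 / 1000 / 8960 kg/m³.  The interlayer air gap is modeled as still air
(k = 0.026 W/mK): at a 1.5-mm gap the Rayleigh number is far below the
convection threshold.  The silicone tubing wall is ignored by default (the
conjugate model lists only PDMS/water/copper) but is available as an
annulus for sensitivity sweeps.  The acrylic supports are omitted (thin,
lateral, low thermal impact).

### Domain and resolution

The full 80 x 90 mm phantom is thermally far-field; the model uses a
reduced 30 x 20 x 10 mm block around the actuator with insulated
truncation faces.  The default grid spacing is 0.5 mm, chosen so one
steady solve runs in seconds on a single core; halving the spacing changes
the six probe temperatures by under 1%.  Temperature *rises* above
ambient converge more slowly (first-order upwind), which matters mostly at
the highest flows; this fidelity limit is discussed under "Known
limitations".  Channel and actuator cross-sections are rasterized by
subsampled area coverage (a cell joins a region when covered ≥ 50%),
keeping the voxelized flow area within 10% of the true circle and the
geometry symmetric about the flow axis.

### Coordinates and probes

Right-handed frame, x along the flow, z up, origin at the actuator center
on the top surface; lengths in mm.  Vessel depth d is measured from the
top surface to the *top* of the channel — for a 2.5-mm vessel inside a
phantom only a few mm thick, "depth from the surface" can only mean the
cover thickness.  Probes: upstream (-L, 0), downstream (+L, 0), reference
(0, L) per layer, with L = 3.5 mm; the bottom layer sits on the surface
plane (z = 0) and the top layer at z = H = 1.5 mm.  Probe values are
trilinear interpolations of cell-center temperatures.

## Sensor front end

The electrical chain is a standard NTC beta model (R0 = 10 kΩ at 25 °C,
B = 3380 K — a typical value for this thermistor class; the part's data
sheet coefficient is configurable), Wheatstone half-bridge pairs with a
differential amplifier (3.3 V supply, 10 kΩ fixed arms, gain 100 —
plausible defaults for the named components), an exponential moving
average with smoothing coefficient 0.05 (a "moving average filter with a
smoothing coefficient" admits only the EMA reading), and decimation of the
20 Hz stream to 1 Hz by non-overlapping 20-sample means.

Three feature modes feed the network, all six-wide:

* `temperature` (default): the six filtered probe temperatures;
* `bridge`: amplified bridge voltages — per layer, up and down against the
  same-layer reference plus the down-vs-up calorimetric differential;
* `diff`: the linearized equivalent of `bridge` — temperature
  differentials (up-ref, dn-ref, dn-up per layer).  Because the steady
  heat equation is linear, raising every boundary temperature by the same
  amount shifts the whole field uniformly, so these features are exactly
  ambient-invariant; bridge voltages are only approximately so (the NTC
  sensitivity drops with temperature).  The ambient-robustness study uses
  `diff` as its reference-compensated arm and raw temperatures as the
  uncompensated ablation.

## Synthetic benchtop campaign

The default campaign mirrors the benchtop protocol: depths {1, 1.5, 2} mm
x flows 1..10 mm/s (30 conditions), 50 measurements per condition
(n = 1500); an expanded variant uses 300 per condition (n = 9000).  Each
condition is one cached steady solve; replicates are re-noised draws — the
physical campaign's replicates are repeated measurements, and re-noising
is the desk-scale equivalent.

The replicate noise SD (default 0.002 °C on the filtered features) is a
calibration choice, not a measured quantity: it was set by propagating
i.i.d. channel noise through the condition-grid Jacobians so that the
noise-floor 95th-percentile flow error is of the order of the sensor's
±0.12 mm/s error margin.  It corresponds to roughly 20 mK of raw 20 Hz
sample noise attenuated by the EMA + 1-s-mean chain.

Grouped five-fold cross-validation partitions the 30 *conditions* (never
rows) into five groups of six; each fold trains on 1200 rows and tests on
300, and every row is tested exactly once.  A leakage guard raises if any
condition appears on both sides of a fold.  The default grouping is the
deterministic Latin-square diagonal (fold = depth rank + flow rank mod 5):
every fold spans depths and flows, and every held-out condition keeps both
a same-depth flow neighbor and a same-flow depth neighbor in training, so
the evaluation measures generalization to unseen conditions by
interpolation.  A seeded random condition shuffle is available
(``scheme="shuffled"``); it routinely isolates whole corner neighborhoods
in one fold and then measures corner extrapolation instead, roughly
doubling the pooled error quantiles.

### What the generator does not emulate

Pump pulsation, chamber humidity, phantom fabrication variability, sensor
drift, and contact-resistance variation are absent.  Real replicates
spread around their condition in feature space; re-noised replicates
cluster tightly.  Passing the recovery tests therefore demonstrates that
the pipeline inverts this forward model at the stated noise level — not
that the physical device's error budget is reproduced.

## Inversion network

Six inputs, hidden widths (64, 64, 32), each hidden block
Linear → BatchNorm → ReLU, 10% dropout regularization placed after the
last hidden block, two linear outputs (flow mm/s, depth mm).  Inputs and
targets are z-scored with training-fold statistics only; the loss is
unweighted MSE on the standardized outputs.  Training uses Adam
(3e-3 cosine-decayed to 3e-5, batch 128, 600 epochs) and is bit-reproducible
under a fixed seed.  The default predictor averages an ensemble of five
identically specified networks with different initialization seeds, which
reduces the seed-to-seed variance of the interpolated surface.

Predictions are projected onto the training label box (flow 1..10 mm/s,
depth 1..2 mm on the default campaign): the sensor only reports within its
calibrated range, and since the truth always lies inside the box the
projection can only shrink errors.

Design notes made where the architecture description is underdetermined:
layer count/widths, optimizer, epoch budget and dropout placement are
declared package defaults (the published description fixes only
ReLU/BatchNorm/10%-dropout and the 6-in/2-out contract).  Dropout after
every hidden layer was measured to roughly double the held-out flow error
on this dataset relative to last-block placement, hence the default.

### Honest accounting of recovery accuracy

On the default synthetic campaign the pooled grouped-CV errors are
dominated not by noise but by *interpolation bias at held-out conditions*:
a fold's network never sees the held-out condition and must interpolate
the feature manifold from neighboring conditions 1 mm/s (or 0.5 mm) away.
At the grid corners (f = 1 or 10 with d = 1 or 2 mm) this is partial
extrapolation.  The simulated sensor's sensitivity also saturates at high
flow (adjacent-flow feature separation ~0.03 °C at f = 9..10, d = 2 —
about 60x worse conditioned than at low flow), a combined effect of the
physics at this scale and of first-order upwind smearing that grid
refinement only mildly improves (+11% separation at 0.25 mm spacing for
30x the cost).  Consequently the pooled 95th-percentile flow error of
this twin sits near 0.4 mm/s, several times the physical device's
±0.12 mm/s, and the worst per-flow depth RMSE (~0.09 mm at f = 1 mm/s)
slightly exceeds the device's 0.07 mm bound, while the pooled depth
quantile (~0.05 mm) and the qualitative findings (dual-layer superiority,
ambient compensation, step tracking, sensitivity ordering) are
reproduced.  The same conditioning limit dominates the ambient study's
worst-case statistic: with exactly compensated features the residual
(~0.3 mm/s) is the maximum of 150 noise draws at the worst-conditioned
test flow, two orders of magnitude below the uncompensated ablation.  The
acceptance script reports whatever the pipeline actually measures.

## Ambient robustness

The chamber protocol keeps the supply water at the chamber temperature, so
the elevated-ambient study raises ambient, inlet and bottom temperatures
together (25 → 30/32.5/35 °C).  By linear superposition this shifts the
whole field uniformly; `diff` features are then exactly compensated and
the residual error measures the estimator, while raw-temperature features
shift far out of distribution and fail by orders of magnitude — the
ablation that quantifies what reference compensation buys.

## Dynamic tracking

Step changes in flow (3 → 6 → 9 mm/s) are simulated with implicit-Euler
transients (the system matrix is refactorized only when the flow level
changes), probed at 20 Hz by temporal interpolation, passed through the
EMA/decimation chain and predicted at 1 Hz.  Settling time is the 10–90%
traversal of the prediction between levels; it grows with vessel depth
because the thermal diffusion path through the cover layer lengthens
(PDMS diffusivity ~1.1e-7 m²/s gives a ~10 s scale per mm).

## Sensitivity sweeps

Each sweep perturbs one physical parameter (phantom conductivity, fluid
conductivity/density, wall thickness, channel diameter, wall stiffness,
or external airflow mapped to the convective coefficient
h = 15..40 W/m²K over 0.05..0.2 m/s, since the model has no external air
domain), re-solves, and reports the maximum min-max-normalized reading
change ΔS_N across the six channels.  Vessel-wall stiffness has no
coupling into the heat equations, so its ΔS_N is identically zero — the
negative control.

## Single-layer ambiguity

The six-channel reading vectors of all 30 conditions are separated by more
than the noise SD, but the bottom-layer calorimetric differential
(downstream - upstream), which is what a conventional single-layer sensor
measures, collides across depths: e.g. (d = 1 mm, f = 10 mm/s) and
(d = 1.5 mm, f = 6 mm/s) differ by ~4e-4 °C, far below the noise.  In
this twin the bottom *reference* channel still carries an absolute-level
depth cue that a pristine simulation preserves better than a real skin
measurement would, so the single-layer arm of the ablation is degraded
rather than helpless; the dual-layer arm must still beat it on depth RMSE.

## Blood-pressure fusion

The synthetic cardio generator produces paired records: 1 Hz flow, 128 Hz
PPG, 1 Hz reference SP/DP with one Valsalva maneuver per record (onset
120 s, duration 140 s) expressed as four raised-cosine phases with
default SP offsets (+15, -20, -15, +10) mmHg — generator choices, with DP
following at 0.6 of the SP offset.  PPG beats are two Gaussian lobes
(systolic peak + dicrotic hump) whose amplitude tracks pulse pressure;
flow tracks mean arterial pressure through a coupling gain (0.08 mm/s per
mmHg default; 0 for the spurious-gain control).  Pressure wander is an
AR(1) process with a 20 s correlation time.

The fusion model processes the flow window (10 s at 1 Hz) with a simple
tanh recurrence and the PPG window with two strided 1-D convolutions and
global average pooling; the concatenated embeddings feed a fully
connected head producing SP and DP.  The `ppg_only` baseline is the same
model without the recurrent branch.  Splits are record-level.  Agreement
is summarized by Bland-Altman bias ± 1.96 x SD (ddof = 1) limits.

## Numerical/degenerate-input conventions

Min-max normalization rejects degenerate ranges; a channel that does not
vary over a sensitivity sweep contributes ΔS_N = 0.  Decimation drops
trailing partial blocks and warns on sub-second streams.  Standardization
guards zero-variance columns.  The all-Neumann thermal system (no bottom
temperature, h = 0) is rejected with a message naming the missing anchor.
Seeds: one master seed expands into per-stage seeds through numpy's
SeedSequence spawn keys; every stochastic component takes an explicit
Generator.

## Known limitations

* First-order upwind advection under-resolves the in-channel thermal
  boundary layer at the highest flows; high-flow sensitivity is therefore
  conservative relative to the physical device.
* The probe plane z = 0 interpolates across the PDMS/air interface.
* No momentum solution, no pulsatility, no bioheat/perfusion terms: the
  twin models the benchtop phantom, not tissue.
* BP fusion is demonstrated on synthetic records only; its human-subject
  agreement statistics are out of scope by design.
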