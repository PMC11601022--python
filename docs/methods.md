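# Methods

## Signal model

The ultrasonic flowmeter reports the molar mass of the gas in its
measurement path from the measured speed of sound, `c = sqrt(gamma R T /
MM)`, using a fixed assumed temperature and adiabatic index. The reported
molar mass is therefore confounded multiplicatively by the true gas
temperature and by the composition dependence of gamma, and additively by
water vapour and CO2/O2 shifts. All gas relations in `gas_physics` are
ideal-gas: mixture molar mass and Cp are mole-fraction weighted and
`gamma = Cp / (Cp - R)`. Species constants are CRC/NIST values at 298 K.
Real-gas corrections and vibrational-relaxation effects on sound speed are
out of scope; over 0–45 degC and <8% SF6 they are far below the sensor
noise. Water vapour is an explicit species so the simulator can produce
tidal humidity swings; saturation pressure uses the Magnus formula (error
over 270–320 K is negligible against sensor noise).

## Analysis pipeline

**Breath detection.** Flow zero crossings with a hysteresis band of 2% of
the 95th-percentile |flow|; candidate half-breaths under 2 mL or 0.3 s are
merged into neighbours. End-tidal molar mass is the median over the last 5%
of each breath's expired volume — in a well-mixed lung the alveolar plateau,
and robust to noise. All thresholds sit in `AnalysisConfig` (YAML-round-
trippable); the detector is a documented stand-in, as the original device
software's exact criteria are not public.

**Phase detection** operates on the per-breath end-tidal series, which is
insensitive to within-breath confounders: washin starts at the first breath
rising more than `max(5 * robust pre-phase spread, 0.15 g/mol)` above the
pre-phase median; washout at the first comparable drop from the running
washin maximum. The washin-complete flag requires the last five washin
breaths to lie within 0.5% relative spread — the precondition for using
them as the known-concentration boundary. Analyses of washin-incomplete
recordings abort with a QC error by default.

**Tidal-change correction.** For each boundary condition (0%/max SF6 ×
inspiration/expiration) the contributing breaths (last 5 of the pre-phase,
last 5 washin breaths) are re-indexed by cumulative volume within the
half-breath, bin-averaged on a 1 mL grid and combined by per-bin median
across breaths. 1 mL is roughly VT/30 for the small infant lung model and
balances noise averaging against curvature; it is config-exposed. Washout
samples are normalised linearly between the matching-phase boundary
interpolants. Samples beyond the boundary volume range use the clamped end
value and are flagged; breaths with >10% flagged samples are QC-flagged.
The correction cancels every confounder that is a stable function of
volume-in-breath and phase. What it cannot cancel is the curvature of
reported molar mass in SF6 fraction (gamma falls as SF6 rises, so the
interpolation chord is not exactly the physical curve); in the simulator
this residual contributes about −0.7% to FRC — the analysis treats gamma as
composition-dependent physics it cannot observe, and this is part of the
honest error budget rather than a removable bias.

**Side-chamber correction.** The normalised signal is modelled as
`x = (1 - f) * u_main + f * u_chamber` with `f` the chamber share of the
measurement path. During washout inspirations `u_main = 0`, so each
inspiration's signal is fitted with `a * exp(-v / lambda)` in inspired
volume (first-order flushing by through-flow; the exponential matches the
forward physics and the observed shape). Non-converging fits or fits with
lambda pinned at its bound fall back to a monotone-decreasing isotonic fit
(a small pool-adjacent-violators routine; pulling in a machine-learning
dependency for a fallback path was not warranted). Estimates are
interpolated linearly in time across expirations. The maximum curve is
`alpha + beta * min curve`: `alpha` comes from the first washin inspiration
(main stream already at the tracer fraction, chambers still clean — the
intercept of an `A - B exp(-v/lambda)` fit extrapolated to zero inspired
volume equals `1 - f`), `beta` from requiring the end-of-washin plateau
(both compartments at the tracer fraction) to extract exactly the tracer
maximum. In the matched forward model this gives `alpha = 1 - f, beta = 1`
and exact extraction. A pure multiplicative scaling is config-selectable
for sensitivity analysis. Carry-over below a detection floor of 0.02
normalised units is treated as "no measurable chamber": respirogram binning
artefacts sit near 0.003 and real chambers an order of magnitude higher,
and subtracting a fitted noise pattern would add bias instead of removing
one. Extraction output is clamped to [0, 1.25 * C_max] for reporting, with
the fraction of samples outside the diagnostic band [-0.25, 1.25] * C_max
reported; the *unclamped* trace feeds the conservation integrals, because
clamping at zero rectifies noise into a spurious re-inspired tracer volume
(about −1% FRC at the default noise level).

**Outcomes.** `FRC = net expired SF6 volume / (c_et,initial - c_et,final)
- dead space`, with the net volume integrated at the sensor plane over the
washout through the end-of-test breath and the apparatus dead space
(default 4.6 mL infant, 9.6 mL toddler) subtracted because it is flushed
alongside the lung. The initial end-tidal concentration is the last washin
breath's — equal to the tracer maximum under the washin-complete
assumption and by the anchor construction. End of test is the first breath
whose end-tidal SF6 falls below 2.5% of that initial value (a stricter
three-breath confirmation mode is available; consensus guidelines use it,
the single-breath rule is the default). CEV sums corrected expired volumes
per washout breath through the end-of-test breath; by default one apparatus
dead space per breath is removed so the LCI reflects alveolar gas turnover
(config-toggleable, since conventions differ). LCI = CEV / FRC is asserted
to 1e-9. Volumes are reported at ATP by default, matching the water-bath
validation setup with no body compartment; BTPS mode applies phase-wise
factors (inspired gas at ambient temperature/humidity, expired gas
saturated at a configurable sensor temperature).

**Visit QC.** Hard flags (washin incomplete, clamped fraction > 5%,
washout breath-volume CV > 40%) are machine-checkable stand-ins for visual
quality control. The acceptability rule then requires at least two trials
with both LCI and FRC within 25% of the accepted-set mean; deviating trials
are dropped simultaneously and the means recomputed to a fixed point, which
makes the result independent of trial order. Whether the 25% rule applies
to the outcomes jointly or separately is unspecified in practice; both are
enforced (AND), the stricter reading.

## The simulator

`simulate_recording` is an explicit gas-transport model, not a curve
generator: one or two perfectly mixed compartments with configurable
volumes and ventilation fractions, a shared plug-flow apparatus dead space
(FIFO of gas parcels) between sensor and lung, half-sine flow (square and
harmonic-distorted profiles available), supply switching air -> 4% SF6 ->
air across pre/washin/washout. The sensed gas temperature and water
fraction relax toward phase-specific targets with an 8 mL through-flow
volume constant; the reported molar mass is computed from the true
mixture's speed of sound re-converted with the device's assumed fixed
temperature and dry-air gamma — reproducing the confounding mechanism
rather than its symptom. Side chambers are a lumped first-order state
flushed by through-flow (volume constant 12 mL, 10% share of the measured
signal; a two-time-constant variant stress-tests model mismatch). Gaussian
sensor noise is added to the recorded traces only; gas transport uses the
clean flow, and all tracer amounts are bookkept so conservation holds to
float precision.

Default study conditions mirror the physical validation: bath 32.5 degC
(room temperature 20 degC for the reduced-temperature condition), tidal
temperature amplitude 1 K with humidity swings on, apparatus dead space
4.6 mL, 200 Hz sampling (a typical mainstream ultrasonic rate; the real
device's rate is not public and the reader accepts any uniform rate >= 50
Hz). Noise SDs — 0.02 g/mol molar mass, 0.001 L/s flow — are of the order
of mainstream ultrasonic sensor resolution; the molar-mass SD is ~0.4% of
the 4% SF6 signal amplitude. Washin/washout lengths default to automatic
sizing from the breath-level dilution recursion (washin to 0.1% residual
plus 5 breaths; washout to past the end-of-test threshold plus 6), which
encodes the washin-complete protocol assumption. The ventilation-
inhomogeneity condition splits the model into two equal-volume compartments
ventilated 70/30 — a moderate asymmetry standing in for the grate insert of
the physical model, whose actual ventilation split is not published. The
condition grid (`condition_grid`) is 2 volumes x 5 conditions x 6 seeded
replicates = 60 runs: small FRC 80 mL / VT 30 mL / RR 30 per min, large
210 / 50 / 20, with +66%/+50% rate, 50/80 mL tidal-volume and room-
temperature variants.

What the simulator does *not* emulate: irregular or sighing breathing,
sensor drift and asymmetric (non-Gaussian) noise, CO2-specific sound-speed
relaxation, the real chambers' geometry (their true time constants are
unknown; parameters here are plausible, and the side-chamber claims are
therefore relative — ablations — rather than absolute), and O2/CO2
exchange in the default in-vitro mode (a steady-exchange in-vivo mode
exists). Passing tests show the algorithm is correct under its own stated
assumptions and robust to the modelled confounders at realistic amplitude;
they do not certify accuracy on clinical recordings.

## Numerical choices

Segment-edge samples (first/last 2% of a half-breath's volume) are trimmed
before the chamber fits: they sit inside the detector's hysteresis band and
can carry the neighbouring phase's gas. Exponential fits use bounded
least squares (`a in [0, 2]`, `lambda in [0.5, 500] mL`) with analytic-free
Jacobians via scipy's trust-region reflective solver. Breath-boundary
continuity of the minimum curve holds by construction; degenerate anchor
systems (no measurable carry-over) fall back to the no-chamber limit
`beta = 1` rather than dividing by a near-zero anchor. Respirogram bins no
contributing breath reached are filled by linear interpolation between
valid bins; interpolation beyond the grid clamps to the end bins and flags
the samples. The extraction denominator is guarded at 0.05 (normalised)
and the boundary separation at 0.05 g/mol; both abort with typed errors
rather than amplifying noise.

## Known limitations

* The tracer-fraction nonlinearity of reported molar mass (composition-
  dependent gamma) leaves a systematic FRC residual of roughly −0.7% that
  no self-calibrating linear interpolation can remove.
* Accuracy claims are made on the forward model; the chamber share and
  volume constant of real sensors are unknown, so absolute side-chamber
  performance on hardware is unvalidated.
* The method requires a complete washin at a known tracer fraction and both
  washin and washout phases; washout-only protocols (e.g. N2 washout) are
  out of scope by design.
* Visual quality control is approximated by thresholded automatic flags.
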