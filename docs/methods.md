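# Methods

## Model and assumptions

The biomechanical core is a three-segment seated body: a rigid trunk and
rigid upper legs hinged near the sacrum, with the lower legs on footrests
and therefore outside the seat-borne mass. Coordinates are body-fixed:
x left–right (left negative), y back–front (forward positive), z up, origin
at the trunk/upper-leg hinge. A forward lean rotates the trunk CoM about x
through θ; a lateral lean rotates both seat-borne terms about an axis
parallel to y through the femur at (∓r, 0, 0). The closed-form CoP
displacement magnitudes assume the trunk CoM vector is vertical and the
upper-leg CoM lies along +y at upright; `body_com` makes no such assumption
and is the oracle the closed forms are tested against.

The typeset source from which the lateral closed form derives is internally
inconsistent about one sign; the implementation uses the form in which the
hip-pivot term `(t_m+u_m) r (1−cos φ)` and the trunk term
`|T| t_m cos θ sin φ` reinforce, which is the unique form consistent with
the rotation semantics above (both CoM contributions move toward the lean
side). The reduction to the pure-forward expression at φ = 0 and agreement
with the full kinematic pipeline on random poses are enforced by tests.

The pressure model treats the trunk + upper-leg assembly as a rigid beam of
length L on a surface of uniform elasticity, with the knee end free to sink.
Static force and torque equilibrium with an affine restoring-force density
determine the density uniquely; the ratio of densities at the IT position
before and after a CoM shift gives a proportional IT pressure affine in the
shift. Negative densities (possible at extreme shifts) are clipped at zero;
the analysis only ever uses the first 95% of the pressure reduction, which
the clip cannot reach. Lateral-lean pressure is *not* modeled analytically —
it depends on unverifiable assumptions about spine motion and IT lift-off —
so the trial generator imposes a configurable lateral slope multiplier ≥ 1
on the offloaded side (default 1.45, matching the observed ratio of lateral
to forward population slopes), and a mild positive response on the loaded
side (default gain 0.25 of the forward slope magnitude).

Mass distribution comes from a supine bed-mat frame (2.86 cm cell pitch)
segmented by six landmark rows (calcaneus, mid patella, ASIS, xyphoid,
sternoclavicular joint, vertex). Cells belong to the band of their row;
a landmark row starts the next segment (half-open bands), and the outer
bands extend to the grid edges so segment masses always sum to the frame
total. Segment CoMs are force-weighted centroids, reported relative to the
ASIS row. Whether head mass should fold into the trunk fraction is not
settled; the convenience constructor folds lower torso + upper torso + head
into the trunk term, and the simulator treats `t_m`, `u_m` as free
parameters.

## Synthetic trials

The generator emulates the instrumented wheelchair: a 40 × 40 cm seat pan on
four corner load cells at 125 Hz (corner forces distributed bilinearly in
(x, y) — the unique separable nonnegative scheme exactly inverted by the
corner-centroid CoP formula), a 16 × 16 pressure mat at a nominal 15 Hz
whose clock carries uniform jitter (default ±10% of the period, emulating
acquisition slowdowns), and four IMUs at 100 Hz mounted so upright reads
≈ 90° pitch. Each IT appears as a 2 × 2 hot block whose value is the peak
pressure (default 60 units) times the proportional pressure, floored at the
ambient level (default 2); pelvis and femur channels are scaled copies of
the trunk trajectory (no separate pelvis model is fitted). Lateral trials
ramp φ and θ together (θ = 0.5 φ by default) because sideways leans
incorporate a forward component. Backrest starts prepend a phase in which a
fraction of the seat-borne weight (default 0.25) rests on a 10° reclined
backrest and ramps off, so peak seat pressure occurs at the upright instant,
as the normalization step assumes. A knee-load CoP bias term (default off)
is available to emulate weight transfer through the hands or footrests.

The trajectory defaults — 1 s upright settle, 8 s ramp to 40° forward / 30°
lateral, 2 s hold, 3 s backrest phase, 10 participants × 3 directions × 3
repetitions — mirror a slow, maximal-lean PR protocol. Per-participant
anthropometry is drawn uniformly from ranges spanning adult seated
anthropometry (see `DEFAULT_COHORT_RANGES`), producing theoretical forward
slopes of roughly −0.03 to −0.07 per cm and sine coefficients of ~10–25 cm.
No sensor noise magnitudes are available for the real hardware; the defaults
(load cell 0.5 N, mat 1.0 pressure units, IMU 0.5°) are package choices
stated here, and tests vary them. All randomness derives from one seed;
each trial's RNG is seeded by (seed, CRC32 of its condition), so cohorts
are reproducible trial-by-trial.

What the generator does **not** emulate: cushion deformation mechanics,
spine curvature (the rigid-trunk sine model is exactly true in simulation,
whereas real sternum pitch diverges from pelvis pitch), sensor drift or
slippage, footrest force transfer beyond the optional bias term, and
knee contractures on the bed mat. Passing recovery tests therefore
demonstrate that the pipeline inverts the stated forward model correctly —
not that the rigid-segment model captures every behavior of real leans.

## Estimation pipeline

Per trial: tare the load cells with the pre-transfer frame mean; CoP from
the corner-centroid formula; align the three streams on the mat's
timestamps by nearest-in-time pairing (samples with a gap above 50 ms, or a
nonpositive tared force sum, are dropped with a warning); average each IT's
2 × 2 block; zero angles and the CoP origin on each stream's first 0.5 s.
IT blocks are located per participant by exhaustive 2 × 2 window search on
the static frames of the first forward trial, one block per seat half;
near-ties fall back to persistence (time above half the block's own
maximum) during that trial, then to the lowest (row, col) anchor.

Normalization divides all pressures by the trial's maximum mean-IT pressure
and re-bases the CoP origin and angle zeros at the peak-time sample. The
peak is located and valued on a centered 0.5-s moving average of the
mean-IT trace: a raw single-sample maximum of a noisy trace is biased
upward (it selects the largest noise excursion) and would systematically
flatten every fitted slope; on noise-free data with an upright dwell at
least as long as the window, the two definitions coincide exactly.

Truncation keeps the contiguous prefix from the re-zero instant until the
tracked pressure first covers 95% of its total reduction. The tracked
pressure is the mean of both ITs for forward leans and the offloaded side
for lateral leans (right IT for a left lean and vice versa) — the side the
maneuver exists to unload; this choice is config-overridable. Repetitions
of a condition are pooled as raw samples into one OLS fit (slope,
intercept, R², SE). The trunk-angle model ΔCoP_y = b sin(Δpitch) is fitted
by least squares on the first 90% of samples counted from the re-zero
instant (deliberately a sample-count rule, in contrast to the
95%-of-reduction rule). Thresholds divide the target proportional reduction
by |slope|. Bland–Altman agreement uses differences fitted − theoretical
with limits of agreement mean ± 1.96 SD (the conventional multiplier; no
other value is prescribed).

## Mixed models

Proportional pressure is regressed on CoP magnitude (centered on its grand
mean) with direction — plus cushion, starting position, and participant
type where present — as treatment-coded fixed effects (baselines forward /
air / backrest / AB) and participant as the grouping factor. Fitting is
REML via statsmodels `MixedLM`; the module's own computation is design
construction, AIC/BIC bookkeeping, CI assembly, and slope composition.
Random structures of increasing richness — intercept only, + CoP slope,
+ direction and CoP×direction, and a maximal structure adding every other
CoP interaction present — are compared by AIC and BIC computed from the
restricted log-likelihood as −2 llf + {2, ln n}·k, with k counting fixed
effects, free covariance parameters, and the residual variance (statsmodels
leaves both criteria undefined under REML; only orderings across structures
on identical data are consumed). Confidence intervals are Wald 95%
(± 1.96 SE); reported degrees of freedom are the large-sample residual
approximation n − k_fe. A Satterthwaite approximation is not available in
the Python mixed-model stack; with thousands of samples per cohort the
normal-approximation p-values are adequate for the structure-level
conclusions drawn here, but small-cohort per-term p-values should be read
with that caveat. Non-convergence is flagged on the result, never silent.

## Numerical choices

* g = 9.80665 m/s²; lengths in cm, forces in N, masses in kg; angles in
  degrees at interfaces and radians internally.
* Exact self-consistency checks (and the corresponding acceptance-script
  measures) run the generator noise-free with a 12.5 Hz mat clock,
  commensurate with the 125 Hz load-cell and 100 Hz IMU clocks, so
  nearest-in-time pairing has exactly zero offset; the default 15 Hz
  nominal rate is kept for the study-condition cohort, where the ±2.7 ms
  pairing offset is a property of the instruments, not of the pipeline.
* The beam model's singular denominator is guarded at 1e-12; lean poses are
  validated to |θ|, |φ| < π/2; proportional pressures are clipped at 0.
* Tie-breaks are deterministic everywhere (lowest (row, col) anchor; stable
  sorts in model ranking).
* Synthetic cohort sizes in tests and the acceptance script (10
  participants, 3 × 3 trials each, ~11k pooled samples) were chosen as the
  smallest sizes at which the population analysis is statistically
  comfortable; all complete in seconds.

## Known limitations

* The analytic pressure model covers forward leans only; lateral behavior
  enters through the simulator's multiplier, so lateral recovery tests
  check pipeline consistency, not lateral biomechanics.
* Per-individual human results cannot be reproduced without the original
  raw recordings; published population tables are used only as inputs to
  composition arithmetic and as qualitative structure references.
* The bed-mat mass estimation assumes the body lies flat; raised knees
  shift upper-leg mass toward the hip (a real-data caveat the synthetic
  frames do not exhibit).
* Max-pressure normalization couples all proportional pressures to one
  (smoothed) trace value; residual normalization noise appears as a small
  multiplicative scatter on fitted slopes, visible in the cohort recovery
  measures.
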