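# sipcop

Seat-interface-pressure vs center-of-pressure analysis for wheelchair
pressure-redistribution maneuvers.

## The problem

Manual wheelchair users are at high risk of pressure injuries from prolonged
sitting; clinical guidelines recommend periodic pressure-redistribution (PR)
maneuvers — forward, leftward, and rightward leans — that offload the ischial
tuberosities (ITs). Pressure mats can measure that offloading directly, but
they are fragile and cushion-dependent. A seat pan instrumented with four
corner load cells is robust and cushion-independent, and tracks the seated
**center of pressure (CoP)** instead. `sipcop` implements the model and
estimation pipeline that make CoP displacement a quantitative surrogate for
**proportional seat interface pressure (SIP)** reduction under the ITs, so a
load-cell system can judge whether a lean actually offloads enough.

The package is aimed at rehabilitation-engineering and seating-clinic
researchers: it provides the forward biomechanical model, a synthetic
multirate sensor-trial generator (the stand-in for human trials), the full
estimation pipeline, and the mixed-effects population analysis, all as an
importable library plus a `sipcop` command-line tool.

## The model

A seated user is three rigid segments (trunk, upper legs, lower legs — the
last carried by the footrests) hinged near the sacrum. With trunk CoM vector
**T**, upper-leg CoM **U**, mass fractions `t_m`, `u_m`, and femur offset
`r`, a forward lean rotates **T** about the x-axis through θ and a lateral
lean rotates both terms about the femur axis through φ. On a level seat the
CoP is the vertical projection of the seat-borne CoM, giving the closed-form
displacement magnitudes

    |ΔCoP| = |T| t_m sin θ                                   (forward)
    |ΔCoP| = hypot(|T| t_m sin θ,
                   (t_m+u_m) r (1−cos φ) + |T| t_m cos θ sin φ)   (combined)

Treating the trunk + upper-leg assembly as a rigid beam of length `L` on a
uniformly elastic seat, static force/torque equilibrium with an affine
restoring-force density `f(y) = a y + b` yields

    f(y) = −2 g m [ (3 CoM_y − 2L)/L² − 3 (2 CoM_y − L) y / L³ ]

and hence a *proportional* IT pressure that is affine in the CoM shift, with
per-individual slope

    dp/dΔCoM_y = 3 (L − 2y_IT) / [ 3 CoM_y0 (L − 2y_IT) − L (2L − 3 y_IT) ]

(negative whenever `CoM_y0 < 2L/3`). For a forward lean the CoM shift equals
the CoP displacement, so this slope is directly the SIP–CoP slope a
load-cell system needs. The estimation pipeline recovers the slope per
individual from sensor data; random-slope linear mixed models (REML, AIC/BIC
structure selection) describe the population; and the CoP threshold for a
target offload `q` is simply `q / |slope|`.

## Worked example

```
$ sipcop all --seed 5 --out demo
wrote 90 trials to demo/trials
...
90 trials processed
direction     slope  target    cop_cm
  forward -0.055329     0.8 14.459032
  forward -0.055329     0.9 16.266411
     left -0.080358     0.8  9.955473
     left -0.080358     0.9 11.199907
    right -0.080321     0.8  9.959993
    right -0.080321     0.9 11.204992
```

This simulates a 10-participant synthetic cohort (3 directions x 3
repetitions), runs the estimation pipeline (taring, CoP from corner forces,
nearest-in-time stream alignment, IT-block extraction, max-pressure
normalization, 95%-of-reduction truncation, pooled per-condition OLS), fits
and ranks three mixed-model random structures, and prints the CoP magnitude
(cm) needed for an 80% / 90% proportional offload in each lean direction,
composed from the winning model's fixed effects. Leaning sideways needs less
CoP travel than leaning forward — the lateral slopes are steeper. Per-run
CSVs (regressions, sine fits, LMM effects, model comparison, Bland–Altman
agreement, thresholds) land under `demo/results/`, each stamped with the
seed and a configuration hash.

Published combined-cohort fixed effects can be plugged straight into the
same composition arithmetic:

```python
>>> from sipcop import LmmResult, total_slope, cop_threshold
>>> m = LmmResult.from_effects_table({"cop": -0.0730, "cop_x_dir_left": -0.0310})
>>> round(cop_threshold(total_slope(m, "left"), 0.90), 2)
8.65
```

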