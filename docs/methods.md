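# Methods

This note records the models implemented in `effshunt`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic evaluation does and does not demonstrate.

## Oxygen carriage model

Saturation follows a Hill-type closed form with a tension-dependent
Hill exponent,

    SO2(P) = (P/P50)^n(P) / (1 + (P/P50)^n(P)),
    n(P)   = 2.82 − 1.20 · 10^(−P[mmHg]/29.25),

in the style of the simple Dash–Korman–Bassingthwaighte dissociation
models. P50 is the standard 26.8 mmHg (3.573 kPa) scaled
multiplicatively by polynomial shift factors in pH (around 7.4), PCO2
(around 40 mmHg) and temperature (around 37 °C). 2,3-DPG is held at its
standard concentration — it is not measured clinically — so its factor
is unity and is omitted. This construction guarantees the properties
the rest of the package relies on: SO2 is strictly increasing in PO2,
equals 0.5 exactly at P50, and shifts right with acidaemia,
hypercapnia and fever (Bohr effect). The standard-condition P50 is
pinned as a regression constant in the tests.

Content combines bound and dissolved oxygen:

    CO2 [ml/dl] = 1.34 · Hb[g/dl] · SO2(P) + 0.0225 · P[kPa],

with the Hüfner capacity (1.34 ml/g) and solubility (0.0225 ml/dl/kPa)
both configurable. Because content is strictly monotone in tension with
slope ≥ the solubility, the inverse (content → tension) is solved by
bracketed root-finding on [0.05, 300] kPa at 1e-8 kPa absolute
tolerance; bisection-type methods are unconditionally safe here. The
measured round-trip error is ~2.5e-9 kPa over the physiological range.

The alveolar gas equation is used in its simplified form
PAO2 = FiO2·(Pb − PH2O) − PaCO2/RER; the neglected inspired-gas
correction term, PaCO2·FiO2·(1 − 1/RER), is < 0.3 kPa on room air at
RER 0.8 and vanishes at RER 1. The full form is available behind a
flag. Barometric pressure (101.325 kPa) and water vapour pressure
(6.27 kPa at 37 °C) are the standard sea-level values, configurable via
the assumptions object or a YAML file. Measured tensions are used as
the analyser reports them; no electrode temperature correction is
applied, and temperature defaults to 37 °C when a record omits it.

## Effective shunt

The shunt equation Qs/Qt = (Cc'O2 − CaO2)/(Cc'O2 − CvO2) contains the
unmeasurable mixed-venous content. Substituting the Fick rearrangement
CvO2 = CaO2 − VO2/Q gives

    ES = (Cc'O2 − CaO2) / (Cc'O2 − CaO2 + VO2/Q).

The *plus* sign in the denominator is the algebraically consistent
form: it alone keeps ES in [0, 1) and makes the forward prediction
(below) an exact inverse, which the self-consistency tests verify to
1e-6 kPa. (A minus sign sometimes seen in print is a sign slip — with
it, ES would exceed 1 or change sign for severe hypoxaemia.)

VO2/Q is expressed in content units: VO2 [ml STPD/min] divided by Q
[dl/min], e.g. 0.25 l/min over 6.5 l/min → 3.85 ml/dl. VO2, Q and RER
cannot be known from a blood gas and are fixed at mid-physiological
defaults (0.25 l/min, 6.5 l/min, 0.8). The sensitivity sweep
(`es_sensitivity`) quantifies their influence: one-at-a-time RER
changes barely move ES, whereas the extremes of a joint VO2/Q sweep
(0.15–1.0 l/min against 3–15 l/min — a 20-fold swing in VO2/Q) can
shift ES by up to ~0.4 in severe hypoxaemia. ES falls monotonically
with assumed VO2 and rises with assumed Q, as the formula dictates. The
defaults are deliberately configurable; the package does not attempt to
fit them per cohort.

Data-quality conventions: a missing Hb falls back to 110 g/l (typical
ICU value) with a logged warning and an output flag; a measured PaO2 at
or above the computed alveolar PO2 (measurement noise, FiO2
transcription error) clamps A-a and ES to 0 and tags the record rather
than raising, while a PaO2 more than 2 kPa above the *inspired* tension
is rejected as physically impossible.

## Forward predictions

Each measure, assumed invariant to the FiO2 change, implies a predicted
PaO2 at new settings:

* P/F: PaO2' = PF · FiO2' (exact identity at unchanged settings).
* A-a: PaO2' = PAO2' − Aa; a non-positive result is an explicit
  prediction failure, recorded per pair.
* ES: CaO2' = Cc'O2(PAO2') − ES/(1−ES) · VO2/Q, then content→tension
  inversion. The equivalent Qs·VO2/(Qt·(Qt−Qs)) form is computed
  alongside and asserted to agree to 1e-10.

Predictions are evaluated at the second sample's FiO2 and PaCO2 (the
pair selection conditions on PaCO2 stability), with the second sample's
pH in the dissociation curve and the first sample's Hb.

## Steady-state gas-exchange model

The simulator behind both the DB method and the synthetic cohorts
represents a lung as a true right-to-left shunt plus 50 compartments
whose V/Q ratios are log-normally distributed (perfusion-weighted
discretisation at 50 equally spaced quantile nodes over ±4σ;
σ = `vq_sigma`, so σ = 0 degenerates to one ideal compartment). This
is a reconstruction of an integrated-model design, not a transcription:
compartment count, distribution family and CO2 treatment are this
package's choices.

Per compartment, gas-phase O2 delivery balances blood uptake,
v_i(PI − PA_i)/K = 10 q_i (C(PA_i) − Cv), with end-capillary blood
fully equilibrated. CO2 carriage is linearised — PaCO2 = K·VCO2/VA with
VCO2 = VO2·RER — and pH follows Henderson–Hasselbalch at zero base
excess (HCO3⁻ 24 mmol/l). The same gas transport constant K (863 mmHg ≈
115.06 kPa) appears in both the O2 and CO2 balances; this makes the
ideal-compartment limit reproduce the simplified alveolar gas equation
*exactly*, so effective shunt recovers a pure latent shunt from
simulated gases as an algebraic identity (measured bias ~4e-11) rather
than an approximation. It also makes "retune ventilation to hit a
PaCO2" a closed form, used when extrapolating database matches.
Linearised CO2 is sufficient here because the evaluation pipeline
conditions on measured PaCO2 and scores only O2 predictions; the
simplification ignores the (real) shunt effect on PaCO2 and CO2–O2
gas-phase interaction.

Numerics: the only global coupling is the scalar mixed-venous content
per run (Cv = Ca − VO2/Q). The residual g(Cv) is strictly decreasing,
so feasibility is decided by its sign at the venous floor — inputs
whose oxygen consumption is unsustainable at the implied delivery
(e.g. shunt 0.95 at default VO2/Q, where Fick would require an
arteriovenous gap of VO2/Q/(1−s) ≈ 77 ml/dl) are reported as having
*no steady state*, distinct from solver failure. Feasible runs converge
by a vectorised secant iteration (tolerance 1e-9 ml/dl on successive
arterial contents, typically < 10 iterations); the inner compartment
equations are solved by 40 bisection steps at the first evaluation and
warm-started Newton steps (analytic content derivative) thereafter.
Everything is batched across runs, which is what makes the database
build tractable: oxygen mass conservation Q(Ca − Cv) = VO2 holds at the
fixed point by construction, and PaO2 is monotone decreasing in shunt
and heterogeneity and increasing in FiO2 (asserted on a three-axis
sweep).

## DB method

The default database grid spans shunt 0–0.5 (step 0.025), V/Q spread
0–2 (step 0.25), cardiac output 3–9 l/min (step 1.5), Hb {80, 110,
140} g/l, the 17 common ventilator FiO2 settings {0.21, 0.25, 0.30, …,
1.0}, and PaCO2 {4.2, 4.8, 5.4, 6.0, 6.6} kPa (realised through
alveolar ventilation). The PaCO2 axis exists so that PaCO2-window
matching is meaningful, and its 0.6 kPa step is exactly covered by the
±0.3 kPa match window; the FiO2 axis uses charted ventilator settings
so exact-to-grid FiO2 matching aligns with clinical values. Of the
240,975 grid points, ~217,000 admit a steady state; infeasible
combinations (severe shunt + heterogeneity on low FiO2 and low Q) are
dropped as incompatible with a living patient. The build takes ~2
minutes on one CPU. Grid axes are configurable via YAML.

Matching uses |ΔPaO2| ≤ 0.5 kPa and |ΔPaCO2| ≤ 0.3 kPa (mirroring the
pipeline's stability window), FiO2 and Hb snapped to the nearest grid
value; an empty match set is a reported outcome, not an error.
Prediction re-runs each matched state at the new FiO2 with ventilation
retuned to the new PaCO2 and returns the arithmetic mean of the
predicted PaO2 values. The state envelope is the per-parameter min/max
over matched (shunt, vq_sigma, Q, Hb) tuples; for two records it is
built from the intersection of the two match sets, so containment in
the single-record envelope holds by construction. In the two-sample
demonstration the second record is the one with the largest FiO2
contrast to the first — the double-FiO2 test quantifies oxygen
responsiveness, so the most contrasting sample is the informative
choice.

## Synthetic cohorts

Each patient draws a latent state — shunt ~ Beta(2,5) scaled to
[0, 0.5] (mean ≈ 14%, right-skewed), V/Q spread ~ U(0, 1.2), Q ~
N(6.5, 1.2²) clipped to [3, 9] l/min, Hb ~ N(105, 15²) clipped to
[60, 160] g/l, VO2 ~ N(0.25, 0.04²) clipped to [0.15, 0.4] l/min — and
a stable PaCO2 target ~ U(4.4, 6.4) kPa with 0.08 kPa between-sample
drift. FiO2 trajectories start higher for sicker lungs, step down
through the charted settings with probability 0.6 per sample (steps of
0.05, floored above room air in proportion to severity), at intervals
of 25–95 min over 4–8 samples. Every gas is produced by the simulator;
measurement noise is additive Gaussian, 0.5 kPa SD on PaO2 and 0.15 kPa
SD on PaCO2, truncated at physiological bounds, with pH derived from
the noisy PaCO2. These noise levels put the unchanged-FiO2 baseline at
a median |ΔPaO2| ≈ 0.48 kPa (the folded-normal median σ√2·Φ⁻¹(¾)),
i.e. the same order as the clinical noise floor such evaluations
report. Identical seeds give identical cohorts; infeasible latent draws
are redrawn with bounded retries. An optional corruption utility
replaces a stated fraction of FiO2 values with an adjacent setting to
model transcription error; it degrades every measure's MAE.

What the synthetic evaluation shows: the full pipeline — selection
filters, predictions, failure accounting, nonparametric comparison —
recovers the expected ranking MAE(ES) < MAE(DB) < MAE(P/F) < MAE(A-a)
under realistic noise, with ES near the designed noise floor, and
ground-truth recovery is exact in the noise-free pure-shunt limit. What
it cannot show: the cohort's gases come from the same model family the
DB method matches against and contain no disease evolution,
recruitment, suction or posture events, no FiO2 transcription error
(unless injected), and no extra-pulmonary drift — so the synthetic MAE
magnitudes are smaller than, and not comparable to, errors on real ICU
data; only the relative ordering and the structural properties carry
over.

## Evaluation conventions

Pair selection takes every qualifying ordered pair within the 3-h
window (a record may appear in several pairs; `consecutive_only`
restricts to adjacent samples). The PaCO2 stability criterion is strict
(< 0.3 kPa), implemented with a 1e-9 guard against float representation
of the difference; the 3-h window is inclusive. Prediction failures are
excluded per measure with counts reported; a flag instead drops such
pairs for all measures to keep medians directly comparable. Mann–
Whitney U tests are exact for group sizes ≤ 20 and tie-corrected
asymptotic above; Bonferroni multiplies by the number of pairwise
comparisons (6 for four measures), capped at 1; fully tied inputs
return p = 1. Because records can appear in multiple pairs, the
per-pair errors are not strictly independent — the tests are used as a
ranking heuristic here, as in the evaluation design this mirrors.

## Problem sizes used in the shipped checks

The shipped test suite and `scripts/acceptance.py` use: a 200-point
inversion grid across 9 (pH, PaCO2) conditions; pure-shunt recovery on
shunt 0.05–0.5 × 3 FiO2 levels; a 200–250-patient noisy cohort
(~1,500 scored pairs) for the validity ranking; the full default
database with 50 patients for the envelope demonstration; and a
900-combination sensitivity sweep. These sizes were chosen so the whole
battery runs in a few minutes on one CPU while leaving every rate
estimated from hundreds of units.

## Known limitations

* VO2, Q and RER are assumed, not measured; ES inherits their
  uncertainty through VO2/Q (quantified by the sensitivity sweep).
* Carboxy- and methaemoglobin are not modelled; 2,3-DPG is fixed.
* The simulator's CO2 side is linear and shunt-blind; its pH has zero
  base excess. Do not use the simulated PaCO2/pH for acid-base work.
* The DB method's numbers are grid- and reconstruction-dependent;
  envelopes are grid cells, not posterior probabilities.
* ES remains a single-number summary: it folds shunt and V/Q
  heterogeneity together by design, and is not fully independent of
  FiO2, ventilation or intracardiac shunting in real patients.
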