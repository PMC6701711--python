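# effshunt

Non-invasive estimation of pulmonary **effective shunt fraction** from a
single arterial blood gas, and a predictive-validity framework for
comparing oxygenation measures in critical care data.

Quantifying how badly a lung oxygenates is central to classifying
respiratory failure and measuring outcomes in ICU research. The indices
in routine use — the PaO2/FiO2 (P/F) ratio and the alveolar–arterial
(A-a) difference — are *tension*-based: they change markedly when the
inspired oxygen fraction changes, even when the lung itself does not.
*Content*-based measures track the true state far better but classically
require invasive mixed-venous sampling. This package implements two
content-based measures computable from a routine blood gas alone, plus
the machinery to test any of these measures against data:

* **Effective shunt (ES)** — the fraction of cardiac output that would
  have to bypass gas exchange in a three-compartment lung to produce the
  observed hypoxaemia. From the shunt equation and the Fick principle
  (CvO2 = CaO2 − VO2/Q):

  ```
  ES = Qs/Qt = (Cc'O2 − CaO2) / (Cc'O2 − CaO2 + VO2/Q)
  ```

  End-capillary content Cc'O2 is evaluated at the ideal alveolar PO2
  from the alveolar gas equation, PAO2 = FiO2·(Pb − PH2O) − PaCO2/RER;
  both contents use a Hill-type oxyhaemoglobin dissociation curve whose
  P50 shifts with the measured pH and PaCO2 (Bohr effect). VO2 and Q are
  assumed constants (defaults 0.25 l/min and 6.5 l/min, configurable).
  Converting a predicted content *back* to a tension is a bracketed
  numerical inversion of the strictly monotone content relation.

* **DB method** — match the blood gas against a precomputed database of
  runs of an integrated steady-state gas-exchange model (true shunt +
  log-normal V/Q heterogeneity + cardiac output + Hb + FiO2), then
  extrapolate the matching runs to new ventilator settings. The spread
  of matched parameters is an explicit statement of how underdetermined
  the lung state is from one sample — and how much a second sample at a
  different FiO2 narrows it.

* **Predictive validity** — each measure, held fixed, implies a
  predicted PaO2 after an FiO2 change. On pairs of blood gases selected
  for a stable lung (≤3 h apart, ventilated, FiO2 weaned down,
  |ΔPaCO2| < 0.3 kPa), the median absolute prediction error (MAE) ranks
  the measures; Kruskal–Wallis and Bonferroni-corrected Mann–Whitney U
  tests compare them. A seeded synthetic ICU cohort generator (built on
  the same gas-exchange model, with known latent states and measurement
  noise) makes the whole pipeline testable end to end.

All tensions are kPa internally (1 kPa = 7.50062 mmHg at the I/O
boundary), contents ml O2/dl, haemoglobin g/l.

## Worked example

Computing the measures for one blood gas (FiO2 0.60, PaO2 9.0 kPa,
PaCO2 5.0 kPa, pH 7.35, Hb 120 g/l — `examples/single_abg_indices.py`):

```
P/F ratio        :  15.00 kPa
A-a difference   :  41.78 kPa
effective shunt  :  36.0%
```

The same lung, predicted after weaning to FiO2 0.40
(`examples/predict_after_fio2_change.py`):

```
predicted PaO2 at FiO2 0.40:
  effective shunt : 8.01 kPa
  P/F ratio       : 6.00 kPa
  A-a difference  : no feasible prediction (A-a prediction non-positive ...)
```

Holding the P/F ratio fixed scales the hypoxaemia linearly and
undershoots; holding the A-a difference fixed predicts a negative
tension outright (a counted prediction failure). The ES prediction
follows the dissociation curve.

How ES absorbs V/Q heterogeneity (`examples/simulate_gas_exchange.py`):
two simulated lungs with identical 10% true shunt, one with marked
heterogeneity:

```
true shunt 10%, V/Q spread 0.0: PaO2 24.21 kPa ... -> effective shunt 10.0%
true shunt 10%, V/Q spread 1.2: PaO2 11.75 kPa ... -> effective shunt 22.9%
```

ES reports the pure shunt that would have the same effect on
oxygenation — by design, heterogeneity and shunt fold into one number.

On a 100-patient synthetic weaning cohort
(`examples/cohort_predictive_validity.py`), the predictive-validity
ranking emerges with the content-based measure nearest the noise floor:

```
measure  mae_kpa  n_scored  n_failed
     es 0.481962       584         0
     pf 1.120440       584         0
     aa 1.840690       572        12
baseline noise floor (unchanged FiO2, n=247): median |dPaO2| = 0.48 kPa
```

`examples/db_state_envelope.py` shows the DB method's state envelope
collapsing when a second blood gas at a different FiO2 is added.

A thin CLI wraps the same functions for CSV workflows:
`effshunt compute`, `effshunt synth`, `effshunt simulate`,
`effshunt db build`, `effshunt db envelope`, `effshunt validate`
(all with `--units {kPa,mmHg}` where relevant; see `--help`).

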