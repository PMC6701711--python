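"""Predict the PaO2 expected after weaning FiO2, for each measure.

Each oxygenation measure implies a forward prediction: hold the measure
fixed, change FiO2, and solve for the new PaO2. The three measures
disagree substantially — this disagreement is exactly what the
predictive-validity evaluation scores against observed outcomes.
"""

import datetime

from effshunt import (
    ABGRecord,
    PredictionError,
    aa_difference,
    effective_shunt,
    pf_ratio,
    predict_pao2_aa,
    predict_pao2_es,
    predict_pao2_pf,
)

before = ABGRecord(
    patient_id="example",
    timestamp=datetime.datetime(2024, 1, 1, 8, 0),
    fio2=0.60,
    pao2=9.0,
    paco2=5.0,
    ph=7.35,
    hb=120.0,
)
new_fio2, new_paco2 = 0.40, 5.0

es = effective_shunt(before)
print(f"measured at FiO2 {before.fio2:.2f}: PaO2 {before.pao2:.1f} kPa "
      f"(ES {es:.1%})")
print(f"predicted PaO2 at FiO2 {new_fio2:.2f}:")
print(f"  effective shunt : "
      f"{predict_pao2_es(es, new_fio2, new_paco2, before.ph, before.hb):.2f} kPa")
print(f"  P/F ratio       : "
      f"{predict_pao2_pf(pf_ratio(before), new_fio2):.2f} kPa")
try:
    pred_aa = predict_pao2_aa(aa_difference(before), new_fio2, new_paco2)
    print(f"  A-a difference  : {pred_aa:.2f} kPa")
except PredictionError as exc:
    print(f"  A-a difference  : no feasible prediction ({exc})")
print()
print("The tension-based predictions scale the hypoxaemia down with FiO2 "
      "— here the A-a gradient is so large that holding it fixed predicts "
      "a negative tension, a failure the evaluation pipeline counts "
      "against the measure. The content-based ES prediction follows the "
      "nonlinear dissociation curve instead.")
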