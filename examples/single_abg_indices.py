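"""Compute all oxygenation measures for a single arterial blood gas.

A ventilated patient on 60% oxygen with PaO2 9.0 kPa: the P/F ratio and
A-a difference describe the same gas in tension units, while the
effective shunt expresses it as the fraction of cardiac output that
would need to bypass gas exchange entirely to produce this hypoxaemia.
"""

import datetime

from effshunt import ABGRecord, assess

record = ABGRecord(
    patient_id="example",
    timestamp=datetime.datetime(2024, 1, 1, 8, 0),
    fio2=0.60,
    pao2=9.0,   # kPa
    paco2=5.0,  # kPa
    ph=7.35,
    hb=120.0,   # g/l
)

result = assess(record)
print(f"P/F ratio        : {result.pf_ratio:6.2f} kPa")
print(f"A-a difference   : {result.aa_difference:6.2f} kPa")
print(f"effective shunt  : {result.effective_shunt:6.1%}")
print()
print(
    "Read: this blood gas looks like a lung in which "
    f"{result.effective_shunt:.0%} of cardiac output bypasses ventilated "
    "alveoli entirely."
)
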