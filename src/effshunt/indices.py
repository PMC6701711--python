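"""Oxygenation measures from a single arterial blood gas, and their
forward PaO2 predictions.

Four measures are compared throughout the package:

* **P/F ratio** — PaO2 / FiO2 (kPa), tension-based;
* **A-a difference** — alveolar minus arterial PO2 (kPa), tension-based;
* **effective shunt (ES)** — the pure right-to-left shunt fraction that
  would, in a three-compartment lung, produce the observed oxygenation
  impairment (content-based);
* **DB** — database inference over an integrated gas-exchange model
  (see :mod:`effshunt.db`).

ES comes from the shunt equation Qs/Qt = (Cc'O2 - CaO2)/(Cc'O2 - CvO2)
with the unmeasurable mixed-venous content replaced via the Fick
principle, CvO2 = CaO2 - VO2/Q, giving

    ES = (Cc'O2 - CaO2) / (Cc'O2 - CaO2 + VO2/Q)

with VO2/Q expressed in content units (ml/dl). End-capillary content is
evaluated at the ideal alveolar PO2 from the alveolar gas equation;
both contents use the measured pH and PaCO2 through the dissociation
curve's P50.

Each measure predicts the PaO2 expected at new ventilator settings
under the assumption that the measure itself is invariant to the FiO2
change; the accuracy of that prediction is the package's predictive
validity metric.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from typing import Optional

import numpy as np

from . import odc
from .errors import InvalidInputError, PredictionError
from .odc import DEFAULT_ASSUMPTIONS, PhysiologicalAssumptions

logger = logging.getLogger(__name__)

# Slack (kPa) allowed on "arterial tension cannot exceed inspired tension"
# before a record is rejected outright rather than merely tagged.
_SUPRA_ALVEOLAR_HARD_LIMIT_KPA = 2.0


@dataclasses.dataclass(frozen=True)
class ABGRecord:
    """One arterial blood gas measurement with ventilator context.

    Tensions in kPa, haemoglobin in g/l, temperature in Celsius.
    ``hb`` and ``temperature`` are optional; computations fall back to
    the assumed defaults when absent.
    """

    patient_id: str
    timestamp: _dt.datetime
    fio2: float
    pao2: float
    paco2: float
    ph: float
    hb: Optional[float] = None
    temperature: Optional[float] = None
    ventilated: bool = True

    def __post_init__(self) -> None:
        if not (0.21 - 1e-9 <= self.fio2 <= 1.0 + 1e-9):
            raise InvalidInputError(f"fio2={self.fio2} outside [0.21, 1.0]")
        if self.pao2 <= 0 or self.paco2 <= 0:
            raise InvalidInputError("pao2 and paco2 must be positive")
        if not (6.5 < self.ph < 8.0):
            raise InvalidInputError(f"ph={self.ph} outside (6.5, 8.0)")
        if self.hb is not None and self.hb <= 0:
            raise InvalidInputError("hb must be positive when present")
        inspired = self.fio2 * DEFAULT_ASSUMPTIONS.pio2
        if self.pao2 > inspired + _SUPRA_ALVEOLAR_HARD_LIMIT_KPA:
            raise InvalidInputError(
                f"pao2={self.pao2} kPa exceeds inspired tension "
                f"{inspired:.2f} kPa at fio2={self.fio2}"
            )


@dataclasses.dataclass(frozen=True)
class OxygenationAssessment:
    """All measures for one record, plus data-quality flags."""

    pf_ratio: float
    aa_difference: float
    effective_shunt: float
    db_shunt_summary: Optional[float] = None
    supra_alveolar: bool = False  # PaO2 above ideal alveolar PO2; A-a/ES clamped
    hb_fallback: bool = False  # record had no Hb; assumed default used


def pf_ratio(record: ABGRecord) -> float:
    """PaO2/FiO2 ratio in kPa."""
    return record.pao2 / record.fio2


def aa_difference(
    record: ABGRecord,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> float:
    """Alveolar-arterial O2 tension difference (kPa), clamped at zero.

    A measured PaO2 slightly above the computed alveolar PO2 (noise or an
    FiO2 transcription error) yields 0 rather than a negative gradient.
    """
    pao2_alv = odc.alveolar_po2(record.fio2, record.paco2, assumptions)
    return max(0.0, pao2_alv - record.pao2)


def _record_hb(record: ABGRecord, assumptions: PhysiologicalAssumptions):
    if record.hb is None:
        logger.warning(
            "record %s/%s has no Hb; assuming %.0f g/l",
            record.patient_id,
            record.timestamp,
            assumptions.hb_default,
        )
        return assumptions.hb_default, True
    return record.hb, False


def effective_shunt(
    record: ABGRecord,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> float:
    """Effective shunt fraction from a single ABG.

    ES = (Cc'O2 - CaO2) / (Cc'O2 - CaO2 + VO2/Q), clamped to 0 when the
    arterial content reaches the end-capillary content (supra-alveolar
    PaO2 from measurement noise). Result in [0, 1).
    """
    hb, _ = _record_hb(record, assumptions)
    t = record.temperature
    pao2_alv = odc.alveolar_po2(record.fio2, record.paco2, assumptions)
    cc = odc.oxygen_content(pao2_alv, record.ph, record.paco2, hb, assumptions, t)
    ca = odc.oxygen_content(record.pao2, record.ph, record.paco2, hb, assumptions, t)
    d = cc - ca
    if d <= 0:
        return 0.0
    return d / (d + assumptions.vo2_q_ml_dl)


def assess(
    record: ABGRecord,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    db_shunt_summary: Optional[float] = None,
) -> OxygenationAssessment:
    """Compute every measure for one record, with quality flags."""
    hb, hb_fallback = _record_hb(record, assumptions)
    pao2_alv = odc.alveolar_po2(record.fio2, record.paco2, assumptions)
    return OxygenationAssessment(
        pf_ratio=pf_ratio(record),
        aa_difference=aa_difference(record, assumptions),
        effective_shunt=effective_shunt(record, assumptions),
        db_shunt_summary=db_shunt_summary,
        supra_alveolar=record.pao2 > pao2_alv,
        hb_fallback=hb_fallback,
    )


def predict_pao2_es(
    es: float,
    new_fio2: float,
    new_paco2: float,
    ph: float,
    hb: Optional[float] = None,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    temperature=None,
) -> float:
    """Predicted PaO2 (kPa) at new settings, assuming ES is unchanged.

    The predicted arterial content is

        CaO2 = Cc'O2(new PAO2) - (Qs/Qt) * VO2 / (Qt - Qs)

    (equivalently Cc'O2 - es/(1-es) * VO2/Q), then inverted back to a
    tension. Raises :class:`PredictionError` when the predicted content
    is below the attainable range (extreme shunt at low FiO2).
    """
    if not (0.0 <= es < 1.0):
        raise InvalidInputError(f"es={es} outside [0, 1)")
    if hb is None:
        hb = assumptions.hb_default
    pao2_alv = odc.alveolar_po2(new_fio2, new_paco2, assumptions)
    cc = odc.oxygen_content(pao2_alv, ph, new_paco2, hb, assumptions, temperature)
    # Two algebraically identical forms of the venous-admixture deficit;
    # computed separately as a guard against unit slips.
    deficit = es / (1.0 - es) * assumptions.vo2_q_ml_dl
    qs = es * assumptions.q_total
    deficit_fick = 100.0 * (qs * assumptions.vo2) / (
        assumptions.q_total * (assumptions.q_total - qs)
    )
    assert abs(deficit - deficit_fick) < 1e-10 * max(1.0, deficit)
    ca = cc - deficit
    if ca <= 0:
        raise PredictionError(
            f"predicted arterial content {ca:.3f} ml/dl non-positive "
            f"(es={es:.3f}, fio2={new_fio2})"
        )
    try:
        return odc.po2_from_content(ca, ph, new_paco2, hb, assumptions, temperature)
    except odc.ContentRangeError as exc:
        raise PredictionError(str(exc)) from exc


def predict_pao2_pf(pf: float, new_fio2: float) -> float:
    """Predicted PaO2 at a new FiO2, assuming the P/F ratio is unchanged."""
    if pf <= 0:
        raise InvalidInputError("pf must be positive")
    return pf * new_fio2


def predict_pao2_aa(
    aa: float,
    new_fio2: float,
    new_paco2: float,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> float:
    """Predicted PaO2 at new settings, assuming the A-a difference is
    unchanged. Raises :class:`PredictionError` when the prediction is
    non-positive (large gradient, low FiO2); callers record this as a
    failed prediction for the pair."""
    if aa < 0:
        raise InvalidInputError("aa must be non-negative")
    pred = odc.alveolar_po2(new_fio2, new_paco2, assumptions) - aa
    if pred <= 0:
        raise PredictionError(
            f"A-a prediction non-positive ({pred:.2f} kPa) at fio2={new_fio2}"
        )
    return pred


def es_sensitivity(
    records,
    rer_values=(0.8, 0.9, 1.0, 1.1),
    q_values=(3.0, 6.0, 9.0, 12.0, 15.0),
    vo2_values=(0.15, 0.25, 0.5, 0.75, 1.0),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
):
    """Sweep the assumed RER, Q and VO2 over wide physiological ranges and
    report how much ES moves on a grid of reference records.

    Returns a DataFrame with one row per (record, rer, q, vo2) combination
    and columns ``es`` and ``es_shift`` (deviation from the ES computed
    under ``assumptions``). The headline summary is
    ``result["es_shift"].abs().max()``.
    """
    import itertools

    import pandas as pd

    rows = []
    for i, rec in enumerate(records):
        es_ref = effective_shunt(rec, assumptions)
        for rer, q, vo2 in itertools.product(rer_values, q_values, vo2_values):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                a = assumptions.replace(rer=rer, q_total=q, vo2=vo2)
            es = effective_shunt(rec, a)
            rows.append(
                {
                    "record": i,
                    "rer": rer,
                    "q_total": q,
                    "vo2": vo2,
                    "es": es,
                    "es_ref": es_ref,
                    "es_shift": es - es_ref,
                }
            )
    return pd.DataFrame(rows)
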