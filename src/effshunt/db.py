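"""The DB oxygenation measure: database inference over the gas-exchange
model.

A single ABG underdetermines the lung: many (shunt, V/Q heterogeneity,
cardiac output, Hb) combinations produce the same blood gas at a given
FiO2. The DB method makes that explicit: a precomputed database of
model runs (:func:`effshunt.simulator.build_database`) is filtered to
the runs whose outputs match the observed ABG within tolerances; the
matched runs are then re-run at new ventilator settings and the mean of
their predicted PaO2 values is the DB prediction. The spread of matched
input parameters is the *state envelope* — one ABG leaves it wide, a
second ABG at a different FiO2 intersects it down.

Match tolerances default to PaO2 +/-0.5 kPa and PaCO2 +/-0.3 kPa
(mirroring the evaluation pipeline's ventilation-stability window);
FiO2 matches exactly after snapping to the grid axis, and Hb matches
the nearest grid value.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import simulator
from .errors import InvalidInputError
from .indices import ABGRecord
from .odc import DEFAULT_ASSUMPTIONS, PhysiologicalAssumptions

#: Input parameters that identify a physiological state in the database.
STATE_PARAMS = ("shunt", "vq_sigma", "q_total", "hb")


@dataclasses.dataclass(frozen=True)
class MatchTolerances:
    """Per-variable windows for matching an ABG to database rows (kPa
    for tensions). ``fio2`` and ``hb`` are snapped to the nearest grid
    value and matched exactly."""

    pao2: float = 0.5
    paco2: float = 0.3


@dataclasses.dataclass
class MatchSet:
    """Database rows consistent with one ABG."""

    runs: pd.DataFrame
    tolerances: MatchTolerances
    record: ABGRecord

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def empty(self) -> bool:
        return self.runs.empty

    def shunt_summary(self) -> Optional[float]:
        """Mean pure-shunt fraction over matched runs (None if empty)."""
        return None if self.empty else float(self.runs["shunt"].mean())


def _snap(value: float, axis: np.ndarray) -> float:
    axis = np.asarray(axis, dtype=float)
    return float(axis[np.argmin(np.abs(axis - value))])


def match_abg(
    database: pd.DataFrame,
    record: ABGRecord,
    tolerances: MatchTolerances = MatchTolerances(),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> MatchSet:
    """All database runs whose outputs match the record within tolerances.

    An empty match set is a legitimate result (reported, not an error):
    it means no modelled state reproduces the observation at this grid
    resolution.
    """
    if database.empty:
        raise InvalidInputError("database is empty")
    fio2 = _snap(record.fio2, database["fio2"].unique())
    hb = _snap(
        record.hb if record.hb is not None else assumptions.hb_default,
        database["hb"].unique(),
    )
    mask = (
        (np.abs(database["fio2"] - fio2) < 1e-9)
        & (np.abs(database["hb"] - hb) < 1e-9)
        & (np.abs(database["out_pao2"] - record.pao2) <= tolerances.pao2)
        & (np.abs(database["out_paco2"] - record.paco2) <= tolerances.paco2)
    )
    return MatchSet(runs=database[mask].copy(), tolerances=tolerances, record=record)


def db_predict(
    matches: MatchSet,
    new_fio2: float,
    new_paco2: float,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> float:
    """Mean PaO2 (kPa) of all matched runs re-run at the new settings.

    Each matched run keeps its physiological state (shunt, vq_sigma, Q,
    Hb, VO2) while FiO2 is set to ``new_fio2`` and alveolar ventilation
    is retuned so the modelled PaCO2 equals ``new_paco2`` (closed form
    under the linear CO2 relation).
    """
    if matches.empty:
        raise InvalidInputError("cannot predict from an empty match set")
    runs = matches.runs
    vo2 = runs["vo2"] if "vo2" in runs else assumptions.vo2
    inputs = pd.DataFrame(
        {
            "shunt": runs["shunt"].to_numpy(),
            "vq_sigma": runs["vq_sigma"].to_numpy(),
            "q_total": runs["q_total"].to_numpy(),
            "hb": runs["hb"].to_numpy(),
            "fio2": new_fio2,
            "vo2": np.asarray(vo2, dtype=float),
            "alveolar_ventilation": simulator.alveolar_ventilation_for_paco2(
                new_paco2, assumptions, vo2=np.asarray(vo2, dtype=float)
            ),
        }
    )
    solved = simulator.steady_state_batch(inputs, assumptions, raise_on_failure=False)
    ok = solved["converged"].to_numpy()
    if not ok.any():
        raise InvalidInputError(
            "no matched run has a steady state at the new settings"
        )
    return float(solved.loc[ok, "out_pao2"].mean())


@dataclasses.dataclass
class ParameterEnvelope:
    """Per-parameter ranges of the states consistent with the record(s).

    ``n_cells`` counts distinct grid states (shunt, vq_sigma, Q, Hb);
    ``ranges`` maps each parameter to its (min, max) over those states.
    Empty envelopes have ``n_cells == 0`` and no ranges.
    """

    states: frozenset
    ranges: dict

    @property
    def n_cells(self) -> int:
        return len(self.states)

    @property
    def empty(self) -> bool:
        return not self.states

    def __contains__(self, params: Tuple[float, ...]) -> bool:
        return tuple(np.round(params, 6)) in self.states

    def issubset(self, other: "ParameterEnvelope") -> bool:
        return self.states <= other.states

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"parameter": p, "min": lo, "max": hi}
                for p, (lo, hi) in self.ranges.items()
            ]
        )


def _states(runs: pd.DataFrame) -> frozenset:
    arr = np.round(runs.loc[:, list(STATE_PARAMS)].to_numpy(dtype=float), 6)
    return frozenset(map(tuple, arr))


def _envelope_from_states(states: frozenset) -> ParameterEnvelope:
    if not states:
        return ParameterEnvelope(states=frozenset(), ranges={})
    arr = np.array(sorted(states))
    ranges = {
        p: (float(arr[:, i].min()), float(arr[:, i].max()))
        for i, p in enumerate(STATE_PARAMS)
    }
    return ParameterEnvelope(states=states, ranges=ranges)


def constrain_state(
    database: pd.DataFrame,
    records: Sequence[ABGRecord],
    tolerances: MatchTolerances = MatchTolerances(),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
) -> ParameterEnvelope:
    """Envelope of physiological states consistent with one or two ABGs.

    With two records the envelope is built from the *intersection* of
    each record's matched state sets, so it is always a subset of either
    single-record envelope — the quantitative form of "a second ABG at a
    different FiO2 constrains the possible physiological states".
    """
    if not 1 <= len(records) <= 2:
        raise InvalidInputError("constrain_state takes one or two records")
    if len(records) == 2 and records[0].patient_id != records[1].patient_id:
        raise InvalidInputError("records must come from the same patient")
    state_sets = [
        _states(match_abg(database, rec, tolerances, assumptions).runs)
        for rec in records
    ]
    states = state_sets[0]
    for s in state_sets[1:]:
        states &= s
    return _envelope_from_states(states)
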