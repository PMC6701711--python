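"""Seeded synthetic ICU blood-gas cohorts.

Emulates the structure the evaluation pipeline assumes: per-patient
latent lung states (pure shunt, V/Q heterogeneity, cardiac output,
haemoglobin, oxygen consumption), FiO2 weaning trajectories over the
common ventilator settings, stable PaCO2 with small drift, and additive
measurement noise on the reported tensions. Every ABG is produced by the
steady-state gas-exchange model, so ground truth is known exactly and
identical seeds give identical cohorts.

What this emulates — and what it does not — is spelled out in the
methods note: there is no disease evolution, recruitment, suction or
posture change within a trajectory, so the synthetic noise floor is
purely measurement noise plus PaCO2 drift.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import simulator
from .errors import ConvergenceError
from .indices import ABGRecord
from .odc import DEFAULT_ASSUMPTIONS, PhysiologicalAssumptions
from .simulator import FIO2_SETTINGS

_EPOCH = _dt.datetime(2024, 1, 1)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Latent pure shunt is Beta(2, 5) scaled to [0, shunt_max] (population
    mean ~14%, right-skewed, matching the clinical picture of mostly
    moderate impairment with a severe tail); V/Q heterogeneity is uniform
    on ``vq_sigma_range``. Measurement noise defaults: 0.5 kPa SD on
    PaO2, 0.15 kPa SD on PaCO2, truncated at physiological bounds.
    """

    n_patients: int = 200
    samples_per_patient: Tuple[int, int] = (4, 8)
    shunt_beta: Tuple[float, float] = (2.0, 5.0)
    shunt_max: float = 0.5
    vq_sigma_range: Tuple[float, float] = (0.0, 1.2)
    q_mean: float = 6.5
    q_sd: float = 1.2
    q_bounds: Tuple[float, float] = (3.0, 9.0)
    hb_mean: float = 105.0
    hb_sd: float = 15.0
    hb_bounds: Tuple[float, float] = (60.0, 160.0)
    vo2_mean: float = 0.25
    vo2_sd: float = 0.04
    vo2_bounds: Tuple[float, float] = (0.15, 0.4)
    paco2_range: Tuple[float, float] = (4.4, 6.4)
    paco2_drift_sd: float = 0.08
    pao2_noise_sd: float = 0.5
    paco2_noise_sd: float = 0.15
    interval_min_range: Tuple[float, float] = (25.0, 95.0)
    fio2_step_prob: float = 0.6
    hb_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.paco2_drift_sd, self.pao2_noise_sd, self.paco2_noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")


def _snap_fio2(value: float) -> float:
    return float(FIO2_SETTINGS[np.argmin(np.abs(FIO2_SETTINGS - value))])


def _draw_patient(rng: np.random.Generator, spec: CohortSpec) -> dict:
    a, b = spec.shunt_beta
    shunt = float(rng.beta(a, b) * spec.shunt_max)
    return {
        "shunt": shunt,
        "vq_sigma": float(rng.uniform(*spec.vq_sigma_range)),
        "q_total": float(
            np.clip(rng.normal(spec.q_mean, spec.q_sd), *spec.q_bounds)
        ),
        "hb": float(np.clip(rng.normal(spec.hb_mean, spec.hb_sd), *spec.hb_bounds)),
        "vo2": float(
            np.clip(rng.normal(spec.vo2_mean, spec.vo2_sd), *spec.vo2_bounds)
        ),
        "paco2_target": float(rng.uniform(*spec.paco2_range)),
    }


def _patient_rows(
    rng: np.random.Generator, spec: CohortSpec, pid: str, latents: dict
) -> pd.DataFrame:
    """Sampling times, FiO2 trajectory and per-sample PaCO2 targets."""
    n = int(rng.integers(spec.samples_per_patient[0], spec.samples_per_patient[1] + 1))
    # sicker lungs start on more oxygen, and are not weaned below a floor
    start = _snap_fio2(
        np.clip(
            0.35 + 0.9 * latents["shunt"] + 0.2 * latents["vq_sigma"]
            + rng.uniform(0.0, 0.15),
            0.25,
            0.95,
        )
    )
    floor = _snap_fio2(max(0.21, 0.21 + 0.3 * latents["shunt"]))
    idx = int(np.argmin(np.abs(FIO2_SETTINGS - start)))
    floor_idx = int(np.argmin(np.abs(FIO2_SETTINGS - floor)))
    fio2s, times, paco2s = [], [], []
    t = float(rng.uniform(0.0, 120.0))
    for _ in range(n):
        fio2s.append(float(FIO2_SETTINGS[idx]))
        times.append(t)
        paco2s.append(
            float(
                np.clip(
                    latents["paco2_target"] + rng.normal(0.0, spec.paco2_drift_sd),
                    2.5,
                    9.0,
                )
            )
        )
        if idx > floor_idx and rng.uniform() < spec.fio2_step_prob:
            idx -= 1
        t += float(rng.uniform(*spec.interval_min_range))
    return pd.DataFrame(
        {
            "patient_id": pid,
            "t_min": times,
            "fio2": fio2s,
            "paco2_target": paco2s,
            **{k: latents[k] for k in ("shunt", "vq_sigma", "q_total", "hb", "vo2")},
        }
    )


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    max_retries: int = 5,
) -> Tuple[List[ABGRecord], pd.DataFrame]:
    """Generate a cohort of ABG records plus the latent-truth table.

    Returns ``(records, truth)`` where ``truth`` holds one row per
    patient with the latent parameters, for recovery tests. Patients
    whose latent draw admits no steady state at some trajectory point
    are redrawn (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        for attempt in range(max_retries + 1):
            latents = _draw_patient(rng, spec)
            rows = _patient_rows(rng, spec, pid, latents)
            rows["alveolar_ventilation"] = simulator.alveolar_ventilation_for_paco2(
                rows["paco2_target"].to_numpy(), assumptions, vo2=rows["vo2"].to_numpy()
            )
            solved = simulator.steady_state_batch(
                rows, assumptions, raise_on_failure=False
            )
            if solved["converged"].all():
                frames.append(solved)
                break
        else:
            raise ConvergenceError(
                f"patient {pid}: no feasible latent draw in {max_retries} retries"
            )
    if not frames:
        return [], pd.DataFrame()
    cohort = pd.concat(frames, ignore_index=True)

    # additive measurement noise, truncated at physiological bounds
    n = len(cohort)
    pao2_meas = cohort["out_pao2"] + rng.normal(0.0, spec.pao2_noise_sd, n)
    pao2_meas = np.clip(
        pao2_meas, 0.5, cohort["fio2"] * assumptions.pio2 - 0.05
    )
    paco2_meas = np.clip(
        cohort["out_paco2"] + rng.normal(0.0, spec.paco2_noise_sd, n), 1.5, 12.0
    )
    ph_meas = simulator.ph_from_paco2(paco2_meas) + rng.normal(0.0, 0.01, n)
    hb_missing = rng.uniform(size=n) < spec.hb_missing_rate

    records = [
        ABGRecord(
            patient_id=row.patient_id,
            timestamp=_EPOCH + _dt.timedelta(minutes=float(row.t_min)),
            fio2=float(row.fio2),
            pao2=float(pao2),
            paco2=float(paco2),
            ph=float(ph),
            hb=None if missing else float(row.hb),
            ventilated=True,
        )
        for row, pao2, paco2, ph, missing in zip(
            cohort.itertuples(), pao2_meas, paco2_meas, ph_meas, hb_missing
        )
    ]
    truth = (
        cohort.groupby("patient_id")
        .first()[["shunt", "vq_sigma", "q_total", "hb", "vo2", "paco2_target"]]
        .reset_index()
    )
    return records, truth


def cohort_to_frame(records: Sequence[ABGRecord]) -> pd.DataFrame:
    """Records as the canonical tabular layout (see :mod:`effshunt.io`)."""
    from .io import records_to_frame

    return records_to_frame(records)


def inject_fio2_transcription_errors(
    records: Sequence[ABGRecord], rate: float, seed: int = 0
) -> Tuple[List[ABGRecord], np.ndarray]:
    """Corrupt a fraction of records' FiO2 to an adjacent common setting.

    Models clinician transcription error (FiO2 is typed in at analysis
    time). Returns the corrupted records and a boolean truth mask of
    which were altered. ``rate=0`` is the identity; ``rate=1`` corrupts
    every record.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    corrupted = rng.uniform(size=len(records)) < rate
    out: List[ABGRecord] = []
    for rec, bad in zip(records, corrupted):
        if not bad:
            out.append(rec)
            continue
        idx = int(np.argmin(np.abs(FIO2_SETTINGS - rec.fio2)))
        if idx == 0:
            idx_new = 1
        elif idx == len(FIO2_SETTINGS) - 1:
            idx_new = idx - 1
        else:
            idx_new = idx + int(rng.choice([-1, 1]))
        new_fio2 = float(FIO2_SETTINGS[idx_new])
        # keep the record physiologically valid after corruption
        if rec.pao2 > new_fio2 * DEFAULT_ASSUMPTIONS.pio2 + 1.9:
            idx_new = idx + 1 if idx + 1 < len(FIO2_SETTINGS) else idx - 1
            new_fio2 = float(FIO2_SETTINGS[idx_new])
        out.append(dataclasses.replace(rec, fio2=new_fio2))
    return out, corrupted
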