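"""Integrated steady-state gas-exchange model.

A lung is represented as a true right-to-left shunt plus ``n_compartments``
gas-exchanging units whose ventilation/perfusion (V/Q) ratios follow a
log-normal distribution with log-scale spread ``vq_sigma`` (``vq_sigma=0``
degenerates to a single ideal compartment). Given pure shunt fraction,
V/Q heterogeneity, cardiac output, haemoglobin, FiO2 and alveolar
ventilation, the model returns steady-state arterial blood gas values.

Per compartment, the O2 mass balance equates gas-phase delivery with
blood uptake,

    v_i (PI - PA_i) / K = 10 q_i (C(PA_i) - Cv)        [ml O2/min]

where PI is the inspired O2 tension, C the content model of
:mod:`effshunt.odc` evaluated at arterial pH/PaCO2, and K the gas
transport constant shared with the CO2 relation. End-capillary blood
fully equilibrates with alveolar gas. Mixed arterial content is the
perfusion-weighted mixture of compartment effluents plus the shunted
mixed-venous fraction, and mixed-venous content follows the Fick
principle, Cv = Ca - VO2/Q. The Cv fixed point is solved by a
vectorised secant iteration; the inner compartment equations by
bisection followed by warm-started Newton steps.

CO2 carriage is linearised: PaCO2 = K * VCO2 / VA with VCO2 = VO2 * RER,
and pH follows from Henderson-Hasselbalch at zero base excess. This is a
reconstruction sufficient for O2 prediction — the evaluation pipeline
conditions on measured PaCO2, and only O2 predictions are scored.

Everything accepts scalars or arrays; the batched path is what makes
database construction tractable.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import odc
from .errors import ConvergenceError, InfeasibleStateError, InvalidInputError
from .odc import DEFAULT_ASSUMPTIONS, PhysiologicalAssumptions

#: Compartment count of the heterogeneous lung discretisation.
N_COMPARTMENTS = 50

# Henderson-Hasselbalch at zero base excess: fixed bicarbonate and CO2
# solubility (mmol/l per kPa).
_HCO3_MMOL_L = 24.0
_CO2_SOLUBILITY = 0.2295

_CA_TOL = 1e-9  # ml/dl; successive arterial-content tolerance
_MAX_SECANT = 80
_PA_FLOOR = 1e-3  # kPa; lower bracket for compartmental PO2


def ph_from_paco2(paco2):
    """Arterial pH from PaCO2 (kPa) at zero base excess."""
    paco2 = np.asarray(paco2, dtype=float)
    out = 6.1 + np.log10(_HCO3_MMOL_L / (_CO2_SOLUBILITY * paco2))
    return float(out) if out.ndim == 0 else out


def alveolar_ventilation_for_paco2(
    paco2, assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS, vo2=None
):
    """VA (l/min) that yields the target PaCO2 under the linear CO2 relation.

    PaCO2 = K * VCO2 / VA  =>  VA = K * VO2 * RER / PaCO2. Closed form, so
    "retuning ventilation to hit a PaCO2" never needs root finding.
    """
    vo2 = assumptions.vo2 if vo2 is None else vo2
    return assumptions.k_gas * np.asarray(vo2, float) * assumptions.rer / np.asarray(
        paco2, float
    )


@dataclasses.dataclass
class ModelRun:
    """One simulator input set, with outputs filled in after solving."""

    shunt: float
    vq_sigma: float
    q_total: float
    hb: float
    fio2: float
    alveolar_ventilation: float
    vo2: float = DEFAULT_ASSUMPTIONS.vo2
    out_pao2: Optional[float] = None
    out_paco2: Optional[float] = None
    out_ph: Optional[float] = None


def mixed_venous_update(
    ca: float, assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS
) -> float:
    """Fick step: mixed-venous content Cv = Ca - VO2/Q (ml/dl).

    Raises :class:`InfeasibleStateError` when the result would be
    non-positive (oxygen consumption unsustainable at this delivery).
    """
    cv = ca - assumptions.vo2_q_ml_dl
    if cv <= 0:
        raise InfeasibleStateError(
            f"mixed-venous content {cv:.3f} ml/dl non-positive "
            f"(Ca={ca:.3f}, VO2/Q={assumptions.vo2_q_ml_dl:.3f})"
        )
    return cv


def _steady_state_arrays(
    shunt,
    vq_sigma,
    q_total,
    hb,
    fio2,
    alveolar_ventilation,
    vo2,
    assumptions: PhysiologicalAssumptions,
    n_compartments: int = N_COMPARTMENTS,
    tol: float = _CA_TOL,
):
    """Vectorised steady-state solve. All parameters broadcast to 1-D.

    Returns ``(pao2, paco2, ph, converged)`` arrays. Non-convergence is
    reported in the mask, not raised, so batch callers can retry or
    discard; the scalar wrapper raises.
    """
    a = assumptions
    (shunt, vq_sigma, q_total, hb, fio2, va, vo2) = np.broadcast_arrays(
        *(
            np.atleast_1d(np.asarray(x, dtype=float))
            for x in (shunt, vq_sigma, q_total, hb, fio2, alveolar_ventilation, vo2)
        )
    )
    if np.any((shunt < 0) | (shunt > 0.95)):
        raise InvalidInputError("shunt must lie in [0, 0.95]")
    if np.any(vq_sigma < 0):
        raise InvalidInputError("vq_sigma must be non-negative")
    if np.any((q_total <= 0) | (va <= 0) | (vo2 <= 0) | (hb <= 0)):
        raise InvalidInputError("q_total, ventilation, vo2 and hb must be positive")
    if np.any((fio2 < 0.21 - 1e-9) | (fio2 > 1.0 + 1e-9)):
        raise InvalidInputError("fio2 must lie in [0.21, 1.0]")

    paco2 = a.k_gas * vo2 * a.rer / va
    ph = ph_from_paco2(paco2)
    p50v = odc.p50(ph, paco2, a.temperature)[:, None]
    pi = (fio2 * a.pio2)[:, None]
    rr = 100.0 * vo2 / q_total  # VO2/Q in ml/dl
    # Fick with a shunt requires an end-capillary/venous content gap of
    # VO2/Q/(1-shunt); beyond the attainable content span no steady state
    # exists (oxygen consumption unsustainable at this delivery). Such rows
    # are marked infeasible here; the residual sign test below catches the
    # remaining, subtler cases.
    c_span = a.o2_capacity * hb / 10.0 + a.o2_solubility * fio2 * a.pio2
    precheck_ok = rr / (1.0 - shunt) < c_span

    # Perfusion-uniform discretisation of the log-normal V/Q distribution:
    # equal-z nodes carry Gaussian perfusion weights, so mixing weights are
    # the same for every run and the V/Q ratio varies across compartments.
    z = np.linspace(-4.0, 4.0, n_compartments)
    w = np.exp(-0.5 * z**2)
    w /= w.sum()
    q_ns = q_total * (1.0 - shunt)
    log_r = (
        np.log(va / q_ns)[:, None]
        - 0.5 * (vq_sigma**2)[:, None]
        + vq_sigma[:, None] * z[None, :]
    )
    r = np.exp(log_r)
    # rescale so that discrete total ventilation matches VA exactly
    vent_total = (q_ns[:, None] * w[None, :] * r).sum(axis=1)
    r *= (va / vent_total)[:, None]
    k = 100.0 * r / a.k_gas  # content-units slope of the gas-side balance

    cap = (a.o2_capacity * hb / 10.0)[:, None]
    sol = a.o2_solubility

    def content(pa):
        return cap * odc._hill_saturation(pa, p50v) + sol * pa

    def dcontent(pa):
        return cap * odc._hill_saturation_derivative(pa, p50v) + sol

    def solve_compartments(cv, pa=None):
        """Root of C(PA) + k*PA = Cv + k*PI per compartment (monotone)."""
        target = cv[:, None] + k * pi
        if pa is None:
            lo = np.full_like(k, _PA_FLOOR)
            hi = np.broadcast_to(pi, k.shape).copy()
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                below = content(mid) + k * mid < target
                lo = np.where(below, mid, lo)
                hi = np.where(below, hi, mid)
            pa = 0.5 * (lo + hi)
        for _ in range(8):
            h = content(pa) + k * pa - target
            if np.max(np.abs(h)) < 1e-11:
                break
            pa = np.clip(pa - h / (dcontent(pa) + k), _PA_FLOOR, pi)
        return pa

    def arterial(cv, pa):
        pa = solve_compartments(cv, pa)
        cc = content(pa)
        ca = shunt * cv + (1.0 - shunt) * (w[None, :] * cc).sum(axis=1)
        return ca, pa

    # Secant iteration on the scalar-per-run fixed point Cv = Ca(Cv) - VO2/Q.
    # The residual g(Cv) = Ca(Cv) - VO2/Q - Cv is strictly decreasing
    # (dCa/dCv < 1), so g at the venous floor decides feasibility outright:
    # g(cv_lo) <= 0 means no steady state exists for these inputs.
    cv_lo = 0.02
    # venous cannot exceed Ca_max - VO2/Q; floor keeps infeasible rows inert
    cv_hi = np.maximum((cap[:, 0] + sol * pi[:, 0]) - rr, cv_lo)
    cv0 = np.full(rr.shape, cv_lo)
    ca0, pa = arterial(cv0, None)
    g0 = ca0 - rr - cv0
    feasible = precheck_ok & (g0 > tol)
    cv1 = np.clip(
        cap[:, 0] * odc._hill_saturation(5.0, p50v[:, 0]) + sol * 5.0, cv_lo, cv_hi
    )
    converged = np.zeros(cv0.shape, dtype=bool)
    ca1 = ca0
    for _ in range(_MAX_SECANT):
        ca1, pa = arterial(cv1, pa)
        g1 = ca1 - rr - cv1
        converged = np.abs(g1) < tol
        if (converged | ~feasible).all():
            break
        denom = g1 - g0
        safe = np.abs(denom) > 1e-14
        step = np.where(safe, g1 * (cv1 - cv0) / np.where(safe, denom, 1.0), 0.5 * g1)
        cv0, g0 = cv1, g1
        cv1 = np.clip(cv1 - step, cv_lo, cv_hi)

    converged &= feasible
    pao2 = np.full_like(cv1, np.nan)
    if converged.any():
        pao2[converged] = odc._po2_from_content_vec(
            ca1[converged], odc.p50(ph, paco2, a.temperature)[converged], hb[converged], a
        )
    return pao2, paco2, ph, converged, feasible


def steady_state(
    run: ModelRun,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    n_compartments: int = N_COMPARTMENTS,
) -> Tuple[float, float, float]:
    """Solve one run to steady state; returns (PaO2, PaCO2, pH).

    Also fills the run's ``out_*`` fields in place. Raises
    :class:`ConvergenceError` if the fixed point is not reached, and
    :class:`InfeasibleStateError` for unsustainable VO2/Q.
    """
    pao2, paco2, ph, ok, feasible = _steady_state_arrays(
        run.shunt,
        run.vq_sigma,
        run.q_total,
        run.hb,
        run.fio2,
        run.alveolar_ventilation,
        run.vo2,
        assumptions,
        n_compartments=n_compartments,
    )
    if not feasible[0]:
        raise InfeasibleStateError(
            f"no steady state exists for shunt={run.shunt}, "
            f"vq_sigma={run.vq_sigma}, q_total={run.q_total}, fio2={run.fio2}: "
            "oxygen consumption unsustainable at this delivery"
        )
    if not ok[0]:
        raise ConvergenceError(
            f"steady state did not converge for {run!r} "
            f"(shunt={run.shunt}, vq_sigma={run.vq_sigma}, fio2={run.fio2})"
        )
    run.out_pao2, run.out_paco2, run.out_ph = (
        float(pao2[0]),
        float(paco2[0]),
        float(ph[0]),
    )
    return run.out_pao2, run.out_paco2, run.out_ph


def steady_state_batch(
    inputs: pd.DataFrame,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    n_compartments: int = N_COMPARTMENTS,
    raise_on_failure: bool = True,
) -> pd.DataFrame:
    """Solve many runs at once.

    ``inputs`` needs columns shunt, vq_sigma, q_total, hb, fio2,
    alveolar_ventilation and optionally vo2. Returns a copy with
    out_pao2/out_paco2/out_ph (and, when ``raise_on_failure=False``,
    boolean ``converged`` and ``feasible`` columns; failed rows hold NaN
    outputs). With ``raise_on_failure=True`` an infeasible row raises
    :class:`InfeasibleStateError` and a feasible-but-unconverged row
    raises :class:`ConvergenceError`.
    """
    vo2 = inputs["vo2"] if "vo2" in inputs else assumptions.vo2
    pao2, paco2, ph, ok, feasible = _steady_state_arrays(
        inputs["shunt"].to_numpy(),
        inputs["vq_sigma"].to_numpy(),
        inputs["q_total"].to_numpy(),
        inputs["hb"].to_numpy(),
        inputs["fio2"].to_numpy(),
        inputs["alveolar_ventilation"].to_numpy(),
        np.asarray(vo2, dtype=float),
        assumptions,
        n_compartments=n_compartments,
    )
    if raise_on_failure:
        if not feasible.all():
            bad = np.flatnonzero(~feasible)
            raise InfeasibleStateError(
                f"{bad.size} of {feasible.size} runs have no steady state "
                f"(first infeasible row index: {bad[0]})"
            )
        if not ok.all():
            bad = np.flatnonzero(~ok)
            raise ConvergenceError(
                f"{bad.size} of {ok.size} runs failed to converge "
                f"(first failing row index: {bad[0]})"
            )
    out = inputs.copy()
    out["out_pao2"] = pao2
    out["out_paco2"] = paco2
    out["out_ph"] = ph
    if not raise_on_failure:
        out["converged"] = ok
        out["feasible"] = feasible
    return out


#: FiO2 values selectable on common ICU ventilators/analysers; also the
#: database FiO2 axis, so exact-to-grid FiO2 matching aligns with charted
#: values.
FIO2_SETTINGS = np.round(np.concatenate(([0.21], np.arange(0.25, 1.0001, 0.05))), 2)


@dataclasses.dataclass(frozen=True)
class DatabaseGrid:
    """Axes of the model-run database. All axes are configurable; the
    defaults are sized so a full build takes minutes on one CPU."""

    shunt: Sequence[float] = tuple(np.round(np.arange(0.0, 0.5001, 0.025), 3))
    vq_sigma: Sequence[float] = tuple(np.round(np.arange(0.0, 2.0001, 0.25), 2))
    q_total: Sequence[float] = (3.0, 4.5, 6.0, 7.5, 9.0)
    hb: Sequence[float] = (80.0, 110.0, 140.0)
    fio2: Sequence[float] = tuple(FIO2_SETTINGS)
    paco2: Sequence[float] = (4.2, 4.8, 5.4, 6.0, 6.6)

    def n_runs(self) -> int:
        return (
            len(self.shunt)
            * len(self.vq_sigma)
            * len(self.q_total)
            * len(self.hb)
            * len(self.fio2)
            * len(self.paco2)
        )

    @classmethod
    def from_yaml(cls, path) -> "DatabaseGrid":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown grid axes: {sorted(unknown)}")
        return cls(**{k: tuple(v) for k, v in raw.items()})


#: A deliberately small grid for unit tests and quick exploration.
COARSE_GRID = DatabaseGrid(
    shunt=tuple(np.round(np.arange(0.0, 0.5001, 0.05), 2)),
    vq_sigma=(0.0, 0.5, 1.0, 1.5),
    q_total=(4.5, 6.5),
    hb=(110.0,),
    fio2=tuple(FIO2_SETTINGS[::2]),
    paco2=(4.8, 5.4, 6.0),
)


def build_database(
    grid: DatabaseGrid = DatabaseGrid(),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    chunk_size: int = 25_000,
    n_compartments: int = N_COMPARTMENTS,
) -> pd.DataFrame:
    """Solve every grid point and return one ModelRun per row.

    The PaCO2 axis is realised by setting alveolar ventilation from the
    linear CO2 relation, so out_paco2 equals the axis value exactly.
    Grid points with no steady state (oxygen consumption unsustainable at
    that shunt/heterogeneity/FiO2/Q combination) are dropped — they are
    states incompatible with a living patient, so they cannot match any
    real ABG.
    """
    a = assumptions
    combos = np.array(
        list(
            itertools.product(
                grid.shunt, grid.vq_sigma, grid.q_total, grid.hb, grid.fio2, grid.paco2
            )
        ),
        dtype=float,
    )
    df = pd.DataFrame(
        combos, columns=["shunt", "vq_sigma", "q_total", "hb", "fio2", "paco2_target"]
    )
    df["vo2"] = a.vo2
    df["alveolar_ventilation"] = alveolar_ventilation_for_paco2(
        df["paco2_target"].to_numpy(), a
    )
    parts = []
    for start in range(0, len(df), chunk_size):
        part = steady_state_batch(
            df.iloc[start : start + chunk_size],
            a,
            n_compartments=n_compartments,
            raise_on_failure=False,
        )
        if not (part["converged"] | ~part["feasible"]).all():
            bad = part.index[~part["converged"] & part["feasible"]]
            raise ConvergenceError(
                f"{len(bad)} feasible grid points failed to converge "
                f"(first: {df.loc[bad[0]].to_dict()})"
            )
        parts.append(part[part["feasible"]])
    out = pd.concat(parts, ignore_index=True)
    return out.drop(columns=["paco2_target", "converged", "feasible"])
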