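"""Oxygen carriage physics.

This module holds the physiological primitives that every oxygenation
measure in the package is built from:

* the oxyhaemoglobin dissociation curve (ODC) — saturation as a function
  of oxygen tension, with the half-saturation tension P50 shifted by pH,
  PaCO2 and temperature (the Bohr effect);
* blood oxygen *content* (haemoglobin-bound plus dissolved);
* the alveolar gas equation (ideal alveolar PO2 from FiO2 and PaCO2);
* the numerical inversion from content back to tension, which is what
  turns a predicted arterial O2 content into a predicted PaO2.

The ODC is a Hill-type closed form with a tension-dependent Hill
exponent and a multiplicative P50 shift for each modifier, in the style
of Dash, Korman and Bassingthwaighte's simple dissociation-curve models.
2,3-DPG is held at its standard concentration (it is not measured
clinically), so its shift factor is unity and is omitted.

All tensions are kilopascals internally; ``MMHG_PER_KPA`` converts at
the I/O boundary only. Contents are ml O2 per dl blood; haemoglobin is
g/l at the interface (the clinical reporting unit) and g/dl inside the
content equation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import ContentRangeError, InvalidInputError

MMHG_PER_KPA = 7.50062

#: Standard half-saturation tension (mmHg) at pH 7.4, PaCO2 40 mmHg, 37 C,
#: standard 2,3-DPG. The kPa equivalent is ~3.573 kPa.
P50_STANDARD_MMHG = 26.8

# Hill exponent varies with tension: n(P) = alpha - beta * 10^(-P/gamma),
# P in mmHg. Lower cooperativity at low tension, ~2.8 at arterial tensions.
_HILL_ALPHA = 2.82
_HILL_BETA = 1.20
_HILL_GAMMA_MMHG = 29.25

_LN10 = np.log(10.0)


def kpa_to_mmhg(x):
    """Convert a tension from kPa to mmHg (array-safe)."""
    return np.asarray(x, dtype=float) * MMHG_PER_KPA


def mmhg_to_kpa(x):
    """Convert a tension from mmHg to kPa (array-safe)."""
    return np.asarray(x, dtype=float) / MMHG_PER_KPA


@dataclasses.dataclass(frozen=True)
class PhysiologicalAssumptions:
    """Assumed constants behind every content calculation.

    The effective shunt computation requires values for whole-body oxygen
    consumption and cardiac output that are not available from a blood gas
    sample; they are fixed at single mid-physiological values and exposed
    here so that their influence can be swept (see
    :func:`effshunt.indices.es_sensitivity`).

    Parameters
    ----------
    rer:
        Respiratory exchange ratio VCO2/VO2, dimensionless.
    q_total:
        Cardiac output, l/min.
    vo2:
        Oxygen consumption, l(STPD)/min.
    pb:
        Barometric pressure, kPa (standard sea level).
    ph2o:
        Saturated water vapour pressure at body temperature, kPa.
    hb_default:
        Haemoglobin fallback when a record omits it, g/l.
    o2_capacity:
        Huefner constant, ml O2 per g Hb.
    o2_solubility:
        Dissolved O2, ml/dl/kPa.
    temperature:
        Default body temperature, Celsius; used when a record omits it.
        Measured tensions are used as reported (no electrode temperature
        correction).
    k_gas:
        Gas-phase transport constant, kPa x l(BTPS)/l(STPD): alveolar
        partial-pressure change per unit STPD gas flux per unit BTPS
        ventilation (the familiar 863 mmHg expressed in kPa). Shared by
        the O2 and CO2 alveolar mass balances so that the simulator's
        ideal-compartment limit reproduces the alveolar gas equation.
    """

    rer: float = 0.8
    q_total: float = 6.5
    vo2: float = 0.25
    pb: float = 101.325
    ph2o: float = 6.27
    hb_default: float = 110.0
    o2_capacity: float = 1.34
    o2_solubility: float = 0.0225
    temperature: float = 37.0
    k_gas: float = 863.0 / MMHG_PER_KPA

    def __post_init__(self) -> None:
        if not (0.7 <= self.rer <= 1.2):
            raise InvalidInputError(f"rer={self.rer} outside [0.7, 1.2]")
        if self.q_total <= 0 or self.vo2 <= 0:
            raise InvalidInputError("q_total and vo2 must be positive")
        if not (self.pb > self.ph2o > 0):
            raise InvalidInputError("require pb > ph2o > 0")
        if self.hb_default <= 0:
            raise InvalidInputError("hb_default must be positive")
        # A VO2/Q ratio exceeding the arterial O2 content attainable at the
        # fallback Hb implies negative mixed-venous content. Published
        # sensitivity sweeps deliberately cross this line, so it is a
        # warning here; the simulator enforces it as a hard error where a
        # real venous compartment must exist.
        if self.vo2_q_ml_dl >= self.o2_capacity * self.hb_default / 10.0:
            warnings.warn(
                "VO2/Q exceeds arterial O2 content at fallback Hb; "
                "mixed-venous content would be negative",
                stacklevel=2,
            )

    @property
    def vo2_q_ml_dl(self) -> float:
        """VO2/Q expressed in content units (ml O2/dl blood)."""
        return 100.0 * self.vo2 / self.q_total

    @property
    def pio2(self) -> float:
        """Inspired O2 tension at FiO2 = 1 (kPa), i.e. pb - ph2o."""
        return self.pb - self.ph2o

    def replace(self, **changes: Any) -> "PhysiologicalAssumptions":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path) -> "PhysiologicalAssumptions":
        """Load assumption overrides from a key-value YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown assumption keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_ASSUMPTIONS = PhysiologicalAssumptions()


def p50(ph=7.4, paco2=5.33, temperature=37.0):
    """Half-saturation O2 tension (kPa) at the given pH, PaCO2, temperature.

    The standard value (pH 7.4, PaCO2 40 mmHg, 37 C) is 26.8 mmHg; each
    modifier scales it multiplicatively. Acidaemia and hypercapnia shift
    the curve right (higher P50, easier unloading); alkalaemia and
    hypocapnia shift it left. Vectorised over all arguments.
    """
    ph = np.asarray(ph, dtype=float)
    dph = ph - 7.4
    dco2 = kpa_to_mmhg(paco2) - 40.0
    dt = np.asarray(temperature, dtype=float) - 37.0
    f_ph = P50_STANDARD_MMHG - 21.279 * dph + 8.872 * dph**2 - 1.47 * dph**3
    f_co2 = P50_STANDARD_MMHG + 4.28e-3 * dco2 + 3.64e-5 * dco2**2
    f_t = P50_STANDARD_MMHG + 1.435 * dt + 4.163e-2 * dt**2 + 6.86e-4 * dt**3
    p50_mmhg = P50_STANDARD_MMHG * (f_ph / P50_STANDARD_MMHG) * (
        f_co2 / P50_STANDARD_MMHG
    ) * (f_t / P50_STANDARD_MMHG)
    out = mmhg_to_kpa(p50_mmhg)
    return float(out) if out.ndim == 0 else out


def _hill_saturation(po2_kpa, p50_kpa):
    """Hill-form SO2 given tension and P50, both kPa. Vectorised."""
    pm = np.asarray(po2_kpa, dtype=float) * MMHG_PER_KPA
    n = _HILL_ALPHA - _HILL_BETA * np.exp(-pm * (_LN10 / _HILL_GAMMA_MMHG))
    # u = (P/P50)^n computed in log space for speed and stability
    u = np.exp(n * (np.log(po2_kpa) - np.log(p50_kpa)))
    return u / (1.0 + u)


def _hill_saturation_derivative(po2_kpa, p50_kpa):
    """dSO2/dPO2 (per kPa) of the Hill form. Vectorised."""
    po2_kpa = np.asarray(po2_kpa, dtype=float)
    pm = po2_kpa * MMHG_PER_KPA
    e = np.exp(-pm * (_LN10 / _HILL_GAMMA_MMHG))
    n = _HILL_ALPHA - _HILL_BETA * e
    dn = _HILL_BETA * (_LN10 / _HILL_GAMMA_MMHG) * MMHG_PER_KPA * e
    logx = np.log(po2_kpa) - np.log(p50_kpa)
    u = np.exp(n * logx)
    dlogu = dn * logx + n / po2_kpa
    return u * dlogu / (1.0 + u) ** 2


def hb_saturation(po2, ph=7.4, paco2=5.33, temperature=37.0):
    """Fractional haemoglobin O2 saturation at the given tension.

    Strictly increasing in ``po2``; the Bohr effect enters through the
    P50 shift, so saturation falls as pH falls or PaCO2 rises at fixed
    tension. Returns a value in (0, 1); equals 0.5 exactly at
    ``po2 == p50(ph, paco2, temperature)``.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise InvalidInputError("po2 must be positive")
    out = _hill_saturation(po2, p50(ph, paco2, temperature))
    return float(out) if out.ndim == 0 else out


def oxygen_content(
    po2,
    ph=7.4,
    paco2=5.33,
    hb=150.0,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    temperature=None,
):
    """Blood O2 content (ml/dl): Hb-bound plus dissolved.

    content = o2_capacity * Hb[g/dl] * SO2 + o2_solubility * PO2.
    ``hb`` is in g/l. Vectorised over tensions.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 <= 0):
        raise InvalidInputError("po2 must be positive")
    hb = np.asarray(hb, dtype=float)
    if np.any(hb < 0):
        raise InvalidInputError("hb must be non-negative")
    t = assumptions.temperature if temperature is None else temperature
    sat = _hill_saturation(po2, p50(ph, paco2, t))
    out = assumptions.o2_capacity * (hb / 10.0) * sat + assumptions.o2_solubility * po2
    return float(out) if out.ndim == 0 else out


# Bracket for the content -> tension inversion (kPa). Monotone objective
# makes bracketed root finding unconditionally safe on this interval.
PO2_BRACKET = (0.05, 300.0)
_INVERSION_XTOL = 1e-8


def po2_from_content(
    content: float,
    ph=7.4,
    paco2=5.33,
    hb=150.0,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    temperature=None,
) -> float:
    """Invert :func:`oxygen_content`: the tension giving this content.

    Content is strictly increasing in tension, so the root is unique;
    it is found by bracketed root-finding on ``PO2_BRACKET`` to an
    absolute tolerance of 1e-8 kPa. Raises :class:`ContentRangeError`
    when the requested content is unattainable at the given Hb,
    identifying the violated bound.
    """
    t = assumptions.temperature if temperature is None else temperature
    p50_val = p50(ph, paco2, t)
    hb_term = assumptions.o2_capacity * (hb / 10.0)

    def f(po2: float) -> float:
        return (
            hb_term * _hill_saturation(po2, p50_val)
            + assumptions.o2_solubility * po2
            - content
        )

    lo, hi = PO2_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0:
        raise ContentRangeError(
            f"content {content:.4f} ml/dl below the minimum attainable "
            f"{content - f_lo:.4f} ml/dl at PO2 = {lo} kPa"
        )
    if f_hi < 0:
        raise ContentRangeError(
            f"content {content:.4f} ml/dl above the maximum attainable "
            f"{content - f_hi:.4f} ml/dl at PO2 = {hi} kPa (Hb = {hb} g/l)"
        )
    return float(brentq(f, lo, hi, xtol=_INVERSION_XTOL))


def _po2_from_content_vec(content, p50_kpa, hb, assumptions, n_iter=60):
    """Vectorised bisection inverse of the content relation.

    Used by the simulator where thousands of inversions are needed at
    once. 60 bisection steps on the standard bracket give ~3e-16 kPa
    resolution. Inputs must be broadcastable arrays; out-of-range
    contents raise :class:`ContentRangeError`.
    """
    content = np.asarray(content, dtype=float)
    hb_term = assumptions.o2_capacity * (np.asarray(hb, dtype=float) / 10.0)

    def f(po2):
        return (
            hb_term * _hill_saturation(po2, p50_kpa)
            + assumptions.o2_solubility * po2
            - content
        )

    lo = np.full(np.broadcast_shapes(content.shape, np.shape(p50_kpa)), PO2_BRACKET[0])
    hi = np.full_like(lo, PO2_BRACKET[1])
    if np.any(f(lo) > 0) or np.any(f(hi) < 0):
        raise ContentRangeError("content outside attainable range in batch inversion")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = f(mid) < 0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def alveolar_po2(
    fio2: float,
    paco2: float,
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    inspired_correction: bool = False,
):
    """Ideal alveolar O2 tension (kPa) from the alveolar gas equation.

    Default is the simplified form

        PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RER

    whose neglected inspired-gas correction term, PaCO2*FiO2*(1 - 1/RER),
    is < 0.3 kPa on room air at RER 0.8 and vanishes as RER -> 1.
    ``inspired_correction=True`` applies the full form
    PAO2 = FiO2*(Pb-PH2O) - PaCO2*(FiO2 + (1-FiO2)/RER).

    Raises :class:`InvalidInputError` for a non-positive result
    (pathological PaCO2/RER combination); never clamps silently.
    """
    fio2 = np.asarray(fio2, dtype=float)
    paco2 = np.asarray(paco2, dtype=float)
    if np.any(fio2 < 0.21 - 1e-9) or np.any(fio2 > 1.0 + 1e-9):
        raise InvalidInputError(f"fio2 must lie in [0.21, 1.0], got {fio2}")
    if np.any(paco2 < 0):
        raise InvalidInputError("paco2 must be non-negative")
    pi = fio2 * (assumptions.pb - assumptions.ph2o)
    if inspired_correction:
        out = pi - paco2 * (fio2 + (1.0 - fio2) / assumptions.rer)
    else:
        out = pi - paco2 / assumptions.rer
    if np.any(out <= 0):
        raise InvalidInputError(
            f"alveolar PO2 non-positive (fio2={fio2}, paco2={paco2}, "
            f"rer={assumptions.rer})"
        )
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class BloodCompartmentState:
    """A (tension, saturation, content) triple for one blood compartment."""

    po2: float
    so2: float
    content: float

    @classmethod
    def from_po2(
        cls,
        po2: float,
        ph: float = 7.4,
        paco2: float = 5.33,
        hb: float = 150.0,
        assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
        temperature=None,
    ) -> "BloodCompartmentState":
        t = assumptions.temperature if temperature is None else temperature
        so2 = float(hb_saturation(po2, ph, paco2, t))
        content = assumptions.o2_capacity * (hb / 10.0) * so2 + (
            assumptions.o2_solubility * po2
        )
        return cls(po2=float(po2), so2=so2, content=float(content))
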