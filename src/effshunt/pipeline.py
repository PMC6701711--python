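"""Cohort-level predictive validity of oxygenation measures.

The evaluation asks a simple question of each measure: computed on one
ABG, how well does it predict the PaO2 actually measured after the FiO2
was changed? Pairs of ABGs are selected so that the underlying lung is
unlikely to have changed between samples:

1. taken within a 3-hour window,
2. from a mechanically ventilated patient,
3. FiO2 reduced between the first and second sample (weaning, which
   avoids absorption-atelectasis artefacts of FiO2 increases),
4. stable alveolar ventilation (|change in PaCO2| < 0.3 kPa, strict).

Per pair and measure, the measure is computed on the first record, the
second PaO2 is predicted at the second record's FiO2/PaCO2 assuming the
measure is unchanged, and the absolute error against the measured value
is recorded. The median absolute error (MAE) over pairs is the
measure's predictive validity. Errors are compared across measures with
a Kruskal-Wallis omnibus test and pairwise Mann-Whitney U tests with
Bonferroni correction.

The baseline noise floor — the median |change in PaO2| across pairs
meeting every criterion except that FiO2 was *unchanged* — bounds the
accuracy any measure could achieve.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import db as dbmod
from . import indices
from .errors import GasExchangeError, InvalidInputError, PredictionError
from .indices import ABGRecord
from .odc import DEFAULT_ASSUMPTIONS, PhysiologicalAssumptions

logger = logging.getLogger(__name__)

MEASURES = ("es", "pf", "aa", "db")

MAX_INTERVAL_MIN = 180.0
MAX_DPACO2_KPA = 0.3


@dataclasses.dataclass(frozen=True)
class ABGPair:
    """Ordered within-patient pair of records passing the selection
    filters; the unit of predictive-validity scoring."""

    first: ABGRecord
    second: ABGRecord
    interval_min: float


def _interval_min(first: ABGRecord, second: ABGRecord) -> float:
    return (second.timestamp - first.timestamp).total_seconds() / 60.0


def _qualifying_pairs(records, fio2_rule) -> List[ABGPair]:
    by_patient: Dict[str, List[ABGRecord]] = {}
    n_skipped = 0
    for rec in records:
        if rec.patient_id is None or rec.timestamp is None:
            n_skipped += 1
            continue
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if n_skipped:
        logger.info("skipped %d records missing id/timestamp", n_skipped)
    pairs: List[ABGPair] = []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: r.timestamp)
        for first, second in itertools.combinations(recs, 2):
            dt = _interval_min(first, second)
            if not (0.0 < dt <= MAX_INTERVAL_MIN):
                continue
            if not (first.ventilated and second.ventilated):
                continue
            if not fio2_rule(first.fio2, second.fio2):
                continue
            # strict "< 0.3 kPa", robust to float representation of the
            # difference (e.g. 5.3 - 5.0)
            if abs(second.paco2 - first.paco2) >= MAX_DPACO2_KPA - 1e-9:
                continue
            pairs.append(ABGPair(first, second, dt))
    pairs.sort(key=lambda p: (p.first.patient_id, p.first.timestamp, p.second.timestamp))
    return pairs


def filter_pairs(
    records: Sequence[ABGRecord], consecutive_only: bool = False
) -> List[ABGPair]:
    """Select the ordered within-patient pairs meeting the four criteria.

    Every qualifying ordered pair within the 3-h window is returned (a
    record may appear in several pairs); ``consecutive_only`` restricts
    to pairs of time-adjacent samples. Output is deterministically
    ordered by (patient, first timestamp, second timestamp), and the
    selection is a pure function of the record set — input order is
    irrelevant.
    """
    pairs = _qualifying_pairs(records, lambda f1, f2: f2 < f1)
    if consecutive_only:
        order: Dict[str, List] = {}
        for rec in records:
            order.setdefault(rec.patient_id, []).append(rec)
        adjacent = set()
        for pid, recs in order.items():
            recs = sorted(recs, key=lambda r: r.timestamp)
            for a, b in zip(recs, recs[1:]):
                adjacent.add((pid, a.timestamp, b.timestamp))
        pairs = [
            p
            for p in pairs
            if (p.first.patient_id, p.first.timestamp, p.second.timestamp) in adjacent
        ]
    return pairs


@dataclasses.dataclass
class BaselineResult:
    """Distribution of |PaO2 change| across unchanged-FiO2 pairs."""

    deltas: np.ndarray
    n_pairs: int

    @property
    def median(self) -> float:
        return float(np.median(self.deltas)) if self.n_pairs else float("nan")


def baseline_error(records: Sequence[ABGRecord]) -> BaselineResult:
    """Noise floor: |PaO2 change| over pairs with *unchanged* FiO2.

    Same selection as :func:`filter_pairs` with criterion (3) replaced
    by equality of FiO2. Real physiological drift plus measurement noise
    over a <=3-h window — no measure can predict better than this.
    """
    pairs = _qualifying_pairs(records, lambda f1, f2: abs(f2 - f1) < 1e-9)
    deltas = np.array([abs(p.second.pao2 - p.first.pao2) for p in pairs])
    return BaselineResult(deltas=deltas, n_pairs=len(pairs))


def _predict_pair(
    pair: ABGPair,
    measure: str,
    assumptions: PhysiologicalAssumptions,
    database: Optional[pd.DataFrame],
    tolerances: dbmod.MatchTolerances,
) -> float:
    """Predicted second-sample PaO2 for one measure; raises
    PredictionError when the measure cannot make a prediction."""
    first, second = pair.first, pair.second
    hb = first.hb if first.hb is not None else assumptions.hb_default
    if measure == "es":
        es = indices.effective_shunt(first, assumptions)
        return indices.predict_pao2_es(
            es, second.fio2, second.paco2, second.ph, hb, assumptions
        )
    if measure == "pf":
        return indices.predict_pao2_pf(indices.pf_ratio(first), second.fio2)
    if measure == "aa":
        aa = indices.aa_difference(first, assumptions)
        return indices.predict_pao2_aa(aa, second.fio2, second.paco2, assumptions)
    if measure == "db":
        if database is None:
            raise InvalidInputError("the 'db' measure requires a database")
        matches = dbmod.match_abg(database, first, tolerances, assumptions)
        if matches.empty:
            raise PredictionError("empty match set for first record")
        return dbmod.db_predict(matches, second.fio2, second.paco2, assumptions)
    raise InvalidInputError(f"unknown measure {measure!r}")


@dataclasses.dataclass
class MeasureScore:
    mae: float
    n_scored: int
    n_failed: int


@dataclasses.dataclass
class PairwiseComparison:
    measure_1: str
    measure_2: str
    u_statistic: float
    p_raw: float
    p_adjusted: float


@dataclasses.dataclass
class ErrorComparison:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise U tests."""

    h_statistic: float
    p_omnibus: float
    pairwise: List[PairwiseComparison]


@dataclasses.dataclass
class ValidityResult:
    per_measure: Dict[str, MeasureScore]
    errors: Dict[str, np.ndarray]
    comparison: Optional[ErrorComparison]
    n_pairs: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": m,
                    "mae_kpa": s.mae,
                    "n_scored": s.n_scored,
                    "n_failed": s.n_failed,
                }
                for m, s in self.per_measure.items()
            ]
        )


def compare_errors(errors: Dict[str, np.ndarray]) -> ErrorComparison:
    """Nonparametric comparison of per-pair absolute errors by measure.

    Returns the Kruskal-Wallis H and p over all measures and two-sided
    Mann-Whitney U tests for every pair of measures, Bonferroni-
    multiplied by the number of comparisons and capped at 1. Fully tied
    input yields p = 1 rather than an exception.
    """
    names = [m for m in errors if len(errors[m]) >= 2]
    if len(names) < 2:
        raise InvalidInputError("need at least two measures with >=2 errors each")
    groups = [np.asarray(errors[m], dtype=float) for m in names]
    if np.ptp(np.concatenate(groups)) == 0:
        h, p_omnibus = 0.0, 1.0  # fully tied input: no evidence of difference
    else:
        try:
            h, p_omnibus = stats.kruskal(*groups)
        except ValueError:
            h, p_omnibus = 0.0, 1.0
    n_comparisons = len(names) * (len(names) - 1) // 2
    pairwise = []
    for m1, m2 in itertools.combinations(names, 2):
        x, y = np.asarray(errors[m1], float), np.asarray(errors[m2], float)
        if np.ptp(np.concatenate([x, y])) == 0:
            u, p_raw = len(x) * len(y) / 2.0, 1.0
        else:
            method = "exact" if max(len(x), len(y)) <= 20 else "auto"
            u, p_raw = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        pairwise.append(
            PairwiseComparison(
                measure_1=m1,
                measure_2=m2,
                u_statistic=float(u),
                p_raw=float(p_raw),
                p_adjusted=min(1.0, float(p_raw) * n_comparisons),
            )
        )
    return ErrorComparison(
        h_statistic=float(h), p_omnibus=float(p_omnibus), pairwise=pairwise
    )


def evaluate(
    pairs: Sequence[ABGPair],
    measures: Sequence[str] = ("es", "pf", "aa"),
    assumptions: PhysiologicalAssumptions = DEFAULT_ASSUMPTIONS,
    database: Optional[pd.DataFrame] = None,
    tolerances: dbmod.MatchTolerances = dbmod.MatchTolerances(),
    drop_failed_pairs: bool = False,
    compare: bool = True,
) -> ValidityResult:
    """Score each measure's PaO2 predictions over the selected pairs.

    Prediction failures (infeasible A-a prediction, empty DB match set)
    are counted per measure and excluded from that measure's median; with
    ``drop_failed_pairs=True`` a pair failing for any measure is dropped
    for all of them, keeping the medians directly comparable.
    """
    if not pairs:
        raise InvalidInputError("no pairs to evaluate")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise InvalidInputError(f"unknown measures: {sorted(unknown)}")
    if "db" in measures and database is None:
        raise InvalidInputError("the 'db' measure requires a database")
    raw: Dict[str, List[float]] = {m: [] for m in measures}
    failed: Dict[str, int] = {m: 0 for m in measures}
    per_pair: List[Dict[str, Optional[float]]] = []
    for pair in pairs:
        row: Dict[str, Optional[float]] = {}
        for m in measures:
            try:
                pred = _predict_pair(pair, m, assumptions, database, tolerances)
                row[m] = abs(pred - pair.second.pao2)
            except GasExchangeError:
                row[m] = None  # prediction failure for this pair/measure
        per_pair.append(row)
    for row in per_pair:
        if drop_failed_pairs and any(row[m] is None for m in measures):
            for m in measures:
                failed[m] += 1
            continue
        for m in measures:
            if row[m] is None:
                failed[m] += 1
            else:
                raw[m].append(row[m])
    errors = {m: np.asarray(v, dtype=float) for m, v in raw.items()}
    per_measure = {
        m: MeasureScore(
            mae=float(np.median(errors[m])) if len(errors[m]) else float("nan"),
            n_scored=len(errors[m]),
            n_failed=failed[m],
        )
        for m in measures
    }
    comparison = None
    if compare and sum(len(v) >= 2 for v in errors.values()) >= 2:
        comparison = compare_errors(
            {m: v for m, v in errors.items() if len(v) >= 2}
        )
    return ValidityResult(
        per_measure=per_measure,
        errors=errors,
        comparison=comparison,
        n_pairs=len(pairs),
    )
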