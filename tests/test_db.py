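"""Database matching, extrapolation, and state-envelope constraint."""

import datetime as dt

import numpy as np
import pytest

from effshunt import db as dbmod
from effshunt import indices, odc, simulator
from effshunt.errors import InvalidInputError
from effshunt.simulator import ModelRun, alveolar_ventilation_for_paco2, steady_state

A = odc.PhysiologicalAssumptions()


def record_from_db_row(row, pid="q"):
    return indices.ABGRecord(
        patient_id=pid,
        timestamp=dt.datetime(2024, 1, 1),
        fio2=float(row["fio2"]),
        pao2=float(row["out_pao2"]),
        paco2=float(row["out_paco2"]),
        ph=float(row["out_ph"]),
        hb=float(row["hb"]),
    )


class TestMatchAbg:
    def test_self_match(self, coarse_db):
        row = coarse_db.iloc[len(coarse_db) // 3]
        matches = dbmod.match_abg(coarse_db, record_from_db_row(row))
        assert not matches.empty
        same = matches.runs[
            (matches.runs["shunt"] == row["shunt"])
            & (matches.runs["vq_sigma"] == row["vq_sigma"])
            & (matches.runs["q_total"] == row["q_total"])
        ]
        assert len(same) >= 1

    def test_zero_tolerance_off_grid_empty(self, coarse_db):
        row = coarse_db.iloc[10]
        rec = record_from_db_row(row)
        rec = indices.ABGRecord(
            patient_id="q",
            timestamp=rec.timestamp,
            fio2=rec.fio2,
            pao2=rec.pao2 + 0.123,
            paco2=rec.paco2,
            ph=rec.ph,
            hb=rec.hb,
        )
        tol = dbmod.MatchTolerances(pao2=0.0, paco2=0.0)
        assert dbmod.match_abg(coarse_db, rec, tol).empty

    def test_widening_tolerances_monotone(self, coarse_db):
        rec = record_from_db_row(coarse_db.iloc[100])
        sizes = [
            len(dbmod.match_abg(coarse_db, rec, dbmod.MatchTolerances(pao2=t, paco2=0.3)))
            for t in (0.1, 0.5, 1.5)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_empty_database_rejected(self, coarse_db):
        with pytest.raises(InvalidInputError):
            dbmod.match_abg(coarse_db.iloc[0:0], record_from_db_row(coarse_db.iloc[0]))


class TestDbPredict:
    def test_identity_at_same_settings(self, coarse_db):
        row = coarse_db.iloc[500]
        matches = dbmod.match_abg(coarse_db, record_from_db_row(row))
        single = dbmod.MatchSet(
            runs=matches.runs[
                (matches.runs["shunt"] == row["shunt"])
                & (matches.runs["vq_sigma"] == row["vq_sigma"])
                & (matches.runs["q_total"] == row["q_total"])
                & (matches.runs["hb"] == row["hb"])
            ],
            tolerances=matches.tolerances,
            record=matches.record,
        )
        pred = dbmod.db_predict(single, row["fio2"], row["out_paco2"], A)
        assert pred == pytest.approx(row["out_pao2"], abs=1e-6)

    def test_mean_of_two(self, coarse_db):
        two = dbmod.MatchSet(
            runs=coarse_db.iloc[[200, 300]],
            tolerances=dbmod.MatchTolerances(),
            record=record_from_db_row(coarse_db.iloc[200]),
        )
        row_a, row_b = coarse_db.iloc[200], coarse_db.iloc[300]
        pred = dbmod.db_predict(two, 0.5, 5.4, A)
        separate = []
        for row in (row_a, row_b):
            one = dbmod.MatchSet(
                runs=coarse_db.iloc[[row.name]],
                tolerances=dbmod.MatchTolerances(),
                record=two.record,
            )
            separate.append(dbmod.db_predict(one, 0.5, 5.4, A))
        assert pred == pytest.approx(np.mean(separate), abs=1e-9)

    def test_pure_shunt_roundtrip_within_grid_error(self, coarse_db):
        # simulate an on-grid pure-shunt patient at two FiO2 levels and
        # check the DB extrapolation hits the second PaO2
        runs = {}
        for fio2 in (0.6, 0.4):
            run = ModelRun(
                shunt=0.2, vq_sigma=0.0, q_total=6.5, hb=110.0, fio2=fio2,
                alveolar_ventilation=float(alveolar_ventilation_for_paco2(5.4, A)),
            )
            steady_state(run, A)
            runs[fio2] = run
        first = record_from_db_row(
            {
                "fio2": 0.6,
                "out_pao2": runs[0.6].out_pao2,
                "out_paco2": runs[0.6].out_paco2,
                "out_ph": runs[0.6].out_ph,
                "hb": 110.0,
            }
        )
        matches = dbmod.match_abg(coarse_db, first)
        assert not matches.empty
        pred = dbmod.db_predict(matches, 0.4, runs[0.4].out_paco2, A)
        assert pred == pytest.approx(runs[0.4].out_pao2, abs=1.0)

    def test_empty_matchset_rejected(self, coarse_db):
        empty = dbmod.MatchSet(
            runs=coarse_db.iloc[0:0],
            tolerances=dbmod.MatchTolerances(),
            record=record_from_db_row(coarse_db.iloc[0]),
        )
        with pytest.raises(InvalidInputError):
            dbmod.db_predict(empty, 0.4, 5.3, A)


class TestConstrainState:
    def _two_records(self, coarse_db, shunt=0.15, vq=0.5, paco2=5.4):
        recs = []
        for fio2 in (0.61, 0.41):
            run = ModelRun(
                shunt=shunt, vq_sigma=vq, q_total=6.5, hb=110.0, fio2=fio2,
                alveolar_ventilation=float(alveolar_ventilation_for_paco2(paco2, A)),
            )
            steady_state(run, A)
            recs.append(
                record_from_db_row(
                    {
                        "fio2": fio2,
                        "out_pao2": run.out_pao2,
                        "out_paco2": run.out_paco2,
                        "out_ph": run.out_ph,
                        "hb": 110.0,
                    }
                )
            )
        return recs

    def test_single_abg_ambiguous(self, coarse_db):
        # tolerances at the coarse grid's spacing: one ABG cannot separate
        # shunt from V/Q heterogeneity
        recs = self._two_records(coarse_db)
        tol = dbmod.MatchTolerances(pao2=1.0, paco2=0.3)
        env = dbmod.constrain_state(coarse_db, recs[:1], tol)
        assert env.n_cells > 1
        lo, hi = env.ranges["shunt"]
        assert lo < hi

    def test_second_abg_strictly_constrains(self, coarse_db):
        recs = self._two_records(coarse_db)
        env1 = dbmod.constrain_state(coarse_db, recs[:1])
        env2 = dbmod.constrain_state(coarse_db, recs)
        assert env2.issubset(env1)
        assert env2.n_cells <= env1.n_cells

    def test_envelope_contains_generating_state(self, coarse_db):
        # records generated from an on-grid run must keep that run inside
        recs = self._two_records(coarse_db, shunt=0.2, vq=0.5)
        env2 = dbmod.constrain_state(coarse_db, recs)
        assert not env2.empty
        assert (0.2, 0.5, 6.5, 110.0) in env2

    def test_mismatched_patients_rejected(self, coarse_db):
        recs = self._two_records(coarse_db)
        other = indices.ABGRecord(
            patient_id="other",
            timestamp=recs[1].timestamp,
            fio2=recs[1].fio2,
            pao2=recs[1].pao2,
            paco2=recs[1].paco2,
            ph=recs[1].ph,
            hb=recs[1].hb,
        )
        with pytest.raises(InvalidInputError):
            dbmod.constrain_state(coarse_db, [recs[0], other])

    def test_empty_envelope_reported(self, coarse_db):
        rec = indices.ABGRecord(
            patient_id="q",
            timestamp=dt.datetime(2024, 1, 1),
            fio2=1.0,
            pao2=1.0,  # deep hypoxaemia on pure O2: off the coarse grid
            paco2=5.4,
            ph=7.4,
            hb=110.0,
        )
        env = dbmod.constrain_state(
            coarse_db, [rec], dbmod.MatchTolerances(pao2=0.01, paco2=0.01)
        )
        assert env.empty and env.n_cells == 0
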