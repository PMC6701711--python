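"""Steady-state gas-exchange model: limits, conservation, monotonicity."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from effshunt import indices, odc, simulator
from effshunt.errors import InfeasibleStateError, InvalidInputError
from effshunt.simulator import ModelRun, alveolar_ventilation_for_paco2, steady_state

A = odc.PhysiologicalAssumptions()


def run_for(shunt=0.0, vq_sigma=0.0, q_total=6.5, hb=110.0, fio2=0.4, paco2=5.3, vo2=None):
    vo2 = A.vo2 if vo2 is None else vo2
    return ModelRun(
        shunt=shunt,
        vq_sigma=vq_sigma,
        q_total=q_total,
        hb=hb,
        fio2=fio2,
        alveolar_ventilation=float(alveolar_ventilation_for_paco2(paco2, A, vo2=vo2)),
        vo2=vo2,
    )


def as_record(run: ModelRun, pid="sim") -> indices.ABGRecord:
    return indices.ABGRecord(
        patient_id=pid,
        timestamp=dt.datetime(2024, 1, 1),
        fio2=run.fio2,
        pao2=run.out_pao2,
        paco2=run.out_paco2,
        ph=run.out_ph,
        hb=run.hb,
    )


class TestCO2Side:
    def test_paco2_follows_ventilation_equation(self):
        run = run_for(paco2=5.3)
        _, paco2, _ = steady_state(run, A)
        assert paco2 == pytest.approx(5.3, abs=1e-12)

    def test_ph_standard(self):
        # zero base excess: PaCO2 5.33 kPa -> pH close to 7.40
        assert simulator.ph_from_paco2(5.33) == pytest.approx(7.40, abs=0.01)

    def test_ventilation_retune_closed_form(self):
        va = alveolar_ventilation_for_paco2(6.0, A)
        assert A.k_gas * A.vo2 * A.rer / va == pytest.approx(6.0, abs=1e-12)


class TestLimits:
    def test_ideal_lung_reaches_alveolar_tension(self):
        run = run_for(shunt=0.0, vq_sigma=0.0, fio2=0.3)
        pao2, paco2, _ = steady_state(run, A)
        assert pao2 == pytest.approx(odc.alveolar_po2(0.3, paco2, A), abs=1e-3)

    def test_high_shunt_far_below_alveolar(self):
        # near-total shunt at a VO2/Q low enough to remain feasible
        run = run_for(shunt=0.9, fio2=0.6, vo2=0.08)
        pao2, paco2, _ = steady_state(run, A)
        assert pao2 < 0.2 * odc.alveolar_po2(0.6, paco2, A)

    def test_unsustainable_vo2_is_infeasible(self):
        with pytest.raises(InfeasibleStateError):
            steady_state(run_for(shunt=0.95, fio2=0.6), A)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            steady_state(run_for(shunt=-0.1), A)
        with pytest.raises(InvalidInputError):
            steady_state(run_for(fio2=0.1), A)


class TestMixedVenous:
    def test_fick_subtraction(self):
        assert simulator.mixed_venous_update(20.0, A) == pytest.approx(
            20.0 - 100.0 * 0.25 / 6.5, abs=1e-12
        )

    def test_zero_content_boundary(self):
        with pytest.raises(InfeasibleStateError):
            simulator.mixed_venous_update(A.vo2_q_ml_dl, A)

    def test_doubling_q_halves_av_difference(self):
        d1 = 20.0 - simulator.mixed_venous_update(20.0, A)
        d2 = 20.0 - simulator.mixed_venous_update(20.0, A.replace(q_total=13.0))
        assert d1 == pytest.approx(2 * d2, rel=1e-12)


class TestShuntRecovery:
    @pytest.mark.parametrize("shunt", [0.05, 0.2, 0.5])
    @pytest.mark.parametrize("fio2", [0.4, 0.6, 0.8])
    def test_es_recovers_pure_shunt(self, shunt, fio2):
        run = run_for(shunt=shunt, fio2=fio2)
        steady_state(run, A)
        es = indices.effective_shunt(as_record(run), A)
        assert es == pytest.approx(shunt, abs=1e-3)

    def test_es_invariant_under_fio2_in_model_world(self):
        values = []
        for fio2 in (0.35, 0.7):
            run = run_for(shunt=0.25, fio2=fio2)
            steady_state(run, A)
            values.append(indices.effective_shunt(as_record(run), A))
        assert abs(values[0] - values[1]) < 0.01

    def test_heterogeneity_inflates_es_above_latent_shunt(self):
        run = run_for(shunt=0.1, vq_sigma=1.0, fio2=0.6)
        steady_state(run, A)
        assert indices.effective_shunt(as_record(run), A) > 0.1 + 0.01


class TestConservationAndMonotonicity:
    def test_oxygen_mass_conservation(self):
        # Q * (Ca - Cv) must equal VO2 at the fixed point; reconstruct the
        # venous side from ES-identical contents
        run = run_for(shunt=0.3, vq_sigma=0.7, fio2=0.5, q_total=5.5)
        pao2, paco2, ph = steady_state(run, A)
        ca = odc.oxygen_content(pao2, ph, paco2, run.hb, A)
        cv = ca - 100.0 * run.vo2 / run.q_total
        # the solver's internal fixed point: re-evaluating one secant step
        # must leave the venous update stationary
        a_mod = A.replace(q_total=run.q_total, vo2=run.vo2)
        assert simulator.mixed_venous_update(ca, a_mod) == pytest.approx(
            cv, abs=1e-9
        )
        assert run.q_total * (ca - cv) / 100.0 == pytest.approx(
            run.vo2, abs=1e-6
        )

    def test_three_axis_monotonicity(self):
        base = dict(vq_sigma=0.5, fio2=0.5, shunt=0.15)
        for axis, values, increasing in [
            ("shunt", [0.0, 0.15, 0.3, 0.45], False),
            ("vq_sigma", [0.0, 0.7, 1.4, 2.0], False),
            ("fio2", [0.3, 0.5, 0.7, 0.9], True),
        ]:
            outs = []
            for v in values:
                kw = dict(base)
                kw[axis] = v
                run = run_for(**kw)
                outs.append(steady_state(run, A)[0])
            diffs = np.diff(outs)
            assert np.all(diffs > 0) if increasing else np.all(diffs < 0), axis

    def test_output_below_inspired_tension(self, coarse_db):
        assert (coarse_db["out_pao2"] < coarse_db["fio2"] * A.pio2).all()


class TestBatch:
    def test_batch_matches_scalar(self):
        rows = pd.DataFrame(
            {
                "shunt": [0.0, 0.2, 0.4],
                "vq_sigma": [0.0, 0.8, 1.5],
                "q_total": [6.5, 5.0, 8.0],
                "hb": [110.0, 90.0, 140.0],
                "fio2": [0.3, 0.5, 0.8],
                "alveolar_ventilation": [4.6, 4.6, 5.2],
            }
        )
        batch = simulator.steady_state_batch(rows, A)
        for i, row in rows.iterrows():
            run = ModelRun(vo2=A.vo2, **row)
            pao2, paco2, ph = steady_state(run, A)
            assert batch.loc[i, "out_pao2"] == pytest.approx(pao2, abs=1e-6)
            assert batch.loc[i, "out_paco2"] == pytest.approx(paco2, abs=1e-12)

    def test_infeasible_rows_flagged_not_fatal(self):
        rows = pd.DataFrame(
            {
                "shunt": [0.1, 0.9],
                "vq_sigma": [0.0, 0.0],
                "q_total": [6.5, 3.0],
                "hb": [110.0, 80.0],
                "fio2": [0.4, 0.21],
                "alveolar_ventilation": [4.6, 4.6],
            }
        )
        out = simulator.steady_state_batch(rows, A, raise_on_failure=False)
        assert out["feasible"].tolist() == [True, False]
        assert np.isnan(out.loc[1, "out_pao2"])
        with pytest.raises(InfeasibleStateError):
            simulator.steady_state_batch(rows, A)


class TestDatabaseGrid:
    def test_coarse_database_shape(self, coarse_db):
        expected_cols = {
            "shunt", "vq_sigma", "q_total", "hb", "fio2", "vo2",
            "alveolar_ventilation", "out_pao2", "out_paco2", "out_ph",
        }
        assert expected_cols <= set(coarse_db.columns)
        assert 0 < len(coarse_db) <= simulator.COARSE_GRID.n_runs()

    def test_grid_yaml_config(self, tmp_path):
        p = tmp_path / "grid.yaml"
        p.write_text("shunt: [0.0, 0.2]\nvq_sigma: [0.0]\nq_total: [6.5]\n"
                     "hb: [110.0]\nfio2: [0.4]\npaco2: [5.3]\n")
        grid = simulator.DatabaseGrid.from_yaml(p)
        assert grid.n_runs() == 2
        db = simulator.build_database(grid, A)
        assert len(db) == 2
        with pytest.raises(InvalidInputError):
            p.write_text("bogus_axis: [1]\n")
            simulator.DatabaseGrid.from_yaml(p)
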