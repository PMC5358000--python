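import numpy as np
import pytest

import osmosim as om
from osmosim.errors import ScheduleError


class TestProtocolConstruction:
    def test_unknown_id_lists_valid_ids(self):
        with pytest.raises(ScheduleError, match="A, B, B1, C, D, E, F"):
            om.build_protocol("X")

    def test_water_load_protocol_dose(self):
        a = om.build_protocol("A")
        ev = [e for e in a.events if e.kind == "oral_load"][0]
        assert ev.volume == pytest.approx(20.0 * 74.0)
        assert ev.duration == 20.0
        assert ev.na_conc == 0.0

    def test_dehydration_rehydration_doses(self):
        b = om.build_protocol("B")
        drink = [e for e in b.events if e.kind == "oral_load"][0]
        assert (drink.t_start, drink.duration) == (2160.0, 3.5)
        assert drink.volume == pytest.approx(15.0 * 74.0)
        b1 = om.build_protocol("B1")
        small = [e for e in b1.events if e.kind == "oral_load"][0]
        assert small.volume == pytest.approx(74.0)
        assert small.duration == 3.0

    def test_salt_pill_during_twelfth_hour(self):
        c = om.build_protocol("C")
        pill = [e for e in c.events if "pill" in e.label][0]
        assert pill.t_start == 720.0
        assert pill.volume == 1.0
        assert pill.volume / 1000.0 * pill.na_conc == pytest.approx(80.0)

    def test_hypertonic_drink_concentration(self):
        d = om.build_protocol("D")
        drink = [e for e in d.events if e.t_start == 1440.0][0]
        assert drink.na_conc == 180.0
        assert drink.volume == pytest.approx(10.0 * 74.0)
        assert drink.duration == 2.0

    def test_saline_infusion_rate_and_tonicity(self):
        e = om.build_protocol("E")
        inf = [ev for ev in e.events if ev.kind == "iv_infusion"][0]
        assert inf.volume / inf.duration == pytest.approx(0.06 * 74.0)
        assert inf.duration == 120.0
        assert inf.na_conc == pytest.approx(50.0 / 58.44 * 1000.0)
        assert any(ev.kind == "ad_lib_open" for ev in e.events)
        assert not any(ev.kind == "ad_lib_open" for ev in om.build_protocol("F").events)

    def test_overlapping_loads_rejected(self):
        events = [om.Event(0.0, "oral_load", volume=10.0, duration=10.0),
                  om.Event(5.0, "oral_load", volume=10.0, duration=10.0)]
        with pytest.raises(ScheduleError, match="overlap"):
            om.Protocol("A", om.default_subject(), events, t_end=60.0)

    def test_json_round_trip(self):
        p = om.build_protocol("C")
        q = om.Protocol.from_json(p.to_json())
        assert q.to_dict() == p.to_dict()

    def test_yaml_round_trip(self):
        p = om.build_protocol("E")
        q = om.Protocol.from_yaml(p.to_yaml())
        assert q.to_dict() == p.to_dict()


class TestBaseline:
    def test_converges_immediately_from_calibrated_state(self, baseline):
        assert baseline.t_elapsed == 0.0
        assert baseline.residual < 1e-6

    def test_osmotic_equilibrium(self, baseline):
        assert abs(baseline.observables.icf_osm - baseline.observables.serum_osm) < 0.1

    def test_idempotent_restart(self, baseline, params):
        again = om.find_baseline(om.Subject(), params=params,
                                 init=om.InitialState(fluid=baseline.fluid,
                                                      hormones=baseline.hormones))
        assert again.t_elapsed == 0.0
        assert again.renal.urine_flow == pytest.approx(baseline.renal.urine_flow)


class TestIntegration:
    def test_zero_duration_gives_single_baseline_row(self):
        ts = om.integrate(om.Protocol("A", om.default_subject(), [], t_end=0.0), dt=0.05)
        assert len(ts.times) == 1
        assert ts.column("serum_osm")[0] == pytest.approx(288.0)
        assert ts.column("urine_flow")[0] == pytest.approx(0.58, rel=1e-6)

    def test_sample_times_present_in_output(self, run_a):
        proto = om.build_protocol("A")
        for t in proto.sample_times:
            assert np.any(np.isclose(run_a.times, t))

    def test_step_refinement_convergence(self, run_a, run_a_coarse):
        """Halving dt changes every sampled observable by far less than 0.1%."""
        for col in ("serum_osm", "serum_Na", "hct", "prot_conc", "avp", "anp",
                    "urine_flow", "urine_osm", "CWI", "GFR"):
            fine = np.array([run_a.value_at(col, t) for t in run_a_coarse.times])
            coarse = run_a_coarse.column(col)
            rel = np.abs(fine - coarse) / np.maximum(np.abs(fine), 1e-3)
            assert rel.max() < 1e-3, col

    def test_identical_inputs_identical_bytes(self):
        a = om.integrate(om.build_protocol("A"), dt=0.1).to_csv_bytes()
        b = om.integrate(om.build_protocol("A"), dt=0.1).to_csv_bytes()
        assert a == b

    def test_csv_round_trip(self, run_a_coarse, tmp_path):
        path = tmp_path / "a.csv"
        run_a_coarse.to_csv(path)
        back = om.TimeSeries.from_csv(path)
        assert np.allclose(back.times, run_a_coarse.times)
        assert np.allclose(back.column("serum_osm"), run_a_coarse.column("serum_osm"))


class TestProtocolContract:
    """Qualitative physiological contract of the packaged protocols."""

    def test_dehydration_raises_osmolality_and_avp_monotonically(self, long_runs):
        for pid, t_dep in (("B", 2160.0), ("C", 1440.0), ("D", 1440.0)):
            r = long_runs[pid]
            m = r.times <= t_dep
            assert np.all(np.diff(r.column("serum_osm")[m]) > -1e-9), pid
            assert np.all(np.diff(r.column("avp")[m]) > -1e-6), pid

    def test_rehydration_suppresses_avp_quickly(self, long_runs):
        """Oral water after dehydration halves AVP within the hour."""
        for pid, t_drink in (("B", 2160.0), ("C", 1440.0)):
            r = long_runs[pid]
            peak = r.column("avp")[r.times <= t_drink].max()
            post = (r.times >= t_drink) & (r.times <= t_drink + 60.0)
            assert r.column("avp")[post].min() < 0.5 * peak, pid

    def test_hypertonic_drink_suppresses_avp_less_than_water(self, long_runs):
        c, d = long_runs["C"], long_runs["D"]
        for dt in (5.0, 10.0, 15.0, 30.0, 60.0):
            assert c.value_at("avp", 1440.0 + dt) < d.value_at("avp", 1440.0 + dt)

    def test_drinking_lowers_final_serum_sodium(self, long_runs):
        assert long_runs["E"].column("serum_Na")[-1] < long_runs["F"].column("serum_Na")[-1]

    def test_serum_sodium_non_decreasing_during_hypertonic_infusion(self, long_runs):
        f = long_runs["F"]
        w = (f.times >= 600.0) & (f.times <= 720.0)
        assert np.all(np.diff(f.column("serum_Na")[w]) >= -1e-9)

    def test_renin_stays_near_baseline_in_all_protocols(self, long_runs, run_a):
        # "Near" means within half of a typical inter-subject spread of
        # plasma renin activity (no significant change).
        for pid, r in {**long_runs, "A": run_a}.items():
            pra = r.column("pra")
            assert 0.5 < pra.min() and pra.max() < 1.5, pid

    def test_isotonic_infusion_fills_plasma_before_interstitium(self):
        """Starling filtration lags: infused saline transiently expands plasma
        more than interstitium, then redistributes."""
        proto = om.Protocol("A", om.default_subject(),
                            [om.Event(0.0, "iv_infusion", volume=1000.0,
                                      na_conc=150.0, duration=10.0)],
                            t_end=90.0, sample_times=[])
        ts = om.integrate(proto, dt=0.05)
        i5 = int(np.searchsorted(ts.times, 5.0))
        dvp = ts.column("V_pl")[i5] - ts.column("V_pl")[0]
        dvi = ts.column("V_is")[i5] - ts.column("V_is")[0]
        assert dvp > dvi
        dvp_late = ts.column("V_pl")[-1] - ts.column("V_pl")[0]
        dvi_late = ts.column("V_is")[-1] - ts.column("V_is")[0]
        assert dvi_late > dvp_late
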