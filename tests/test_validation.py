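import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import osmosim as om
from osmosim import validation
from osmosim.errors import ValidationInputError


class TestSemToSd:
    @pytest.mark.parametrize("sem,n,expected", [(2.0, 9, 6.0), (0.5, 16, 2.0), (3.0, 1, 3.0)])
    def test_conversion(self, sem, n, expected):
        assert om.sem_to_sd(sem, n) == pytest.approx(expected)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationInputError):
            om.sem_to_sd(1.0, 0)


class TestZScore:
    def test_exact_match_scores_zero(self):
        assert om.z_score(285.0, 285.0, 5.0) == 0.0

    def test_one_sd_away(self):
        assert om.z_score(290.0, 285.0, 5.0) == pytest.approx(1.0)

    @given(m=st.floats(-100.0, 100.0), mu=st.floats(-100.0, 100.0), s=st.floats(0.1, 50.0))
    def test_symmetric_about_the_mean(self, m, mu, s):
        assert om.z_score(m, mu, s) == pytest.approx(om.z_score(2 * mu - m, mu, s), rel=1e-9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationInputError):
            om.z_score(1.0, 1.0, 0.0)

    @pytest.mark.parametrize("z,bin_", [(0.999, validation.BIN_LOW),
                                        (1.0, validation.BIN_MID),
                                        (2.0, validation.BIN_MID),
                                        (2.001, validation.BIN_HIGH)])
    def test_bin_boundaries_fall_in_middle_bin(self, z, bin_):
        assert validation.z_bin(z) == bin_


class TestRmse:
    def test_identical_series_zero(self):
        assert om.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        # differences (3, 4): sqrt(25/2)
        assert om.rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(3.5355339059, rel=1e-9)

    @given(c=st.floats(-10.0, 10.0))
    def test_constant_offset(self, c):
        x = np.array([1.0, 5.0, 9.0])
        assert om.rmse(x + c, x) == pytest.approx(abs(c), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationInputError):
            om.rmse([1.0], [1.0, 2.0])


def _toy_run(values, times=None):
    times = np.asarray(times if times is not None else np.arange(len(values)), float)
    return om.TimeSeries(times=times, data={"serum_osm": np.asarray(values, float)})


class TestBuildReport:
    def test_empty_reference_set(self):
        refs = pd.DataFrame(columns=list(validation.REF_COLUMNS))
        rep = om.build_report({"A": _toy_run([288.0, 289.0])}, refs)
        assert rep.n_comparisons == 0
        assert sum(rep.tallies.values()) == 0

    def test_single_matching_point(self):
        refs = pd.DataFrame([{"protocol": "A", "variable": "serum_osm", "units": "",
                              "time_min": 1.0, "mean": 289.0, "sd": 2.0,
                              "sem": np.nan, "n": np.nan}])
        rep = om.build_report({"A": _toy_run([288.0, 289.0, 290.0])}, refs)
        assert rep.tallies == {validation.BIN_LOW: 1, validation.BIN_MID: 0,
                               validation.BIN_HIGH: 0}
        assert rep.points["z"].iloc[0] == 0.0

    def test_unmatched_reference_point_named(self):
        refs = pd.DataFrame([{"protocol": "Z", "variable": "serum_osm", "units": "",
                              "time_min": 0.0, "mean": 288.0, "sd": 1.0,
                              "sem": np.nan, "n": np.nan}])
        with pytest.raises(ValidationInputError, match="'Z'"):
            om.build_report({"A": _toy_run([288.0])}, refs)

    def test_tallies_sum_to_comparisons(self):
        rng = np.random.default_rng(7)
        run = _toy_run(288.0 + rng.normal(0, 3, 20))
        rows = [{"protocol": "A", "variable": "serum_osm", "units": "",
                 "time_min": float(t), "mean": 288.0, "sd": 1.5,
                 "sem": np.nan, "n": np.nan} for t in range(20)]
        rep = om.build_report({"A": run}, pd.DataFrame(rows))
        assert sum(rep.tallies.values()) == rep.n_comparisons == 20

    def test_constructed_offset_fixture_fills_middle_bin(self, run_a_coarse):
        """With references placed 1.5 SD below the model everywhere, every
        comparison must land in the 1-2 SD bin."""
        refs = om.make_synthetic_refs({"A": run_a_coarse}, offset_sd=1.5, seed=3)
        resolved = validation.read_reference_csv(io.StringIO(refs.to_csv(index=False)))
        rep = om.build_report({"A": run_a_coarse}, resolved)
        assert rep.n_comparisons > 0
        assert rep.tallies[validation.BIN_MID] == rep.n_comparisons
        assert np.allclose(rep.points["z"], 1.5, atol=1e-9)

    def test_bin_tallies_invariant_under_time_relabeling(self):
        run = _toy_run([280.0, 290.0, 300.0], times=[0.0, 10.0, 20.0])
        rows = [{"protocol": "A", "variable": "serum_osm", "units": "",
                 "time_min": t, "mean": 285.0, "sd": 4.0, "sem": np.nan, "n": np.nan}
                for t in (0.0, 10.0, 20.0)]
        rep1 = om.build_report({"A": run}, pd.DataFrame(rows))
        # Monotone relabeling of the time axis (t -> t**2 + 1).
        run2 = _toy_run([280.0, 290.0, 300.0], times=[1.0, 101.0, 401.0])
        rows2 = [dict(r, time_min=r["time_min"] ** 2 + 1.0) for r in rows]
        rep2 = om.build_report({"A": run2}, pd.DataFrame(rows2))
        assert rep1.tallies == rep2.tallies

    def test_report_serializes(self, run_a_coarse):
        refs = om.make_synthetic_refs({"A": run_a_coarse}, seed=1)
        resolved = validation.read_reference_csv(io.StringIO(refs.to_csv(index=False)))
        rep = om.build_report({"A": run_a_coarse}, resolved)
        assert "tallies" in rep.to_json()
        assert "TOTAL" in rep.to_text_matrix()


class TestReferenceCsv:
    def test_round_trip_lossless(self, tmp_path, run_a_coarse):
        refs = om.make_synthetic_refs({"A": run_a_coarse}, seed=5)
        path = tmp_path / "refs.csv"
        om.write_reference_csv(refs, path)
        back = validation.read_reference_csv(path)
        for col in ("protocol", "variable", "time_min", "mean"):
            assert list(back[col]) == pytest.approx(list(refs[col])) \
                if col in ("time_min", "mean") else (list(back[col]) == list(refs[col]))

    def test_sem_rows_resolved_via_sqrt_n(self, tmp_path):
        df = pd.DataFrame([{"protocol": "A", "variable": "serum_osm", "units": "",
                            "time_min": 0.0, "mean": 288.0, "sd": np.nan,
                            "sem": 2.0, "n": 9}])
        path = tmp_path / "refs.csv"
        df.to_csv(path, index=False)
        assert validation.read_reference_csv(path)["sd_resolved"].iloc[0] == pytest.approx(6.0)

    def test_row_without_dispersion_rejected(self):
        df = pd.DataFrame([{"protocol": "A", "variable": "serum_osm", "units": "",
                            "time_min": 0.0, "mean": 288.0, "sd": np.nan,
                            "sem": np.nan, "n": np.nan}])
        with pytest.raises(ValidationInputError):
            validation.read_reference_csv(io.StringIO(df.to_csv(index=False)))
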