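import math

import numpy as np
import pandas as pd
import pytest

import stroketriage as st
from conftest import random_point_in_disc
from stroketriage.destination_sets import RegionLabel
from stroketriage.errors import ValidationError
from stroketriage.spatial_stats import (
    field_frame,
    raster_grid,
    read_raster,
    summarize_field,
    write_raster,
)


class TestRasterGrid:
    def test_disc_radius_30_step_30_has_five_points(self):
        xs, ys = raster_grid(st.Disc(30.0), 30.0)
        pts = sorted(zip(xs, ys))
        assert pts == [(-30.0, 0.0), (0.0, -30.0), (0.0, 0.0), (0.0, 30.0), (30.0, 0.0)]

    def test_lattice_area_converges_to_disc_area(self):
        r = 30.0
        xs, _ = raster_grid(st.Disc(r), r / 100)
        assert len(xs) * (r / 100) ** 2 == pytest.approx(math.pi * r * r, rel=0.02)

    def test_deterministic_ordering(self):
        a = raster_grid(st.Disc(12.0), 0.7)
        b = raster_grid(st.Disc(12.0), 0.7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("step", [0.0, -1.0, 60.0, 100.0])
    def test_invalid_step_rejected(self, step):
        with pytest.raises(ValidationError):
            raster_grid(st.Disc(30.0), step)


class TestEvaluateEnvironment:
    def test_csc_only_environment(self):
        centers = [
            st.StrokeCenter("A", "CSC", st.Location(-5.0, 0.0)),
            st.StrokeCenter("B", "CSC", st.Location(5.0, 0.0)),
        ]
        env = st.Environment(centers, st.Disc(20.0), st.EuclideanTravelTime())
        field, s = st.evaluate_environment(env, 1.0)
        assert s.triage_fraction == 0.0
        assert s.higher_order_fraction == 0.0
        assert math.isnan(s.bhr_psc_median) and math.isnan(s.bhr_csc_median)
        assert math.isnan(s.frac_bhr_psc_ge_2)
        assert np.isnan(field.bhr_psc_max).all()

    def test_fraction_invariants(self, env25):
        _, s = st.evaluate_environment(env25, 0.6)
        assert 0.0 <= s.higher_order_fraction <= s.triage_fraction <= 1.0

    def test_collinear_configuration_matches_fine_brute_force(self):
        # hand-built 1 CSC + 2 PSC collinear geography
        centers = [
            st.StrokeCenter("C", "CSC", st.Location(6.0, 0.0)),
            st.StrokeCenter("P1", "PSC", st.Location(-6.0, 0.0)),
            st.StrokeCenter("P2", "PSC", st.Location(2.0, 0.0)),
        ]
        env = st.Environment(centers, st.Disc(10.0), st.EuclideanTravelTime())
        _, s = st.evaluate_environment(env, 0.5)
        # independent brute force via the scalar classifier at step/10
        xs, ys = raster_grid(env.region, 0.05)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(xs), size=4000, replace=False)
        labels = np.array(
            [
                int(st.classify_point(st.Location(float(xs[i]), float(ys[i])), env).label)
                for i in idx
            ]
        )
        assert s.triage_fraction == pytest.approx(float((labels != 1).mean()), abs=0.02)
        assert s.higher_order_fraction == pytest.approx(
            float((labels == 3).mean()), abs=0.02
        )

    def test_field_matches_scalar_path_per_point(self, env25):
        field, _ = st.evaluate_environment(env25, 1.5)
        rng = np.random.default_rng(4)
        for i in rng.choice(len(field.x), size=60, replace=False):
            p = st.Location(float(field.x[i]), float(field.y[i]))
            cls = st.classify_point(p, env25)
            assert int(cls.label) == field.label[i]
            assert cls.option_count == field.option_count[i]
            if cls.label is RegionLabel.HIGHER_ORDER:
                res = st.point_bhr(p, st.destination_set(p, env25), env25.dido)
                assert field.bhr_psc_max[i] == pytest.approx(res.bhr_psc_max)
                if res.bhr_csc_max is None:
                    assert np.isnan(field.bhr_csc_max[i])
                else:
                    assert field.bhr_csc_max[i] == pytest.approx(res.bhr_csc_max)
            else:
                assert np.isnan(field.bhr_psc_max[i])

    def test_halving_step_changes_fractions_below_one_percent(self, env25):
        _, a = st.evaluate_environment(env25, 0.3)
        _, b = st.evaluate_environment(env25, 0.15)
        assert abs(a.triage_fraction - b.triage_fraction) < 0.01
        assert abs(a.higher_order_fraction - b.higher_order_fraction) < 0.01

    def test_scale_invariance_of_fractions_and_bhr_psc(self, env25):
        lam = 4.0
        scaled = st.Environment(
            [
                st.StrokeCenter(
                    c.id, c.level, st.Location(lam * c.location.x, lam * c.location.y)
                )
                for c in env25.centers
            ],
            st.Disc(30.0 * lam),
            st.EuclideanTravelTime(),
            dido=env25.dido,
        )
        _, a = st.evaluate_environment(env25, 0.6)
        _, b = st.evaluate_environment(scaled, 0.6 * lam)
        assert b.triage_fraction == pytest.approx(a.triage_fraction)
        assert b.higher_order_fraction == pytest.approx(a.higher_order_fraction)
        assert b.bhr_psc_median == pytest.approx(a.bhr_psc_median)
        assert b.frac_bhr_psc_ge_2 == pytest.approx(a.frac_bhr_psc_ge_2)
        # BHR_CSC is not scale-free at fixed DIDO: enlarging the region
        # shrinks the relative weight of the transfer delay
        assert b.bhr_csc_median > a.bhr_csc_median


class TestStudy:
    def test_single_replicate_median_equals_environment_summary(self):
        study = st.run_simulation_study([2], [5], 30.0, reps=1, step=1.0, seed=5)
        env = st.generate_random_environment(2, 5, 30.0, rng=st.replicate_rng(5, 2, 5, 0))
        _, s = st.evaluate_environment(env, 1.0)
        (combo,) = study.combos
        assert combo.stats["triage_fraction"][0] == pytest.approx(s.triage_fraction)
        assert combo.stats["bhr_psc_median"][0] == pytest.approx(s.bhr_psc_median)

    def test_same_seed_identical_tables(self):
        a = st.run_simulation_study([1, 2], [2, 3], 30.0, reps=2, step=1.5, seed=9)
        b = st.run_simulation_study([1, 2], [2, 3], 30.0, reps=2, step=1.5, seed=9)
        pd.testing.assert_frame_equal(a.per_environment, b.per_environment)
        pd.testing.assert_frame_equal(a.summary_frame(), b.summary_frame())
        assert len(a.combos) == 4

    def test_combo_median_within_replicate_range(self):
        study = st.run_simulation_study([2], [5], 30.0, reps=8, step=1.0, seed=2)
        (combo,) = study.combos
        vals = study.per_environment["triage_fraction"]
        med = combo.stats["triage_fraction"][0]
        assert vals.min() <= med <= vals.max()

    def test_doubling_reps_stabilizes_median(self):
        a = st.run_simulation_study([2], [5], 30.0, reps=20, step=0.6, seed=3)
        b = st.run_simulation_study([2], [5], 30.0, reps=40, step=0.6, seed=3)
        ma = a.combos[0].stats["triage_fraction"][0]
        mb = b.combos[0].stats["triage_fraction"][0]
        assert abs(ma - mb) < 0.03

    def test_range_report_extrema_match_manual_scan(self):
        study = st.run_simulation_study([1, 2], [2, 4], 30.0, reps=3, step=1.0, seed=4)
        rr = st.range_report(study)
        meds = [c.stats["triage_fraction"][0] for c in study.combos]
        assert rr.triage_fraction_min == min(meds)
        assert rr.triage_fraction_max == max(meds)
        single = st.run_simulation_study([2], [5], 30.0, reps=3, step=1.0, seed=4)
        rr1 = st.range_report(single)
        assert rr1.triage_fraction_min == rr1.triage_fraction_max


class TestOutputs:
    def test_raster_roundtrip(self, env25, tmp_path):
        field, _ = st.evaluate_environment(env25, 1.5)
        p = tmp_path / "raster.csv"
        write_raster(field, p)
        back = read_raster(p, step=1.5)
        assert np.array_equal(back.label, field.label)
        assert np.array_equal(back.option_count, field.option_count)
        assert np.allclose(back.x, field.x) and np.allclose(back.y, field.y)
        assert np.allclose(back.bhr_psc_max, field.bhr_psc_max, equal_nan=True)
        assert np.allclose(back.bhr_csc_max, field.bhr_csc_max, equal_nan=True)
        # summaries recomputed from the round-tripped field agree
        assert summarize_field(back).triage_fraction == pytest.approx(
            summarize_field(field).triage_fraction
        )

    def test_raster_and_summary_schemas(self, env25, tmp_path):
        field, _ = st.evaluate_environment(env25, 2.0)
        assert list(field_frame(field).columns) == [
            "x", "y", "label", "option_count", "bhr_psc_max", "bhr_csc_max", "dominates",
        ]
        study = st.run_simulation_study([2], [5], 30.0, reps=2, step=2.0, seed=1)
        paths = st.write_outputs(field, study, tmp_path)
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert list(summary.columns) == [
            "n_csc", "n_psc", "radius", "dido", "reps", "stat", "median", "iqr_lo", "iqr_hi",
        ]
        assert all(p.exists() for p in paths)

    def test_figure_generation_smoke(self, env25, tmp_path):
        field, _ = st.evaluate_environment(env25, 1.5)
        study = st.run_simulation_study([2], [5], 30.0, reps=2, step=2.0, seed=1)
        paths = st.write_outputs(field, study, tmp_path, env=env25, figures=True)
        assert (tmp_path / "map.png").exists()
        assert (tmp_path / "study.png").exists()

    def test_geojson_written_in_geo_mode(self, tmp_path):
        c = tmp_path / "centers.csv"
        c.write_text(
            "id,level,lat,lon\nA,CSC,52.5,13.4\nB,PSC,52.6,13.2\nC,PSC,52.4,13.6\n"
        )
        env = st.load_environment(c)
        field, _ = st.evaluate_environment(env, env.region.diameter / 80)
        st.write_outputs(field, None, tmp_path, env=env)
        import json

        doc = json.loads((tmp_path / "raster.geojson").read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == len(field.x)
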