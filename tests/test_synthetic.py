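import json
import warnings

import numpy as np
import pandas as pd
import pytest

from braingap import io as bio
from braingap.synthetic import (
    CohortConfig,
    ConfigurationError,
    _largest_remainder,
    generate_cohort_table,
    generate_exposome_table,
    simulate_bag_outcomes,
    simulate_subject_timeseries,
    write_fixture_set,
)


def cfg(**kw):
    defaults = dict(n_subjects=20, n_regions=8, n_samples=120, seed=7)
    defaults.update(kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CohortConfig(**defaults)


class TestCohortConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(group_mix={"HC": 0.5, "AD": 0.4})
        with pytest.raises(ConfigurationError):
            cfg(region_mix={"LAC": 1.2, "nonLAC": -0.2})

    def test_bad_age_range_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(age_range=(80.0, 30.0))

    def test_too_few_regions_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(n_regions=3)

    def test_small_sample_count_warns(self):
        with pytest.warns(UserWarning, match="n_samples"):
            CohortConfig(n_subjects=5, n_regions=8, n_samples=20, seed=0)


class TestGenerateCohortTable:
    def test_seeded_determinism(self):
        c = cfg(n_subjects=100)
        t1 = generate_cohort_table(c)
        t2 = generate_cohort_table(c)
        assert [vars(r) for r in t1] == [vars(r) for r in t2]

    def test_degenerate_mix_all_hc(self):
        c = cfg(group_mix={"HC": 1.0})
        assert all(r.diagnosis == "HC" for r in generate_cohort_table(c))

    def test_largest_remainder_allocation(self):
        # oracle: direct multinomial largest-remainder count
        assert _largest_remainder({"HC": 0.5, "AD": 0.5}, 1000) == {"HC": 500, "AD": 500}
        assert _largest_remainder({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, 100) in (
            {"a": 34, "b": 33, "c": 33},
            {"a": 33, "b": 34, "c": 33},
            {"a": 33, "b": 33, "c": 34},
        )
        c = cfg(n_subjects=1000, group_mix={"HC": 0.5, "AD": 0.5})
        counts = pd.Series([r.diagnosis for r in generate_cohort_table(c)]).value_counts()
        assert 498 <= counts["AD"] <= 502

    def test_ages_within_range(self):
        c = cfg(n_subjects=200, age_range=(40.0, 60.0))
        ages = [r.age for r in generate_cohort_table(c)]
        assert min(ages) >= 40.0 and max(ages) <= 60.0


class TestSimulateSubjectTimeseries:
    def test_seeded_determinism(self):
        c = cfg()
        rec = generate_cohort_table(c)[0]
        a = simulate_subject_timeseries(rec, c, seed=3).values
        b = simulate_subject_timeseries(rec, c, seed=3).values
        np.testing.assert_array_equal(a, b)

    def test_lambda_anchor_at_age_min(self):
        c = cfg()
        lam = max(
            c.lam0 - c.coupling_slope * (c.age_range[0] - c.age_range[0]),
            c.lam_floor,
        )
        assert lam == c.lam0

    def test_young_subject_has_stronger_within_block_coupling(self):
        from braingap.synthetic import _block_assignment
        c = cfg(n_regions=12, n_samples=600)
        base = generate_cohort_table(c)[0]
        blocks = _block_assignment(c.n_regions, c.n_blocks)
        within = (blocks[:, None] == blocks[None, :]) & ~np.eye(12, dtype=bool)

        def mean_within_corr(age):
            rec = type(base)(**{**vars(base), "age": age, "diagnosis": "HC"})
            ts = simulate_subject_timeseries(rec, c, seed=99)
            return np.corrcoef(ts.values)[within].mean()

        assert mean_within_corr(20.0) > mean_within_corr(80.0)

    def test_effective_age_orders_groups(self):
        c = cfg()
        rec = generate_cohort_table(c)[0]
        effs = {}
        for d in ("HC", "MCI", "AD"):
            r = type(rec)(**{**vars(rec), "diagnosis": d, "region": "nonLAC"})
            effs[d] = r.effective_age(c)
        assert effs["HC"] < effs["MCI"] < effs["AD"]
        lac = type(rec)(**{**vars(rec), "diagnosis": "HC", "region": "LAC"})
        assert lac.effective_age(c) == effs["HC"] + c.lac_extra_offset

    def test_scanner_scale_applied(self):
        c = cfg(scanner_scale=2.0)
        rec = generate_cohort_table(c)[0]
        r0 = type(rec)(**{**vars(rec), "scanner": "scanner0"})
        r1 = type(rec)(**{**vars(rec), "scanner": "scanner1"})
        a = simulate_subject_timeseries(r0, c, seed=5).values
        b = simulate_subject_timeseries(r1, c, seed=5).values
        np.testing.assert_allclose(b, 2.0 * a)

    def test_planted_synergy_triplet(self):
        from braingap.hoi import o_information_pair
        c = cfg(n_regions=8, n_samples=4000, plant_synergy=True,
                lam0=0.05, cross_coupling0=0.02, coupling_slope=0.0)
        rec = generate_cohort_table(c)[0]
        ts = simulate_subject_timeseries(rec, c, seed=1)
        # regions 0,1 drive region -1: their pair-vs-rest Omega goes negative
        assert o_information_pair(ts, 0, 1) < -0.02


class TestExposome:
    def test_determinism_and_columns(self):
        t1 = generate_exposome_table(["Chile", "USA"], seed=1)
        t2 = generate_exposome_table(["Chile", "USA"], seed=1)
        pd.testing.assert_frame_equal(t1, t2)
        assert {"GINI", "PM25", "communicable_burden",
                "noncommunicable_burden", "GII"} <= set(t1.columns)

    def test_needs_two_countries(self):
        with pytest.raises(ValueError):
            generate_exposome_table(["Chile"], seed=0)

    def test_null_effects_leave_bag_independent_of_gini(self):
        c = cfg(n_subjects=500)
        recs = generate_cohort_table(c)
        expo = generate_exposome_table(sorted({r.country for r in recs}), seed=2)
        out = simulate_bag_outcomes(recs, expo, seed=3)
        merged = out.merge(expo, on="country")
        r = np.corrcoef(merged["GINI"], merged["bag"])[0, 1]
        assert abs(r) < 0.1

    def test_planted_gini_slope_recovered_by_ols(self):
        c = cfg(n_subjects=500)
        recs = generate_cohort_table(c)
        expo = generate_exposome_table(sorted({r.country for r in recs}), seed=2)
        out = simulate_bag_outcomes(recs, expo, gini_slope=0.3, seed=3)
        merged = out.merge(expo, on="country")
        g = merged["GINI"] - merged["GINI"].mean()
        slope = float((g * merged["bag"]).sum() / (g**2).sum())
        assert slope == pytest.approx(0.3, abs=0.1)


class TestWriteFixtureSet:
    def test_round_trip_and_manifest(self, tmp_path):
        c = cfg(n_subjects=4)
        recs = generate_cohort_table(c)
        manifest = write_fixture_set(recs, c, tmp_path)
        assert len(manifest["files"]) == c.n_subjects + 2

        ts = simulate_subject_timeseries(recs[0], c, seed=c.seed + 1000)
        read_back = bio.read_timeseries_matrix(
            tmp_path / f"{recs[0].subject_id}_timeseries.tsv"
        )
        np.testing.assert_array_equal(read_back.values, ts.values)
        assert read_back.region_labels == ts.region_labels

        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["n_subjects"] == 4

    def test_checksum_tracks_content(self, tmp_path):
        c = cfg(n_subjects=2)
        recs = generate_cohort_table(c)
        m1 = write_fixture_set(recs, c, tmp_path / "a")
        m2 = write_fixture_set(recs, c, tmp_path / "b")
        assert [f["sha256"] for f in m1["files"]] == [f["sha256"] for f in m2["files"]]
        c2 = cfg(n_subjects=2, seed=8)
        m3 = write_fixture_set(generate_cohort_table(c2), c2, tmp_path / "c")
        assert m1["files"][0]["sha256"] != m3["files"][0]["sha256"]
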