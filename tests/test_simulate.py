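import numpy as np
import pandas as pd
import pytest

from actiprofile import (
    BodyCompositionModel,
    OutcomeCoefficients,
    SubjectParams,
    default_outcome_coefficients,
    detect_nonwear,
    diurnal_weights,
    expected_band_fractions,
    fit_intensity_gradient,
    generate_cohort,
    generate_subject_series,
    intensity_distribution,
    mvpa_minutes,
    true_mvpa_minutes,
    average_acceleration,
)
from actiprofile import DEFAULT_BAND_EDGES
from actiprofile.simulate import _tail_band_probs


def make_params(**over):
    base = dict(
        subject_id="S1", sex="female", age=10.0, stature=140.0, pubertal=0,
        base_level=0.19, tail_exponent=-1.69, wear_days=7,
    )
    base.update(over)
    return SubjectParams(**base)


class TestSubjectSeries:
    def test_same_seed_is_bit_identical(self):
        p = make_params()
        a = generate_subject_series(p, 11)
        b = generate_subject_series(p, 11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_differs(self):
        p = make_params()
        a = generate_subject_series(p, 11)
        b = generate_subject_series(p, 12)
        assert not a.data["counts"].equals(b.data["counts"])

    def test_record_spans_wear_days_with_full_weekend(self):
        for days in (4, 7, 9):
            s = generate_subject_series(make_params(wear_days=days), 0)
            assert len(s) == days * 1440
            weekdays = set(s.timestamps.dt.dayofweek)
            assert {5, 6} <= weekdays  # full Saturday and Sunday present
            day_counts = s.timestamps.dt.normalize().value_counts()
            assert (day_counts == 1440).all()  # every calendar day complete

    def test_no_gaps_means_no_nonwear_detected(self):
        s = generate_subject_series(make_params(wear_days=4), 5)
        assert detect_nonwear(s).nonwear_intervals == []

    def test_inserted_block_recovered_exactly(self):
        p = make_params(nonwear_blocks=[(2, 10.0, 120)])
        s = generate_subject_series(p, 3)
        mask = detect_nonwear(s)
        assert len(mask.nonwear_intervals) == 1
        start, end = mask.nonwear_intervals[0]
        assert (end - start).total_seconds() == 120 * 60
        assert (~mask.wear).sum() == 120

    def test_inserted_minutes_equal_recovered_minutes(self):
        blocks = [(1, 8.0, 150), (3, 13.5, 200), (5, 9.25, 95)]
        p = make_params(nonwear_blocks=blocks)
        mask = detect_nonwear(generate_subject_series(p, 9))
        assert (~mask.wear).sum() == sum(b[2] for b in blocks)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_params(nonwear_blocks=[(1, 8.0, 200), (1, 10.0, 120)])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            make_params(nonwear_blocks=[(1, 8.0, 0)])

    def test_met_channel_monotone_in_acceleration(self):
        s = generate_subject_series(make_params(), 4)
        order = np.argsort(s.acceleration)
        mets = s.met_estimate[order]
        assert np.all(np.diff(mets) >= 0)

    def test_heart_rate_physiological_during_wear_only(self):
        p = make_params(nonwear_blocks=[(2, 10.0, 120)])
        s = generate_subject_series(p, 3)
        mask = detect_nonwear(s)
        assert np.all((s.heart_rate[mask.wear] >= 30) & (s.heart_rate[mask.wear] <= 240))
        assert np.all(s.heart_rate[~mask.wear] == 0)


class TestExpectedBandFractions:
    def test_fractions_sum_to_one(self):
        dist = expected_band_fractions(make_params())
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_power_law_yields_exact_gradient(self):
        _, _, mids, q = _tail_band_probs(-1.5, DEFAULT_BAND_EDGES)
        mu_tail = float(np.dot(q, mids))
        p = make_params(base_level=mu_tail, tail_exponent=-1.5, diurnal_amplitude=0.0)
        dist = expected_band_fractions(p)
        assert dist.fractions[0] == pytest.approx(0.0, abs=1e-12)
        fit = fit_intensity_gradient(dist)
        assert fit.gradient == pytest.approx(-1.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_all_sedentary_is_unfittable(self):
        from actiprofile.simulate import SEDENTARY_MEAN

        p = make_params(base_level=SEDENTARY_MEAN)
        dist = expected_band_fractions(p)
        assert dist.fractions[0] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="unfittable"):
            fit_intensity_gradient(dist)

    def test_shallower_exponent_decays_more_slowly(self):
        shallow = expected_band_fractions(make_params(tail_exponent=-1.2))
        steep = expected_band_fractions(make_params(tail_exponent=-1.54))
        # band-over-band ratios in the tail
        r_shallow = shallow.fractions[2:24] / shallow.fractions[1:23]
        r_steep = steep.fractions[2:24] / steep.fractions[1:23]
        assert np.all(r_shallow > r_steep)

    def test_empirical_fractions_converge_to_analytic(self):
        p = make_params(wear_days=60)
        s = generate_subject_series(p, 21)
        mask = detect_nonwear(s)
        w = diurnal_weights(s, mask)
        emp = intensity_distribution(s, mask, w)
        exp = expected_band_fractions(p)
        tv = 0.5 * np.abs(emp.fractions - exp.fractions).sum()
        assert tv < 0.02

    def test_mvpa_matches_binomial_expectation(self):
        p = make_params(wear_days=60)
        s = generate_subject_series(p, 8)
        mask = detect_nonwear(s)
        w = diurnal_weights(s, mask)
        observed = mvpa_minutes(s, mask, w)
        expected = true_mvpa_minutes(p)
        # ~290k epochs: binomial MC error on the daily minutes is small
        assert observed == pytest.approx(expected, rel=0.10)


class TestCohort:
    def test_requested_counts_and_both_sexes(self):
        c = generate_cohort(12, 8, seed=1)
        assert (c.table["sex"] == "female").sum() == 12
        assert (c.table["sex"] == "male").sum() == 8
        assert set(c.table.columns) >= {
            "age", "stature", "pubertal", "wear_time_h",
            "true_volume", "true_intensity", "tblh_bmc_kg", "lean_kg", "fat_kg",
        }

    def test_same_seed_same_cohort(self):
        a = generate_cohort(5, 5, seed=7)
        b = generate_cohort(5, 5, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.series_seeds == b.series_seeds

    def test_empty_stratum_refused_downstream(self):
        c = generate_cohort(0, 10, seed=2)
        with pytest.raises(ValueError, match="empty stratum"):
            BodyCompositionModel(
                c.table, "tblh_bmc_kg", sex="female",
                volume_col="true_volume", intensity_col="true_intensity",
            )

    def test_noise_free_model3_recovers_generating_coefficients(self):
        coeffs = default_outcome_coefficients()
        coeffs[0] = OutcomeCoefficients("tblh_bmc_kg", -0.60, 0.60, -0.15, 0.20,
                                        0.040, 0.0080, 0.05, 0.0004, 0.0)
        c = generate_cohort(60, 0, coeffs=coeffs, seed=3)
        res = BodyCompositionModel(
            c.table, "tblh_bmc_kg", sex="female",
            volume_col="true_volume", intensity_col="true_intensity",
        ).fit()
        m3 = res.model(3)
        assert m3.coef("true_volume") == pytest.approx(0.60, abs=1e-8)
        assert m3.coef("true_intensity") == pytest.approx(-0.15, abs=1e-8)
        assert m3.coef("true_volumextrue_intensity") == pytest.approx(0.20, abs=1e-8)
        assert m3.coef("age") == pytest.approx(0.040, abs=1e-8)
        assert m3.coef("stature") == pytest.approx(0.0080, abs=1e-8)
        assert m3.coef("wear_time_h") == pytest.approx(0.0004, abs=1e-8)

    def test_lazy_series_regeneration_is_stable(self):
        c = generate_cohort(2, 0, seed=4)
        sid = c.table["subject_id"].iloc[0]
        pd.testing.assert_frame_equal(c.series(sid).data, c.series(sid).data)

    def test_cohort_scale_matches_defaults(self):
        """Sex-stratified generator means sit near the intended volume scale."""
        c = generate_cohort(300, 300, seed=6)
        f = c.table[c.table.sex == "female"]["true_volume"].mean()
        m = c.table[c.table.sex == "male"]["true_volume"].mean()
        assert 0.16 < f < 0.23
        assert 0.18 < m < 0.26
        assert m > f

    def test_manifest_round_trip(self, tmp_path):
        import json

        c = generate_cohort(3, 2, seed=9)
        c.write(tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert len(manifest["subjects"]) == 5
        assert set(manifest["series_seeds"]) == set(c.series_seeds)
        back = pd.read_csv(tmp_path / "cohort.csv")
        assert len(back) == 5


class TestMetricRecovery:
    """Each profile metric, recovered from the epoch level through the
    full wear/weighting/fitting chain, tracks the generating parameter
    that controls it.  One parameter is varied per experiment: the
    25-band gradient of any mixture-type intensity process also reflects
    the sedentary share (as it does in real data), so varying volume and
    intensity jointly probes that confounding, not recovery fidelity.
    """

    def _recover(self, base, tail, seed):
        p = make_params(subject_id="R", base_level=float(base),
                        tail_exponent=float(tail))
        s = generate_subject_series(p, seed)
        mask = detect_nonwear(s)
        w = diurnal_weights(s, mask)
        vol = average_acceleration(s, mask, w)
        grad = fit_intensity_gradient(intensity_distribution(s, mask, w)).gradient
        return vol, grad

    def test_recovered_volume_tracks_base_level(self):
        rng = np.random.default_rng(17)
        base = rng.uniform(0.12, 0.32, 200)
        got = [self._recover(b, -1.69, 1000 + i)[0] for i, b in enumerate(base)]
        assert np.corrcoef(base, got)[0, 1] > 0.95

    def test_recovered_gradient_tracks_tail_exponent(self):
        rng = np.random.default_rng(18)
        tail = rng.uniform(-2.2, -1.2, 200)
        got = [self._recover(0.19, t, 2000 + i)[1] for i, t in enumerate(tail)]
        assert np.corrcoef(tail, got)[0, 1] > 0.95
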