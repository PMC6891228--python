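"""LI computation, peak search, classification, reliability, group summary."""

import math

import numpy as np
import pytest

from conftest import make_epochs, raised_cosine
from ftcdli.laterality import (
    SubjectResult,
    compute_li,
    find_poi_peak,
    group_mean_li,
    split_half_reliability,
)
from ftcdli.preprocess import PipelineConfig
from ftcdli.stats import GroupSummary


def _grid(fs=10.0):
    return np.arange(int(38 * fs)) / fs - 12.0


class TestFindPoiPeak:
    def test_unimodal_bump_at_11s(self, config):
        t = _grid()
        wave = raised_cosine(t, peak=11.0, half_width=7.0)
        latency, window = find_poi_peak(wave, t, config)
        assert latency == pytest.approx(11.0)
        assert window == pytest.approx((10.0, 12.0))

    def test_window_clamped_inside_epoch_not_poi(self, config):
        t = _grid()
        wave = raised_cosine(t, peak=17.8, half_width=2.0)
        latency, window = find_poi_peak(wave, t, config)
        assert latency == pytest.approx(17.8)
        # window extends past the POI edge (18 s) but stays inside the epoch
        assert window == pytest.approx((16.8, 18.8))

    def test_absolute_peak_picks_negative_trough(self, config):
        t = _grid()
        wave = raised_cosine(t, 14.0, 2.0, amplitude=1.0) \
            - raised_cosine(t, 9.0, 2.0, amplitude=2.0)
        latency, window = find_poi_peak(wave, t, config)
        assert latency == pytest.approx(9.0)
        assert window == pytest.approx((8.0, 10.0))

    def test_matches_brute_force_search(self, config):
        rng = np.random.default_rng(3)
        t = _grid()
        wave = rng.normal(0, 1, len(t))
        latency, _ = find_poi_peak(wave, t, config)
        # explicit loop over POI grid points
        best_t, best_v = None, -1.0
        for ti, vi in zip(t, wave):
            if 4.0 <= ti <= 18.0 and abs(vi) > best_v:
                best_t, best_v = ti, abs(vi)
        assert latency == best_t


class TestComputeLI:
    def test_identical_channels_give_zero_li_and_low_category(self):
        epochs = make_epochs(np.zeros((10, 380)))
        res = compute_li(epochs)
        assert res.li == 0.0
        assert np.all(res.per_trial_li == 0.0)
        assert res.category == "low"

    def test_channel_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        t = _grid()
        waves = np.array([
            raised_cosine(t, 11.0, 7.0, amplitude=3.0) + rng.normal(0, 0.2, len(t))
            for _ in range(12)
        ])
        res = compute_li(make_epochs(waves))
        res_sw = compute_li(make_epochs(-waves))
        assert res_sw.li == pytest.approx(-res.li, abs=1e-10)
        assert abs(res_sw.t) == pytest.approx(abs(res.t), abs=1e-10)
        assert {res.category, res_sw.category} == {"left", "right"}

    def test_subject_li_equals_mean_of_per_trial_lis(self):
        rng = np.random.default_rng(11)
        t = _grid()
        waves = np.array([
            raised_cosine(t, 10.0, 6.0, amplitude=rng.uniform(1, 4))
            + rng.normal(0, 0.3, len(t))
            for _ in range(15)
        ])
        res = compute_li(make_epochs(waves))
        assert res.li == pytest.approx(np.mean(res.per_trial_li), abs=1e-12)
        assert res.df == res.n_accepted - 1

    def test_matches_brute_force_recomputation_on_toy_set(self):
        """Oracle: explicit loops over grid points on a 5-trial toy EpochSet."""
        t = _grid()
        amps = [1.0, 2.0, 3.0, 2.5, 1.5]
        waves = np.array([raised_cosine(t, 12.0, 5.0, a) for a in amps])
        epochs = make_epochs(waves)
        res = compute_li(epochs)

        mean_wave = epochs.diff.mean(axis=0)
        best_i = None
        best = -1.0
        for i in range(len(t)):
            if 4.0 <= t[i] <= 18.0 and abs(mean_wave[i]) > best:
                best, best_i = abs(mean_wave[i]), i
        lat = t[best_i]
        vals = [mean_wave[i] for i in range(len(t)) if lat - 1 <= t[i] < lat + 1]
        assert res.peak_latency == lat
        assert res.li == pytest.approx(sum(vals) / len(vals), abs=1e-12)

    def test_exclusion_below_minimum_trials(self):
        epochs = make_epochs(np.ones((8, 380)) * 0.5)
        res = compute_li(epochs)
        assert res.excluded
        assert "9" in res.exclusion_reason

    def test_single_trial_has_undefined_t(self):
        t = _grid()
        epochs = make_epochs([raised_cosine(t, 11.0, 7.0, 2.0)])
        res = compute_li(epochs)
        assert math.isnan(res.t)
        assert res.category == "low"
        assert res.excluded

    def test_no_accepted_trials_errors(self):
        epochs = make_epochs(np.zeros((3, 380)))
        epochs.accepted[:] = False
        with pytest.raises(ValueError):
            compute_li(epochs)


class TestSplitHalf:
    def _cohort(self, amps, negate_even=False, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = _grid()
        sets = []
        for a in amps:
            waves = []
            for k in range(10):
                w = raised_cosine(t, 11.0, 7.0, amplitude=a)
                if negate_even and k % 2 == 1:
                    w = -w
                waves.append(w + rng.normal(0, noise, len(t)))
            sets.append(make_epochs(np.array(waves)))
        return sets

    def test_noise_free_cohort_has_unit_reliability(self):
        res = split_half_reliability(self._cohort([1.0, 2.0, 3.0, 4.0]))
        assert res.r == pytest.approx(1.0)
        assert np.allclose(res.li_odd, res.li_even)

    def test_negated_even_half_gives_minus_one(self):
        res = split_half_reliability(
            self._cohort([1.0, 2.0, 3.0, 4.0], negate_even=True)
        )
        assert res.r == pytest.approx(-1.0)

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            split_half_reliability(self._cohort([1.0, 2.0]))

    def test_cohort_reliability_at_calibrated_noise(self):
        """A 19-subject cohort at realistic noise shows high (>0.8) reliability."""
        from ftcdli.pipeline import run_subject
        from ftcdli.simulate import CohortSpec, SimParams, simulate_cohort

        spec = CohortSpec(
            n_subjects=19, li_mean=2.2, li_sd=3.0,
            base_params=SimParams(noise_sd=0.5, n_trials=20), seed=41,
        )
        recs, _ = simulate_cohort(spec)
        epoch_sets = [run_subject(r)[1] for r in recs]
        assert split_half_reliability(epoch_sets).r > 0.8


class TestGroupSummary:
    def _result(self, li, category="left", excluded=False):
        return SubjectResult(
            subject_id="s", li=li, peak_latency=11.0, window=(10, 12),
            per_trial_li=np.array([li]), n_trials_total=20, n_accepted=15,
            t=2.0, df=14, p=0.01, category=category, excluded=excluded,
        )

    def test_simple_mean_and_sd(self):
        g = group_mean_li([self._result(x) for x in (1.0, 2.0, 3.0)])
        assert g.li == GroupSummary(mean=2.0, sd=1.0, n=3)

    def test_single_subject_sd_flagged(self):
        g = group_mean_li([self._result(2.5)])
        assert g.li.mean == 2.5
        assert g.li.sd == 0.0
        assert not g.sd_defined

    def test_category_percentages(self):
        results = (
            [self._result(2.0, "left")] * 15
            + [self._result(-2.0, "right")] * 3
            + [self._result(0.1, "low")] * 1
        )
        g = group_mean_li(results)
        assert g.category_counts == {"left": 15, "right": 3, "low": 1}
        rounded = {c: round(p) for c, p in g.category_percent.items()}
        assert rounded == {"left": 79, "right": 16, "low": 5}

    def test_excluded_subjects_do_not_contribute(self):
        results = [self._result(1.0), self._result(99.0, excluded=True)]
        g = group_mean_li(results)
        assert g.li.n == 1
        assert g.n_excluded == 1
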