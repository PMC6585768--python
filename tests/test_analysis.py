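"""Spike-train statistics: rates, filtering, correlations, recruitment."""

import numpy as np
import pandas as pd
import pytest

from striabot import analysis
from striabot.analysis import (CORRELATION_BINS, calcium_filter,
                               coactive_neurons, binned_rates,
                               instantaneous_population_correlation,
                               mean_corrected_traces, positive_mode,
                               recruitment_distance_distribution,
                               selected_action, shuffle_spikes,
                               spike_matrix, winning_channel)
from striabot.simulate import SpikeData


def make_spikes(times, ids, duration, n_neurons):
    times = np.asarray(times, float)
    ids = np.asarray(ids, np.int64)
    order = np.lexsort((ids, times))
    return SpikeData(times[order], ids[order], duration, n_neurons)


def pearson_oracle(x, y):
    """Direct two-pass covariance definition of Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum()
                 / np.sqrt((xm * xm).sum() * (ym * ym).sum()))


class TestBinnedRates:
    def test_single_spike_single_bin(self, hemisphere_spec):
        spikes = make_spikes([100.0], [0], 200.0, hemisphere_spec.n_neurons)
        with pytest.warns(UserWarning):
            rates = binned_rates(spikes, hemisphere_spec, bin_ms=200.0)
        # one spike among 40 neurons of channel 0 D1 in a 0.2 s bin
        assert rates.loc[0.0, "0:D1"] == pytest.approx(1 / 0.2 / 40)

    def test_homogeneous_poisson_recovers_rate(self, hemisphere_spec):
        rng = np.random.default_rng(0)
        r, dur = 5.0, 20_000.0
        n = hemisphere_spec.n_neurons
        counts = rng.poisson(r * dur / 1000.0, size=n)
        times = np.concatenate([rng.uniform(0, dur, c) for c in counts])
        ids = np.repeat(np.arange(n), counts)
        spikes = make_spikes(times, ids, dur, n)
        rates = binned_rates(spikes, hemisphere_spec, bin_ms=200.0,
                            group_by="hemisphere_type")
        assert rates.mean().mean() == pytest.approx(r, rel=0.02)

    def test_group_sizes_cover_roster(self, hemisphere_spec):
        sizes = hemisphere_spec.neurons.groupby(
            ["channel", "type"], observed=True).size()
        assert sizes.sum() == hemisphere_spec.n_neurons


class TestCalciumFilter:
    def test_peak_value(self):
        counts = np.zeros(1000)
        counts[10] = 1
        f = calcium_filter(counts)
        assert f[10] == pytest.approx(1000.0 / 300.0)  # ~3.333 s^-1

    def test_linearity_over_superposition(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(0.05, 500).astype(float)
        b = rng.poisson(0.02, 500).astype(float)
        assert np.allclose(calcium_filter(a + b),
                           calcium_filter(a) + calcium_filter(b))

    def test_zero_train(self):
        assert calcium_filter(np.zeros(100)).sum() == 0.0


class TestPearsonAgainstOracle:
    def test_matches_direct_covariance_to_1e12(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        y = 0.3 * x + rng.normal(size=5000)
        got = np.corrcoef(np.vstack([x, y]))[0, 1]
        assert got == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_windowed_correlation_matches_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=3000)
        b = rng.normal(size=3000)
        centers, r = instantaneous_population_correlation(
            a, b, window=500.0, step=250.0)
        starts = ((centers - 250.0)).astype(int)
        for st, val in zip(starts, r):
            assert val == pytest.approx(
                pearson_oracle(a[st:st + 500], b[st:st + 500]), abs=1e-12)


class TestPairwiseCorrelations:
    def test_identical_trains_correlate_one(self, hemisphere_spec):
        # two neurons of channel 0 with identical spike times
        ids = hemisphere_spec.ids(channels=[(0, 0)])[:2]
        t = np.arange(100.0, 10_000.0, 250.0)
        spikes = make_spikes(np.tile(t, 2), np.repeat(ids, len(t)),
                             10_000.0, hemisphere_spec.n_neurons)
        mat = spike_matrix(spikes, ids)
        tr = calcium_filter(mat)
        assert np.corrcoef(tr)[0, 1] == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(4)
        tr = calcium_filter(rng.poisson(0.005, size=(2, 200_000)).astype(float))
        assert abs(np.corrcoef(tr)[0, 1]) < 0.05

    def test_histogram_mass_sums_to_one(self, hemisphere_spec):
        from striabot.analysis import CorrelationSummary
        rng = np.random.default_rng(0)
        s = CorrelationSummary(
            {("D1-D1", "within"): rng.uniform(-1, 1, 500)}, 500, 0)
        dens, centers = s.histogram("D1-D1", "within")
        assert dens.sum() == pytest.approx(1.0)
        assert len(dens) == len(centers)

    def test_positive_mode_bins_centered_on_tenths(self):
        centers = (CORRELATION_BINS[:-1] + CORRELATION_BINS[1:]) / 2
        assert 0.6 in np.round(centers, 6)
        r = np.concatenate([np.full(50, -0.3), np.full(30, 0.61),
                            np.full(10, 0.1)])
        assert positive_mode(r) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            positive_mode(np.full(10, -0.5))

    def test_relabeling_invariance_within_channel(self, hemisphere_spec):
        """Histograms depend on channel geometry, not neuron identity."""
        rng = np.random.default_rng(5)
        n = hemisphere_spec.n_neurons
        counts = rng.poisson(2.0 * 20.0, size=n)  # 2 Hz over 20 s
        times = np.concatenate([rng.uniform(0, 20_000.0, c) for c in counts])
        ids = np.repeat(np.arange(n), counts)
        spikes = make_spikes(times, ids, 20_000.0, n)
        s1 = analysis.pairwise_correlation_histograms(
            spikes, hemisphere_spec, n_sample=100, seed=1)
        # permute neuron ids within each channel/type block
        perm = np.arange(n)
        for _, grp in hemisphere_spec.neurons.groupby(
                ["channel", "type"], observed=True):
            idx = grp["id"].to_numpy()
            perm[idx] = rng.permutation(idx)
        spikes2 = make_spikes(times, perm[ids], 20_000.0, n)
        s2 = analysis.pairwise_correlation_histograms(
            spikes2, hemisphere_spec, n_sample=100, seed=1)
        for key in s1.coefficients:
            assert len(s1.coefficients[key]) == len(s2.coefficients[key])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self, hemisphere_spec):
        rng = np.random.default_rng(6)
        n = hemisphere_spec.n_neurons
        counts = rng.poisson(0.04, size=(n, 5000))
        rows, cols = np.nonzero(counts)
        spikes = make_spikes(cols.astype(float) + 0.5, rows, 5000.0, n)
        mats = analysis.correlation_matrix_subsample(spikes, hemisphere_spec)
        m = mats["D2-D2"]
        assert m.shape == (288, 288)  # 8 neurons x 36 channels
        finite = np.isfinite(np.diag(m))
        assert np.allclose(np.diag(m)[finite], 1.0)
        assert np.allclose(m[np.ix_(finite, finite)],
                           m[np.ix_(finite, finite)].T, atol=1e-12)


class TestInstantaneousCorrelation:
    def test_identical_traces(self):
        x = np.sin(np.linspace(0, 20, 5000)) + 2
        _, r = instantaneous_population_correlation(x, x, window=1000.0)
        assert np.allclose(r, 1.0)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_population_correlation(
                np.zeros(100), np.zeros(100), window=200.0)

    def test_shuffled_control_near_zero(self):
        rng = np.random.default_rng(7)
        n = 50
        counts = rng.poisson(0.01, size=(n, 60_000))
        rows, cols = np.nonzero(counts)
        spikes = make_spikes(cols.astype(float) + 0.5, rows, 60_000.0, n)
        sh = shuffle_spikes(spikes, rng)
        assert np.array_equal(np.bincount(sh.ids, minlength=n),
                              np.bincount(spikes.ids, minlength=n))
        a = calcium_filter(spike_matrix(sh, np.arange(25)).sum(axis=0))
        b = calcium_filter(spike_matrix(sh, np.arange(25, 50)).sum(axis=0))
        _, r = instantaneous_population_correlation(a, b, window=15_000.0,
                                                    step=500.0)
        # unbiased around zero; single-window estimates have sd ~ 0.1
        assert abs(np.nanmean(r)) < 0.15


class TestWinnerAndAction:
    def test_clear_winner(self):
        a = np.full(2000, 5.0)
        b = np.zeros(2000)
        w = winning_channel(a, b, labels=("A", "B"))
        assert (w == "A").all()

    def test_tie_gives_none(self):
        a = np.full(2000, 3.0)
        w = winning_channel(a, a.copy(), labels=("A", "B"))
        assert (w == "none").all()

    def test_margin_threshold(self):
        a = np.full(2000, 1.00)
        b = np.full(2000, 1.02)  # 2% relative difference < 5% margin
        assert (winning_channel(a, b, labels=("A", "B")) == "none").all()

    def test_selected_action_agreement(self):
        left = np.array(["A", "A", "B", "none"], dtype=object)
        right = np.array(["A", "B", "B", "none"], dtype=object)
        out = selected_action(left, right)
        assert list(out) == ["A", "none", "B", "none"]


class TestCoactiveAndRecruitment:
    def test_silent_network_empty(self):
        spikes = make_spikes([], [], 1000.0, 10)
        assert coactive_neurons(spikes, 0.0, 1000.0) == set()

    def test_all_driven_full_roster(self):
        spikes = make_spikes(np.full(10, 50.0), np.arange(10), 100.0, 10)
        assert coactive_neurons(spikes, 0.0, 100.0) == set(range(10))

    def test_same_channel_distance_zero(self, hemisphere_spec):
        ids = hemisphere_spec.ids(channels=[(1, 1)])
        res = recruitment_distance_distribution(
            {int(ids[0])}, {int(ids[0]), int(ids[1])}, hemisphere_spec,
            downsample=hemisphere_spec.n_neurons, seed=0)
        assert np.allclose(res.nn_distances, 0.0)
        assert res.antagonist_only_set == {int(ids[1])}

    def test_near_channel_distance_one(self, hemisphere_spec):
        a = hemisphere_spec.ids(channels=[(1, 1)])[0]
        b = hemisphere_spec.ids(channels=[(1, 2)])[0]
        res = recruitment_distance_distribution(
            {int(a)}, {int(a), int(b)}, hemisphere_spec,
            downsample=hemisphere_spec.n_neurons, seed=0)
        assert np.allclose(res.nn_distances, 1.0)

    def test_disjoint_sets_invariant(self, hemisphere_spec):
        ids = hemisphere_spec.ids(channels=[(0, 0)])[:10]
        res = recruitment_distance_distribution(
            set(ids[:5].tolist()), set(ids.tolist()), hemisphere_spec,
            downsample=hemisphere_spec.n_neurons, seed=0)
        assert not (res.control_set & res.antagonist_only_set)

    def test_empty_control_rejected(self, hemisphere_spec):
        with pytest.raises(ValueError, match="control"):
            recruitment_distance_distribution(set(), {1}, hemisphere_spec)


class TestMeanCorrection:
    def test_constant_trace_zeroed_and_mean_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(2.0, 1.0, size=(3, 1000))
        out = mean_corrected_traces(x)
        assert np.allclose(out.mean(axis=-1), 0.0, atol=1e-12)
        assert np.allclose(mean_corrected_traces(np.full((2, 10), 7.0)), 0.0)

    def test_correlation_invariant(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 2000))
        r0 = pearson_oracle(x, y)
        r1 = pearson_oracle(mean_corrected_traces(x),
                            mean_corrected_traces(y))
        assert r0 == pytest.approx(r1, abs=1e-12)
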