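"""STAPSSS waveforms, shift-bootstrap null, bias and selectivity tests."""

import numpy as np
import pandas as pd
import pytest

import pawcode as pc
from pawcode.single_unit import (
    WINDOW_BINS,
    BalancedKWResult,
    balanced_kruskal_wallis,
    compute_stapsss,
    coupling_and_bias,
    peak_offset,
    selectivity_test,
    shift_null,
    stapsss_coupling,
)


def brute_stapsss(spike_bins, status):
    """Direct per-spike window average (edge windows excluded)."""
    windows = []
    for t, k in enumerate(spike_bins):
        if k and WINDOW_BINS <= t < len(status) - WINDOW_BINS:
            windows.extend([status[t - 100 : t + 101]] * int(k))
    w = np.mean(windows, axis=0)
    return w / w.mean() if w.mean() > 0 else w


class TestWaveform:
    def test_matches_brute_force_on_short_sessions(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            T = 1000
            status = (rng.random(T) < 0.4).astype(float)
            spikes = rng.poisson(0.05, size=T)
            if spikes[WINDOW_BINS:-WINDOW_BINS].sum() == 0:
                continue
            res = compute_stapsss(spikes, status)
            np.testing.assert_allclose(
                res.waveform, brute_stapsss(spikes, status), atol=1e-12
            )

    def test_constant_swing_status_gives_flat_waveform(self):
        spikes = np.zeros(2000, dtype=int)
        spikes[500:1500:90] = 1
        res = compute_stapsss(spikes, np.ones(2000))
        assert np.allclose(res.waveform, 1.0)
        assert res.waveform_std == 0.0

    def test_single_spike_reads_status_window(self):
        status = np.zeros(1000)
        status[450:520] = 1.0
        spikes = np.zeros(1000, dtype=int)
        spikes[500] = 1
        res = compute_stapsss(spikes, status)
        window = status[400:601]
        np.testing.assert_allclose(res.waveform, window / window.mean())

    def test_time_reversal_mirrors_waveform(self):
        rng = np.random.default_rng(1)
        status = (rng.random(3000) < 0.3).astype(float)
        spikes = rng.poisson(0.03, size=3000)
        spikes[:WINDOW_BINS] = spikes[-WINDOW_BINS:] = 0
        fwd = compute_stapsss(spikes, status).waveform
        rev = compute_stapsss(spikes[::-1], status[::-1]).waveform
        np.testing.assert_allclose(rev, fwd[::-1], atol=1e-12)

    def test_low_rate_unit_rejected(self):
        spikes = np.zeros(60000, dtype=int)  # 10 min
        spikes[30000] = 1
        with pytest.raises(ValueError, match="0.1 Hz"):
            compute_stapsss(spikes, np.ones(60000))

    def test_multi_spike_bins_weighted_by_count(self):
        status = np.zeros(1000)
        status[350:450] = 1.0
        spikes = np.zeros(1000, dtype=int)
        spikes[400] = 2
        spikes[600] = 1
        res = compute_stapsss(spikes, status)
        np.testing.assert_allclose(
            res.waveform, brute_stapsss(spikes, status), atol=1e-12
        )

    def test_coupling_invariant_to_status_scaling(self):
        """c depends on the mean-normalized waveform only."""
        rng = np.random.default_rng(2)
        status = (rng.random(4000) < 0.3).astype(float)
        spikes = rng.poisson(0.05, size=4000)
        a = stapsss_coupling(spikes, status, n_shifts=200, seed=3)
        b = stapsss_coupling(spikes, status * 7.0, n_shifts=200, seed=3)
        assert a.coupling == pytest.approx(b.coupling, rel=1e-9)


class TestShiftNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        status = (rng.random(5000) < 0.4).astype(float)
        spikes = rng.poisson(0.05, size=5000)
        q1 = shift_null(spikes, status, n_shifts=300, seed=9)
        q2 = shift_null(spikes, status, n_shifts=300, seed=9)
        assert q1 == q2

    def test_matches_explicit_rotation_oracle(self):
        """FFT sliding-window path equals recomputing each rotated train."""
        rng = np.random.default_rng(4)
        T = 2000
        status = (rng.random(T) < 0.35).astype(float)
        spikes = rng.poisson(0.04, size=T)
        n_spikes = spikes.sum()

        def circular_cv(offset):
            rolled = np.roll(spikes, offset)
            idx = np.nonzero(rolled)[0]
            offs = np.arange(-WINDOW_BINS, WINDOW_BINS + 1)
            win = status[(idx[:, None] + offs) % T]
            w = rolled[idx] @ win / n_spikes
            return w.std() / w.mean() if w.mean() > 0 else 0.0

        r = np.fft.irfft(
            np.conj(np.fft.rfft(spikes.astype(float))) * np.fft.rfft(status),
            n=T,
        )
        from pawcode.single_unit import _circular_moving_moments

        s1, s2 = _circular_moving_moments(r, 201)
        mean = s1 / (201 * n_spikes)
        var = np.maximum(s2 / (201 * n_spikes**2) - mean**2, 0)
        cv = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
        for off in (150, 700, 1300, 1899):
            assert cv[off] == pytest.approx(circular_cv(off), abs=1e-10)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="4 s"):
            shift_null(np.ones(300, dtype=int), np.ones(300), n_shifts=100)

    def test_too_few_shifts_rejected(self):
        with pytest.raises(ValueError, match="100"):
            shift_null(np.ones(1000, dtype=int), np.ones(1000), n_shifts=50)


class TestPeakOffset:
    def test_center_peak_is_zero(self):
        w = np.ones(201)
        w[100] = 2.0
        assert peak_offset(w) == 0.0

    def test_mirrored_waveform_negates_offset(self):
        w = np.ones(201)
        w[80] = 1.8  # 200 ms before the spike
        assert peak_offset(w) == -200.0
        assert peak_offset(w[::-1]) == 200.0

    def test_flat_waveform_is_missing(self):
        assert peak_offset(np.ones(201)) is None

    def test_ties_break_toward_zero(self):
        w = np.ones(201)
        w[90] = w[95] = 1.5
        assert peak_offset(w) == -50.0

    def test_planted_latency_yields_negative_offset(self, shared_arch):
        """Swing gain delayed by +200 ms: movement precedes the spikes."""
        import dataclasses

        arch = dataclasses.replace(
            shared_arch,
            swing_latency_s_by_area={"M2": 0.2, "M1": 0.2, "S1": 0.2},
        )
        cfg = pc.SessionConfig(duration_s=600.0, seed=12)
        pop = pc.generate_population(arch, cfg)
        pop["swing_gain"] = 1.0
        pop.loc[pop.index[0], "swing_gain"] = 3.0
        sess = pc.generate_session(arch, cfg, population=pop)
        paw = pop.iloc[0]["contra_paw"]
        status = pc.binarize_paw(
            sess.paw_velocity[:, pc.PAWS.index(paw)], paw=paw
        )
        res = stapsss_coupling(
            sess.spike_counts(0.01)[0], status, seed=1
        )
        assert res.significant
        assert -320.0 <= res.peak_offset_ms <= -80.0


class TestBias:
    def _table(self, couplings):
        return pd.DataFrame(
            [
                {"unit_id": 0, "paw": paw, "coupling": c}
                for paw, c in couplings.items()
            ]
        )

    def _units(self, hemi):
        return pd.DataFrame(
            [{"unit_id": 0, "area": "S1", "hemisphere": hemi,
              "region": "forelimb", "snr": 3.0, "single_unit": True}]
        )

    def test_equal_couplings_give_unit_bias(self):
        tab = self._table({"front_left": 1.5, "front_right": 1.5,
                           "hind_left": 0.7, "hind_right": 0.7})
        bias = coupling_and_bias(tab, self._units("L"))
        assert np.allclose(bias["bias"], 1.0)

    def test_left_hemisphere_right_over_left(self):
        tab = self._table({"front_left": 1.0, "front_right": 2.0,
                           "hind_left": 1.0, "hind_right": 1.0})
        bias = coupling_and_bias(tab, self._units("L"))
        front = bias[bias["pair"] == "front"]["bias"].iloc[0]
        assert front == pytest.approx(2.0)

    def test_right_hemisphere_flips_ratio(self):
        tab = self._table({"front_left": 1.0, "front_right": 2.0,
                           "hind_left": 1.0, "hind_right": 1.0})
        bias = coupling_and_bias(tab, self._units("R"))
        front = bias[bias["pair"] == "front"]["bias"].iloc[0]
        assert front == pytest.approx(0.5)

    def test_zero_ipsilateral_coupling_is_missing(self):
        tab = self._table({"front_left": 0.0, "front_right": 2.0,
                           "hind_left": 1.0, "hind_right": 1.0})
        bias = coupling_and_bias(tab, self._units("L"))
        assert np.isnan(bias[bias["pair"] == "front"]["bias"].iloc[0])


class TestSelectivity:
    def test_identical_distributions_select_nothing(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(list(pc.CLASSES), 60)
        counts = rng.poisson(3.0, size=len(labels))
        table = selectivity_test(counts, labels)
        assert not table["selective"].any()

    def test_drink_only_unit_is_drink_selective(self):
        rng = np.random.default_rng(6)
        labels = np.repeat(list(pc.CLASSES), 60)
        counts = np.zeros(len(labels), dtype=int)
        counts[labels == "drink"] = rng.poisson(4.0, size=60)
        table = selectivity_test(counts, labels).set_index("class")
        assert table.loc["drink", "selective"]
        assert not table.drop("drink")["selective"].any()

    def test_adjusted_pvalues_follow_bh_step_up(self):
        rng = np.random.default_rng(7)
        labels = np.repeat(list(pc.CLASSES), 40)
        counts = rng.poisson(2.0, size=len(labels))
        counts[labels == "rear"] += rng.poisson(2.0, size=40)
        table = selectivity_test(counts, labels)
        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(table["p_adj"], manual, atol=1e-12)

    def test_absent_class_flagged_untested(self):
        labels = np.repeat(["step", "rest"], 100)
        counts = np.random.default_rng(8).poisson(2.0, size=200)
        table = selectivity_test(counts, labels).set_index("class")
        assert not table.loc["drink", "tested"]


class TestBalancedKruskalWallis:
    def test_null_distributions_yield_few_pairs(self):
        rng = np.random.default_rng(9)
        labels = np.repeat(list(pc.CLASSES), 40)
        counts = rng.poisson(3.0, size=len(labels))
        res = balanced_kruskal_wallis(counts, labels, n_resamples=30, seed=1)
        assert res.mean_significant_pairs <= 1.5

    def test_planted_class_dominates_pairs(self):
        rng = np.random.default_rng(10)
        labels = np.repeat(list(pc.CLASSES), 40)
        counts = rng.poisson(3.0, size=len(labels))
        counts[labels == "groom"] += rng.poisson(3.0, size=40)
        res = balanced_kruskal_wallis(counts, labels, n_resamples=30, seed=1)
        assert res.mean_significant_pairs >= 3.0
        groom_rate = np.mean(
            [v for k, v in res.pair_means.items() if "groom" in k]
        )
        other_rate = np.mean(
            [v for k, v in res.pair_means.items() if "groom" not in k]
        )
        assert groom_rate > other_rate

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        labels = np.repeat(list(pc.CLASSES), 30)
        counts = rng.poisson(3.0, size=len(labels))
        r1 = balanced_kruskal_wallis(counts, labels, n_resamples=20, seed=4)
        r2 = balanced_kruskal_wallis(counts, labels, n_resamples=20, seed=4)
        assert r1.mean_significant_pairs == r2.mean_significant_pairs

    def test_small_class_skipped_with_warning(self):
        labels = np.array(
            ["step"] * 50 + ["turn"] * 50 + ["drink"] * 3
            + ["groom"] * 50 + ["rear"] * 50 + ["rest"] * 50
        )
        counts = np.random.default_rng(12).poisson(2.0, size=len(labels))
        with pytest.warns(UserWarning, match="smallest class"):
            res = balanced_kruskal_wallis(counts, labels, n_resamples=5)
        assert isinstance(res, BalancedKWResult)
        assert np.isnan(res.mean_significant_pairs)

    def test_missing_class_rejected(self):
        labels = np.repeat(["step", "rest"], 50)
        counts = np.zeros(100, dtype=int)
        with pytest.raises(ValueError, match="six"):
            balanced_kruskal_wallis(counts, labels)
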