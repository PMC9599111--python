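"""Morlet transform, band power and ERSP tests, with an independent
bandpass+Hilbert oracle for the power estimates."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from oscinet import (
    ALPHA,
    BETA,
    GroundTruth,
    band_power,
    compute_ersp,
    generate_dataset,
    group_ersp,
    morlet_tfr,
)
from oscinet.simulate import ParadigmSpec, TrialDataset


def _tone_dataset(atlas, freq=10.0, fs=128.0, amp=1.0, n_trials=2):
    """A deterministic pure-tone dataset (all ROIs identical)."""
    p = ParadigmSpec(
        baseline_window=(-2.0, -1.0), cue_window=(-1.0, 0.0), task_window=(0.0, 3.0),
        rest_lead=1.0, sampling_rate=fs,
        group_sizes={"CG": n_trials, "M-AIG": n_trials, "F-AIG": n_trials},
    )
    t = p.time()
    x = amp * np.cos(2 * np.pi * freq * t)
    data = np.tile(x, (3 * n_trials, 130, 1))
    group = np.array(
        ["CG"] * n_trials + ["M-AIG"] * n_trials + ["F-AIG"] * n_trials, dtype=object
    )
    return TrialDataset(data=data, group=group, time=t, sampling_rate=fs, atlas=atlas, paradigm=p)


class TestMorlet:
    def test_pure_tone_power_concentrates_at_its_frequency(self, atlas):
        ds = _tone_dataset(atlas, freq=10.0)
        tfr = morlet_tfr(ds, freqs=np.arange(8.0, 30.0), cycles=None)
        p = tfr.power()[0, 0]  # freqs x samples
        interior = slice(100, -100)
        prof = p[:, interior].mean(axis=1)
        assert tfr.freqs[np.argmax(prof)] == pytest.approx(10.0)
        # at 10 Hz the power is flat over time away from edges
        row = p[np.argmax(prof), interior]
        assert row.std() / row.mean() < 0.01
        # away from the tone (beyond the 14 Hz wavelet's ~2 Hz bandwidth)
        # there is essentially no power
        beta_rows = prof[tfr.freqs >= 16]
        assert beta_rows.max() < 1e-3 * prof.max()

    def test_coefficients_linear_in_amplitude(self, atlas):
        d1 = _tone_dataset(atlas, amp=1.0)
        d2 = _tone_dataset(atlas, amp=2.0)
        freqs = np.arange(8.0, 14.0)
        c1 = morlet_tfr(d1, freqs).coeffs[0, 0]
        c2 = morlet_tfr(d2, freqs).coeffs[0, 0]
        assert np.allclose(np.abs(c2), 2 * np.abs(c1), rtol=1e-10)

    def test_frequency_above_nyquist_rejected(self, atlas):
        ds = _tone_dataset(atlas, fs=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tfr(ds, freqs=np.array([40.0]))
        with pytest.raises(ValueError, match="empty"):
            morlet_tfr(ds, freqs=np.array([]))

    def test_white_noise_band_power_matches_closed_form(self, atlas, small_paradigm):
        """Unit-energy-pair wavelets: E|c|^2 = 2*sigma^2 for white noise."""
        rng = np.random.default_rng(3)
        p = small_paradigm
        sigma = 0.7
        data = sigma * rng.standard_normal((20, 130, p.n_samples))
        group = np.array(["CG"] * 8 + ["M-AIG"] * 6 + ["F-AIG"] * 6, dtype=object)
        ds = TrialDataset(
            data=data, group=group, time=p.time(), sampling_rate=p.sampling_rate,
            atlas=atlas, paradigm=p,
        )
        tfr = morlet_tfr(ds, freqs=np.arange(8.0, 14.0))
        bp = band_power(tfr, ALPHA, (-2.0, 3.0))
        assert bp.mean() == pytest.approx(2 * sigma**2, rel=0.10)


class TestBandPower:
    def test_zero_signal_gives_zero_power(self, atlas):
        ds = _tone_dataset(atlas, amp=0.0)
        tfr = morlet_tfr(ds, freqs=np.arange(8.0, 14.0))
        assert band_power(tfr, ALPHA, (0.0, 3.0)).max() == 0.0

    def test_stationary_signal_has_equal_baseline_and_task_power(self, null_dataset):
        tfr = morlet_tfr(null_dataset, freqs=np.arange(8.0, 14.0))
        e_b = band_power(tfr, ALPHA, null_dataset.paradigm.baseline_window)
        e_t = band_power(tfr, ALPHA, null_dataset.paradigm.task_window)
        assert e_t.mean() == pytest.approx(e_b.mean(), rel=0.05)

    def test_window_outside_time_axis_rejected(self, null_dataset):
        tfr = morlet_tfr(null_dataset, freqs=np.arange(8.0, 14.0))
        with pytest.raises(ValueError, match="outside"):
            band_power(tfr, ALPHA, (5.0, 12.0))
        with pytest.raises(ValueError, match="not covered"):
            band_power(tfr, BETA, (0.0, 3.0))


class TestERSPFormula:
    @pytest.mark.parametrize(
        "e_t, e_b, expected",
        [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (0.5, 1.0, -0.5), (0.0, 1.0, -1.0)],
    )
    def test_identities_exact(self, e_t, e_b, expected):
        assert compute_ersp(e_t, e_b) == expected

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_ersp(1.0, 0.0)
        with pytest.raises(ValueError, match="baseline"):
            compute_ersp(np.array([1.0, 1.0]), np.array([1.0, -0.5]))

    @given(
        e_t=st.floats(0.0, 1e6, allow_nan=False),
        e_b=st.floats(1e-9, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_lower_bound_property(self, e_t, e_b):
        """ERSP >= -1 for any nonnegative powers with positive baseline."""
        assert compute_ersp(e_t, e_b) >= -1.0


def _hilbert_ersp(ds: TrialDataset, band, margin=0.3):
    """Independent ERSP oracle: Butterworth bandpass + analytic-signal power."""
    sos = scipy.signal.butter(
        4, [band.lo, band.hi], btype="bandpass", fs=ds.sampling_rate, output="sos"
    )
    xf = scipy.signal.sosfiltfilt(sos, np.asarray(ds.data, dtype=float), axis=-1)
    power = np.abs(scipy.signal.hilbert(xf, axis=-1)) ** 2
    t = ds.time
    out = {}
    for g in ds.paradigm.group_sizes:
        idx = ds.trial_indices(g)
        e = {}
        for name, (lo, hi) in (
            ("b", ds.paradigm.baseline_window), ("t", ds.paradigm.task_window)
        ):
            m = (t >= lo + margin) & (t < hi - margin)
            e[name] = power[idx][:, :, m].mean(axis=(0, 2))
        out[g] = e["t"] / e["b"] - 1.0
    return out


class TestGroupERSP:
    def test_null_dataset_has_near_zero_ersp(self, null_dataset):
        res = group_ersp(null_dataset)
        assert len(res.table) == 130 * 2 * 3
        assert np.abs(res.table.ersp).max() < 0.35
        assert set(res.table.label) <= {"ERS", "ERD"}

    def test_planted_gain_recovered_and_matches_hilbert_oracle(self, planted_dataset):
        res = group_ersp(planted_dataset)
        atlas = planted_dataset.atlas
        i = atlas.index("cuneus_L")
        ersp_cg = res.ersp("alpha", "CG")
        # true ERSP = g^2 - 1 = 3; broadband noise dilutes the ratio slightly
        assert 2.2 < ersp_cg[i] < 3.3
        others = np.delete(ersp_cg, i)
        assert np.abs(others).max() < 0.5
        # agreement with the independent filter+Hilbert pipeline
        oracle = _hilbert_ersp(planted_dataset, ALPHA)["CG"]
        assert ersp_cg[i] == pytest.approx(oracle[i], rel=0.10)
        assert np.abs(others - np.delete(oracle, i)).max() < 0.25

    def test_alpha_effect_does_not_leak_into_beta(self, planted_dataset):
        res = group_ersp(planted_dataset)
        i = planted_dataset.atlas.index("cuneus_L")
        beta_cg = res.ersp("beta", "CG")
        assert abs(beta_cg[i]) < 0.3  # noise ceiling, no planted beta effect

    def test_label_consistent_with_sign(self, planted_dataset):
        res = group_ersp(planted_dataset)
        tab = res.table
        assert ((tab.ersp > 0) == (tab.label == "ERS")).all()

    def test_ersp_standard_error_shrinks_with_trial_count(self, atlas):
        """Group ERSP noise scales like 1/sqrt(n): quadrupling the trial
        count roughly halves the spread of null ERSP values across ROIs."""
        from dataclasses import replace

        from oscinet import ALPHA, GroundTruth, ParadigmSpec, generate_dataset

        base = ParadigmSpec(
            baseline_window=(-2.0, -1.0), cue_window=(-1.0, 0.0),
            task_window=(0.0, 3.0), rest_lead=1.0, sampling_rate=128.0,
            group_sizes={"CG": 4, "M-AIG": 2, "F-AIG": 2},
        )
        spreads = []
        for n_cg in (4, 16):
            p = replace(base, group_sizes={"CG": n_cg, "M-AIG": 2, "F-AIG": 2})
            ds = generate_dataset(p, atlas, GroundTruth(noise_level=0.3), seed=31)
            res = group_ersp(ds, bands=(ALPHA,))
            spreads.append(res.ersp("alpha", "CG").std())
        assert spreads[1] < spreads[0]
        assert spreads[0] / spreads[1] == pytest.approx(2.0, rel=0.45)

    def test_trial_activation_shape_and_consistency(self, planted_dataset):
        res = group_ersp(planted_dataset)
        act = res.trial_activation("alpha")
        assert act.shape == (planted_dataset.n_trials, 130)
        assert np.all(act >= -1.0)
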