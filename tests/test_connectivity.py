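"""Phase extraction, PLV estimation and the three-group threshold rule."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.signal

from oscinet import (
    ALPHA,
    BETA,
    Coupling,
    GroundTruth,
    PLVMatrix,
    bessel_ratio_plv,
    compute_plv,
    compute_threshold,
    generate_dataset,
    group_plv,
    instantaneous_phase,
)
from oscinet.simulate import ParadigmSpec, TrialDataset

GROUPS = ("CG", "M-AIG", "F-AIG")


def _make_dataset(atlas, data, paradigm):
    n = sum(paradigm.group_sizes.values())
    group = np.concatenate(
        [[g] * k for g, k in paradigm.group_sizes.items()]
    ).astype(object)
    return TrialDataset(
        data=data, group=group, time=paradigm.time(),
        sampling_rate=paradigm.sampling_rate, atlas=atlas, paradigm=paradigm,
    )


class TestInstantaneousPhase:
    @pytest.fixture(scope="class")
    def tone_ds(self, atlas, small_paradigm):
        t = small_paradigm.time()
        rng = np.random.default_rng(0)
        data = np.empty((20, 130, t.size))
        lag = 0.01  # ROI 1 lags ROI 0 by 10 ms
        for k in range(20):
            phi = rng.uniform(-np.pi, np.pi)
            data[k] = np.cos(2 * np.pi * ALPHA.center * t + phi)
            data[k, 1] = np.cos(2 * np.pi * ALPHA.center * (t - lag) + phi)
        return _make_dataset(atlas, data, small_paradigm)

    def test_phase_advances_at_carrier_rate(self, tone_ds):
        phases, times = instantaneous_phase(tone_ds, ALPHA)
        dphi = np.diff(np.unwrap(phases[0, 0]))
        expected = 2 * np.pi * ALPHA.center / tone_ds.sampling_rate
        assert np.allclose(dphi, expected, rtol=0.02)
        assert phases.max() <= np.pi and phases.min() > -np.pi

    def test_amplitude_invariance(self, tone_ds):
        scaled = _make_dataset(
            tone_ds.atlas, 5.0 * np.asarray(tone_ds.data), tone_ds.paradigm
        )
        p1, _ = instantaneous_phase(tone_ds, ALPHA)
        p2, _ = instantaneous_phase(scaled, ALPHA)
        assert np.allclose(p1, p2, atol=1e-9)

    def test_constant_lag_matches_hilbert_oracle(self, tone_ds):
        """Phase difference of a lagged copy is 2*pi*f*tau, as the
        analytic-signal (Hilbert) oracle also reports."""
        phases, _ = instantaneous_phase(tone_ds, ALPHA)
        dphi = np.angle(np.exp(1j * (phases[:, 0] - phases[:, 1])))
        expected = 2 * np.pi * ALPHA.center * 0.01
        assert np.allclose(dphi, expected, atol=0.03)
        # independent oracle: bandpass + Hilbert on the raw trial
        sos = scipy.signal.butter(
            4, [ALPHA.lo, ALPHA.hi], btype="bandpass",
            fs=tone_ds.sampling_rate, output="sos",
        )
        xf = scipy.signal.sosfiltfilt(sos, np.asarray(tone_ds.data[0, :2]), axis=-1)
        z = scipy.signal.hilbert(xf, axis=-1)
        mid = slice(200, -200)
        oracle = np.angle((z[0, mid] * np.conj(z[1, mid])).mean())
        assert oracle == pytest.approx(expected, abs=0.03)

    def test_band_above_nyquist_rejected(self, tone_ds):
        from oscinet.bands import BandSpec

        with pytest.raises(ValueError, match="Nyquist"):
            instantaneous_phase(tone_ds, BandSpec("hi", 60.0, 70.0))


class TestComputePLV:
    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(-np.pi, np.pi, size=(10, 50))
        assert compute_plv(ph, ph) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(-np.pi, np.pi, size=(10, 50))
        assert compute_plv(ph, ph + 1.3) == pytest.approx(1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            compute_plv(np.zeros((1, 50)), np.zeros((1, 50)))

    def test_independent_phases_hit_the_resultant_floor(self):
        """Mean PLV of n independent uniform phases ~ sqrt(pi)/(2 sqrt(n))."""
        rng = np.random.default_rng(3)
        n = 20
        vals = [
            compute_plv(
                rng.uniform(-np.pi, np.pi, size=(n, 1)),
                rng.uniform(-np.pi, np.pi, size=(n, 1)),
            )
            for _ in range(400)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_trial_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, size=(12, 40))
        b = rng.uniform(-np.pi, np.pi, size=(12, 40))
        perm = rng.permutation(12)
        assert compute_plv(a, b) == pytest.approx(compute_plv(a[perm], b[perm]))


class TestGroupPLV:
    @pytest.fixture(scope="class")
    def plv_paradigm(self, small_paradigm):
        # PLV estimates need a decent trial count to beat sampling noise
        from dataclasses import replace

        return replace(
            small_paradigm, group_sizes={"CG": 36, "M-AIG": 6, "F-AIG": 6}
        )

    @pytest.fixture(scope="class")
    def coupled_ds(self, atlas, plv_paradigm):
        truth = GroundTruth(
            coupling=tuple(
                Coupling("insula_L", "insula_R", "alpha", g, 5.0) for g in GROUPS
            ),
            noise_level=0.0,
        )
        return generate_dataset(plv_paradigm, atlas, truth, seed=21)

    def test_three_matrices_with_bounds_and_symmetry(self, coupled_ds):
        mats = group_plv(coupled_ds, ALPHA)
        assert set(mats) == set(GROUPS)
        for m in mats.values():
            assert np.allclose(m.values, m.values.T)
            assert 0 <= m.values.min() and m.values.max() <= 1
            assert np.allclose(np.diag(m.values), 1.0)

    def test_planted_pair_separates_from_floor(self, coupled_ds):
        m = group_plv(coupled_ds, ALPHA)["CG"]
        i = coupled_ds.atlas.index("insula_L")
        j = coupled_ds.atlas.index("insula_R")
        target = bessel_ratio_plv(5.0)
        assert m.values[i, j] == pytest.approx(target, abs=0.08)
        off = m.values.copy()
        off[i, j] = off[j, i] = 0.0
        np.fill_diagonal(off, 0.0)
        assert m.values[i, j] > off.max() + 0.2

    def test_plv_monotone_in_kappa(self, atlas, plv_paradigm):
        """Planted PLV increases with concentration, tracking I1/I0."""
        pairs = [("insula_L", "insula_R"), ("cuneus_L", "cuneus_R"),
                 ("precuneus_L", "precuneus_R")]
        kappas = [1.0, 2.0, 5.0]
        truth = GroundTruth(
            coupling=tuple(
                Coupling(a, b, "alpha", "CG", k) for (a, b), k in zip(pairs, kappas)
            ),
            noise_level=0.0,
        )
        n_seeds = 8
        got = np.zeros((n_seeds, 3))
        for s, seed in enumerate(range(22, 22 + n_seeds)):
            ds = generate_dataset(plv_paradigm, atlas, truth, seed=seed)
            m = group_plv(ds, ALPHA)["CG"]
            got[s] = [m.values[atlas.index(a), atlas.index(b)] for a, b in pairs]
        mean = got.mean(axis=0)
        assert mean[0] < mean[1] < mean[2]
        # Monte-Carlo oracle: resultant of n von-Mises phase differences
        n = plv_paradigm.group_sizes["CG"]
        rng = np.random.default_rng(99)
        for val, k in zip(mean, kappas):
            r = np.abs(np.exp(1j * rng.vonmises(0, k, size=(4000, n))).mean(axis=1))
            se = np.sqrt(r.var() / n_seeds + r.var() / 4000)
            assert abs(val - r.mean()) < 3 * se + 0.01

    def test_group_with_too_few_trials_rejected(self, atlas):
        p = ParadigmSpec(
            baseline_window=(-2.0, -1.0), cue_window=(-1.0, 0.0),
            task_window=(0.0, 3.0), rest_lead=1.0, sampling_rate=128.0,
            group_sizes={"CG": 4, "M-AIG": 1, "F-AIG": 4},
        )
        ds = generate_dataset(p, atlas, GroundTruth(), seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            group_plv(ds, ALPHA)


class TestThreshold:
    def _mat(self, mean, band=ALPHA, group="CG", n=130):
        # symmetric matrix with the requested off-diagonal mean
        v = np.full((n, n), mean, dtype=float)
        np.fill_diagonal(v, 1.0)
        return PLVMatrix(values=v, band=band, group=group, n_trials=10)

    @pytest.mark.parametrize(
        "means, expected",
        [((0.3, 0.3, 0.3), 0.6), ((0.1, 0.2, 0.3), 0.4), ((0.6, 0.6, 0.6), 1.2)],
    )
    def test_formula_exact(self, means, expected):
        thr = compute_threshold(
            self._mat(means[0], group="M-AIG"),
            self._mat(means[1], group="F-AIG"),
            self._mat(means[2], group="CG"),
        )
        assert thr.threshold == pytest.approx(expected, abs=1e-12)
        assert thr.component_means == {
            "M-AIG": pytest.approx(means[0]),
            "F-AIG": pytest.approx(means[1]),
            "CG": pytest.approx(means[2]),
        }

    def test_formula_independent_of_matrix_size(self):
        small = [
            PLVMatrix(
                np.full((4, 4), 0.25) + np.eye(4) * 0.75, ALPHA, g, 10
            )
            for g in ("M-AIG", "F-AIG", "CG")
        ]
        thr = compute_threshold(*small)
        assert thr.threshold == pytest.approx(0.5, abs=1e-12)

    def test_ceiling_exceedance_flagged(self):
        with pytest.warns(UserWarning, match="ceiling"):
            thr = compute_threshold(
                self._mat(0.6, group="M-AIG"),
                self._mat(0.6, group="F-AIG"),
                self._mat(0.6, group="CG"),
            )
        assert thr.exceeds_ceiling

    def test_band_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band"):
            compute_threshold(
                self._mat(0.3, group="M-AIG"),
                self._mat(0.3, band=BETA, group="F-AIG"),
                self._mat(0.3, group="CG"),
            )

    def test_shape_mismatch_rejected(self):
        small = PLVMatrix(np.eye(4), ALPHA, "F-AIG", 10)
        with pytest.raises(ValueError, match="shape"):
            compute_threshold(self._mat(0.3, group="M-AIG"), small, self._mat(0.3))
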