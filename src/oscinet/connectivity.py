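"""Phase extraction, phase-locking-value matrices, and the three-group
threshold interception rule.

Phase locking between two ROIs is measured across trials: at each task
sample the phase difference is pooled over trials into a resultant
vector, and its length (in [0, 1]) is averaged over the task window.
Because trial phases are randomised by the paradigm, a consistent
phase relation across trials indicates functional coupling; n
independent phases leave a chance floor of about 1/sqrt(n).

Networks for the three trial groups are thresholded with a *shared*
interception value so their edge sets are comparable::

    threshold = 2 * (mean_PLV_M + mean_PLV_F + mean_PLV_CG) / 3

i.e. twice the across-group average of the mean (off-diagonal) PLV.
The formula can exceed 1; that is allowed and simply yields empty
networks (a warning is logged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from .bands import BandSpec
from .simulate import TrialDataset
from .spectral import default_cycles

__all__ = [
    "PLVMatrix",
    "ThresholdSpec",
    "instantaneous_phase",
    "compute_plv",
    "group_plv",
    "compute_threshold",
]


@dataclass
class PLVMatrix:
    """Symmetric ROI x ROI phase-locking values in [0, 1] for one (band, group)."""

    values: np.ndarray
    band: BandSpec
    group: str
    n_trials: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("PLV values must lie in [0, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def mean_plv(self) -> float:
        """Mean PLV over the off-diagonal (self-coupling excluded)."""
        n = self.n_rois
        off = ~np.eye(n, dtype=bool)
        return float(self.values[off].mean())


@dataclass
class ThresholdSpec:
    """The shared interception threshold and its per-group components."""

    threshold: float
    component_means: dict[str, float]
    band: str = ""

    @property
    def exceeds_ceiling(self) -> bool:
        return self.threshold > 1.0


def instantaneous_phase(
    ds: TrialDataset,
    band: BandSpec,
    window: tuple[float, float] | None = None,
    decim: int = 1,
    trials: np.ndarray | slice = slice(None),
) -> tuple[np.ndarray, np.ndarray]:
    """Band phase per (trial, ROI, sample) within a window.

    The phase is the argument of the Morlet coefficient at the
    band-center frequency, so it is invariant to amplitude scaling of
    the input.  Samples within half a wavelet width of the window
    borders are excluded.  Returns ``(phases, times)`` with phases in
    (-pi, pi].
    """
    band.check_nyquist(ds.sampling_rate)
    window = window or ds.paradigm.task_window
    cycles = default_cycles(np.array([band.center]))
    margin = float(cycles[0] / band.center / 2.0)
    times = ds.time[::decim]
    from .spectral import _window_samples

    smask = _window_samples(times, window, margin)
    from .spectral import _morlet_coeff_stream

    (_, coeff), = _morlet_coeff_stream(
        ds.data[trials], ds.sampling_rate, np.array([band.center]), cycles, decim=decim
    )
    return np.angle(coeff[..., smask]), times[smask]


def compute_plv(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Across-trials phase-locking value of two phase arrays (trials x samples).

    At each sample the resultant length of exp(i * (phase_i - phase_j))
    over trials is taken; the PLV is its mean over samples.
    """
    phase_i = np.atleast_2d(np.asarray(phase_i, dtype=float))
    phase_j = np.atleast_2d(np.asarray(phase_j, dtype=float))
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase arrays must have equal shapes")
    if phase_i.shape[0] < 2:
        raise ValueError("PLV across trials needs at least 2 trials")
    z = np.exp(1j * (phase_i - phase_j))
    resultant = np.abs(z.mean(axis=0))
    return float(resultant.mean())


def _plv_matrix_from_phases(phases: np.ndarray, chunk: int = 200) -> np.ndarray:
    """All-pairs PLV from phases (trials x ROIs x samples)."""
    n_trials, n_rois, n_samp = phases.shape
    z = np.exp(1j * phases)
    acc = np.zeros((n_rois, n_rois))
    for s in range(0, n_samp, chunk):
        zc = z[:, :, s : s + chunk]
        # resultant of the phase differences, all pairs at once
        c = np.einsum("nrt,nst->rst", zc.conj(), zc) / n_trials
        acc += np.abs(c).sum(axis=2)
    plv = acc / n_samp
    plv = 0.5 * (plv + plv.T)
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


def group_plv(
    ds: TrialDataset,
    band: BandSpec,
    window: tuple[float, float] | None = None,
    decim: int = 1,
) -> dict[str, PLVMatrix]:
    """One symmetric PLV matrix per trial group for one band.

    By default phases are taken over the task window.  Groups need at
    least two trials.
    """
    out: dict[str, PLVMatrix] = {}
    for g in ds.paradigm.group_sizes:
        idx = ds.trial_indices(g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 trials; PLV is degenerate")
        phases, _ = instantaneous_phase(ds, band, window=window, decim=decim, trials=idx)
        out[g] = PLVMatrix(
            values=_plv_matrix_from_phases(phases),
            band=band,
            group=g,
            n_trials=int(idx.size),
        )
    return out


def compute_threshold(
    plv_m: PLVMatrix, plv_f: PLVMatrix, plv_cg: PLVMatrix
) -> ThresholdSpec:
    """Shared edge threshold: 2 x (mean_M + mean_F + mean_CG) / 3.

    The three matrices must share band and shape.  A threshold above the
    PLV ceiling of 1 is legal (all networks come out empty) and is
    flagged with a warning.
    """
    mats = (plv_m, plv_f, plv_cg)
    bands = {m.band.name for m in mats}
    shapes = {m.values.shape for m in mats}
    if len(bands) != 1:
        raise ValueError(f"PLV matrices must share a band, got {sorted(bands)}")
    if len(shapes) != 1:
        raise ValueError(f"PLV matrices must share a shape, got {shapes}")
    means = {m.group: m.mean_plv for m in mats}
    threshold = 2.0 * sum(means.values()) / 3.0
    spec = ThresholdSpec(threshold=threshold, component_means=means, band=bands.pop())
    if spec.exceeds_ceiling:
        warnings.warn(
            f"threshold {threshold:.3f} exceeds the PLV ceiling of 1; "
            "all thresholded networks will be empty",
            stacklevel=2,
        )
    return spec
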