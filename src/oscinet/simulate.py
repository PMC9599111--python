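"""Trial-structured synthetic ROI oscillations with known ERSP and PLV.

The generator emulates the motor-imagery-of-swallowing paradigm: 19 s
trials sampled at 1200 Hz with a 6 s rest segment (of which the last
two seconds, -5..-3 s, serve as baseline), a 3 s cue (-3..0 s) and a
10 s imagery task window (0..10 s, zero at imagery onset), for three
trial groups — the non-induced control group (CG, 40 trials) and the
male/female action-observation-induced groups (M-AIG and F-AIG, 20
trials each).

Signal model, per ROI and trial::

    x(t) = sum_bands  env_b(t) * cos(2*pi*(f_b + delta) * t + phi)  +  sigma * n_1/f(t)

* one oscillator per band at the band-center carrier ``f_b``, with a
  small per-trial frequency jitter ``delta`` (oscillation peaks in real
  recordings wander from trial to trial; the jitter also dephases
  uncoupled ROI pairs over the 10 s task window, concentrating the PLV
  chance floor);
* ``env_b(t)`` equals 1 outside the task window and the amplitude gain
  ``g`` inside it, so the planted true ERSP is ``g**2 - 1``;
* phase coupling: coupled ROIs share a latent per-trial phase (and
  frequency jitter); the non-reference ROI adds von-Mises jitter of
  concentration ``kappa``, so the planted true PLV of a coupled pair is
  the Bessel ratio ``I1(kappa) / I0(kappa)``;
* uncoupled ROIs draw independent uniform phases, giving the usual
  ``~1/sqrt(n_trials)`` resultant-length floor;
* additive 1/f ("pink") broadband noise of standard deviation ``sigma``
  relative to the unit oscillator amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .atlas import AtlasSpec, N_ROIS, as_roi_indices
from .bands import DEFAULT_BANDS, BandSpec

__all__ = [
    "ParadigmSpec",
    "Coupling",
    "GroundTruth",
    "TrialDataset",
    "generate_dataset",
    "demo_ground_truth",
]

GROUPS = ("CG", "M-AIG", "F-AIG")


@dataclass(frozen=True)
class ParadigmSpec:
    """Trial timing and group design.

    Windows are half-open ``[start, end)`` in seconds relative to task
    (imagery) onset at t = 0.  The trial spans from ``baseline_window[0]
    - rest_lead`` to ``task_window[1]``; under the defaults that is
    -9..10 s, i.e. a 19 s trial whose 6 s rest segment precedes the cue
    but only its final 2 s (-5..-3 s) are used as baseline.
    """

    baseline_window: tuple[float, float] = (-5.0, -3.0)
    cue_window: tuple[float, float] = (-3.0, 0.0)
    task_window: tuple[float, float] = (0.0, 10.0)
    rest_lead: float = 4.0
    sampling_rate: float = 1200.0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CG": 40, "M-AIG": 20, "F-AIG": 20}
    )

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("baseline_window", self.baseline_window),
            ("cue_window", self.cue_window),
            ("task_window", self.task_window),
        ):
            if not a < b:
                raise ValueError(f"{name} must have start < end, got {a}..{b}")
        if self.baseline_window[1] > self.cue_window[0] or self.cue_window[1] > self.task_window[0]:
            raise ValueError("windows must be disjoint and ordered baseline < cue < task")
        if self.rest_lead < 0:
            raise ValueError("rest_lead must be nonnegative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
            if n <= 0:
                raise ValueError(f"group {g!r} must have a positive trial count, got {n}")

    @property
    def t_start(self) -> float:
        return self.baseline_window[0] - self.rest_lead

    @property
    def t_stop(self) -> float:
        return self.task_window[1]

    @property
    def duration(self) -> float:
        """Total trial duration in seconds (19 s under defaults)."""
        return self.t_stop - self.t_start

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_trials(self) -> int:
        return sum(self.group_sizes.values())

    def time(self) -> np.ndarray:
        """Per-sample time in seconds relative to task onset; contains 0."""
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a half-open [start, end) window."""
        t = self.time()
        return (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)


@dataclass(frozen=True)
class Coupling:
    """A planted phase coupling between two ROIs in one band and group."""

    roi_i: str
    roi_j: str
    band: str
    group: str
    kappa: float

    def __post_init__(self) -> None:
        if self.roi_i == self.roi_j:
            raise ValueError("coupling requires two distinct ROIs")
        if self.kappa < 0:
            raise ValueError(f"von-Mises concentration kappa must be >= 0, got {self.kappa}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.roi_i, self.roi_j))

    @property
    def true_plv(self) -> float:
        """Planted phase-locking value, the Bessel ratio I1(kappa)/I0(kappa)."""
        return float(bessel_ratio_plv(self.kappa))


def bessel_ratio_plv(kappa: float) -> float:
    """Expected resultant length of a von-Mises distribution, I1(k)/I0(k)."""
    from scipy.special import i0e, i1e

    return float(i1e(kappa) / i0e(kappa))


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects: ERSP amplitude gains and pairwise phase couplings.

    Parameters
    ----------
    ersp_gain
        Map ``(roi_label, band_name, group) -> g`` with ``g > 0``; the
        oscillator amplitude in the task window is ``g`` times its
        baseline amplitude, so the implied true ERSP is ``g**2 - 1``.
        Unlisted cells default to g = 1 (no modulation).
    coupling
        Planted couplings, one entry per unordered ROI pair per
        (band, group).
    noise_level
        1/f noise standard deviation relative to the unit oscillator
        amplitude.
    freq_jitter
        Half-width (Hz) of the uniform per-trial carrier-frequency
        jitter shared within a coupled component.
    """

    ersp_gain: dict[tuple[str, str, str], float] = field(default_factory=dict)
    coupling: tuple[Coupling, ...] = ()
    noise_level: float = 0.3
    freq_jitter: float = 0.5

    def __post_init__(self) -> None:
        for (roi, band, group), g in self.ersp_gain.items():
            if g <= 0:
                raise ValueError(f"ersp gain must be > 0, got {g} for {(roi, band, group)}")
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} in ersp_gain")
        seen = set()
        for c in self.coupling:
            key = (c.pair, c.band, c.group)
            if key in seen:
                raise ValueError(f"duplicate coupling for pair {set(c.pair)} in {c.band}/{c.group}")
            seen.add(key)
            if c.group not in GROUPS:
                raise ValueError(f"unknown group {c.group!r} in coupling")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.freq_jitter < 0:
            raise ValueError("freq_jitter must be >= 0")

    def gain(self, roi: str, band: str, group: str) -> float:
        return self.ersp_gain.get((roi, band, group), 1.0)

    def couplings_for(self, band: str, group: str) -> list[Coupling]:
        return [c for c in self.coupling if c.band == band and c.group == group]


@dataclass
class TrialDataset:
    """Trials x ROIs x samples array with group labels and paradigm metadata."""

    data: np.ndarray
    group: np.ndarray
    time: np.ndarray
    sampling_rate: float
    atlas: AtlasSpec
    paradigm: ParadigmSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.group = np.asarray(self.group, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x ROIs x samples")
        if self.data.shape[1] != N_ROIS:
            raise ValueError(f"expected {N_ROIS} ROIs, got {self.data.shape[1]}")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length must match the sample axis")
        if self.data.shape[0] != self.group.size:
            raise ValueError("one group label per trial required")
        unknown = set(self.group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        counts = {g: int(np.sum(self.group == g)) for g in self.paradigm.group_sizes}
        if counts != self.paradigm.group_sizes:
            raise ValueError(
                f"trial counts {counts} do not match paradigm group sizes "
                f"{self.paradigm.group_sizes}"
            )
        if not (self.time.min() <= 0 <= self.time.max()):
            raise ValueError("time axis must contain the task-onset zero point")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def trial_indices(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return np.flatnonzero(self.group == group)

    def select_group(self, group: str) -> np.ndarray:
        """Trials of one group, as a trials x ROIs x samples view."""
        return self.data[self.trial_indices(group)]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise, rows independent; deterministic scaling."""
    n_bins = n_samples // 2 + 1
    spec = rng.standard_normal((*shape, n_bins)) + 1j * rng.standard_normal((*shape, n_bins))
    w = np.zeros(n_bins)
    w[1:] = 1.0 / np.sqrt(np.arange(1, n_bins))  # amplitude ~ f^(-1/2) => power ~ 1/f
    spec *= w
    x = scipy.fft.irfft(spec, n=n_samples, axis=-1)
    # analytic std of irfft of a complex-Gaussian spectrum with these weights
    scale = 2.0 * np.sqrt(np.sum(w**2)) / n_samples
    return x / scale


def _assign_phase_params(
    rng: np.random.Generator,
    atlas: AtlasSpec,
    couplings: list[Coupling],
    freq_jitter: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI carrier phase and frequency jitter for one trial and band.

    Coupled components share a latent phase and jitter; within a
    component the reference ROI (smallest atlas index) carries the
    latent phase exactly and every other ROI adds von-Mises jitter with
    the concentration of the coupling edge linking it toward the
    reference (breadth-first), so a disjoint planted pair attains
    exactly the Bessel-ratio PLV.
    """
    phi = rng.uniform(-np.pi, np.pi, size=N_ROIS)
    delta = rng.uniform(-freq_jitter, freq_jitter, size=N_ROIS)
    if not couplings:
        return phi, delta

    adj: dict[int, list[tuple[int, float]]] = {}
    for c in couplings:
        i, j = as_roi_indices(atlas, (c.roi_i, c.roi_j))
        adj.setdefault(i, []).append((j, c.kappa))
        adj.setdefault(j, []).append((i, c.kappa))

    visited: set[int] = set()
    for root in sorted(adj):
        if root in visited:
            continue
        # BFS from the smallest-index ROI of the component
        visited.add(root)
        queue = [root]
        latent_phi, latent_delta = phi[root], delta[root]
        while queue:
            u = queue.pop(0)
            for v, kappa in adj[u]:
                if v in visited:
                    continue
                visited.add(v)
                jitter = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
                phi[v] = latent_phi + jitter
                delta[v] = latent_delta
                queue.append(v)
    return phi, delta


def generate_dataset(
    paradigm: ParadigmSpec | None = None,
    atlas: AtlasSpec | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    dtype=np.float32,
) -> TrialDataset:
    """Generate a trial dataset with planted ERSP and PLV ground truth.

    Identical arguments and seed give bit-identical output.  Trials are
    ordered group-block-wise in ``paradigm.group_sizes`` order and are
    i.i.d. within group.
    """
    from .atlas import default_atlas

    paradigm = paradigm or ParadigmSpec()
    atlas = atlas or default_atlas()
    truth = truth or GroundTruth()
    for band in bands:
        band.check_nyquist(paradigm.sampling_rate)
        if truth.freq_jitter >= band.lo:
            raise ValueError("freq_jitter must be small compared to the band frequencies")
    # ground truth must refer to known ROIs/bands
    band_names = {b.name for b in bands}
    for roi, band_name, _ in truth.ersp_gain:
        atlas.index(roi)
        if band_name not in band_names:
            raise ValueError(f"ersp_gain refers to unknown band {band_name!r}")
    for c in truth.coupling:
        atlas.index(c.roi_i), atlas.index(c.roi_j)
        if c.band not in band_names:
            raise ValueError(f"coupling refers to unknown band {c.band!r}")

    rng = np.random.default_rng(seed)
    t = paradigm.time()
    n_samples = t.size
    task_mask = paradigm.window_mask(paradigm.task_window)

    groups_per_trial: list[str] = []
    for g, n in paradigm.group_sizes.items():
        groups_per_trial.extend([g] * n)
    n_trials = len(groups_per_trial)

    # per-(band, group) gain vectors and coupling lists, resolved once
    gain_vec = {
        (band.name, g): np.array(
            [truth.gain(lab, band.name, g) for lab in atlas.roi_labels], dtype=float
        )
        for band in bands
        for g in paradigm.group_sizes
    }
    coupl = {
        (band.name, g): truth.couplings_for(band.name, g)
        for band in bands
        for g in paradigm.group_sizes
    }

    data = np.empty((n_trials, N_ROIS, n_samples), dtype=dtype)
    for k, g in enumerate(groups_per_trial):
        x = np.zeros((N_ROIS, n_samples))
        for band in bands:
            phi, delta = _assign_phase_params(rng, atlas, coupl[band.name, g], truth.freq_jitter)
            osc = np.cos(
                2.0 * np.pi * (band.center + delta)[:, None] * t[None, :] + phi[:, None]
            )
            osc[:, task_mask] *= gain_vec[band.name, g][:, None]
            x += osc
        if truth.noise_level > 0:
            x += truth.noise_level * _pink_noise(rng, (N_ROIS,), n_samples)
        data[k] = x

    return TrialDataset(
        data=data,
        group=np.array(groups_per_trial, dtype=object),
        time=t,
        sampling_rate=paradigm.sampling_rate,
        atlas=atlas,
        paradigm=paradigm,
    )


def demo_ground_truth(
    atlas: AtlasSpec,
    ers_gain: float = 1.8,
    kappa: float = 5.0,
    n_hot_rois: int = 10,
    noise_level: float = 0.3,
    bands: tuple[str, ...] = ("alpha", "beta"),
) -> GroundTruth:
    """A study-flavoured ground truth for demos and recovery checks.

    Plants strong ERS in occipital/visual parcels (the dominant
    activation during visual-strategy motor imagery) in every group,
    extra ERS in the induced groups, and alpha-band phase coupling among
    frontal and cingulate parcels (a "cold hub" substrate) in all groups.
    """
    visual = atlas.rois_in_system("visual")[:n_hot_rois]
    frontal = atlas.rois_in_system("frontoparietal")[:4] + atlas.rois_in_system(
        "cinguloopercular"
    )[:2]
    gains: dict[tuple[str, str, str], float] = {}
    for roi in visual:
        for band in bands:
            for group in GROUPS:
                boost = 1.1 if group != "CG" else 1.0
                gains[(roi, band, group)] = ers_gain * boost
    couplings = [
        Coupling(a, b, "alpha", group, kappa)
        for ai, a in enumerate(frontal)
        for b in frontal[ai + 1 :]
        for group in GROUPS
    ]
    return GroundTruth(
        ersp_gain=gains, coupling=tuple(couplings), noise_level=noise_level
    )
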