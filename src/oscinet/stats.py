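"""Between-group inference on ROI activation.

Group differences in trial-level activation (baseline-normalised task
power, E_t/E_b - 1 per trial) are tested with a two-sided permutation
T-test: the pooled-variance two-sample t statistic is recomputed under
random relabelings of the pooled trials, and the p-value is the
add-one-smoothed fraction of permuted |t| at least as extreme as the
observed one,

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm),

so p is never exactly 0 and its resolution floor is 1/(n_perm + 1).
10,000 permutations are used by default.  Each family of 130 ROI tests
(per band, per group pair) is corrected with Benjamini-Hochberg FDR at
q <= 0.05, and effect sizes are reported as Hedges' g, the pooled-SD
standardised mean difference with the small-sample correction
J = 1 - 3 / (4 * (n_a + n_b) - 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasSpec

__all__ = [
    "permutation_ttest",
    "fdr_correct",
    "hedges_g",
    "compare_groups",
]

_PERM_CHUNK = 2000


def _t_stat(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Pooled-variance two-sample t from sufficient statistics (vectorised)."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    dof = n_a + n_b - 2
    s2 = (ss_a + ss_b) / dof
    denom = np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mean_a - mean_b) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _perm_pvalues(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed t and permutation p for each column of pooled (n x m)."""
    pooled = np.asarray(pooled, dtype=float)
    n, m = pooled.shape
    n_b = n - n_a
    sum_all = pooled.sum(axis=0)
    sumsq_all = (pooled**2).sum(axis=0)

    def t_for(rows_a: np.ndarray) -> np.ndarray:
        # rows_a: (k, n_a) index matrix selecting group a for k relabelings
        sel = pooled[rows_a]  # (k, n_a, m)
        sum_a = sel.sum(axis=1)
        sumsq_a = (sel**2).sum(axis=1)
        return _t_stat(sum_a, sumsq_a, n_a, sum_all - sum_a, sumsq_all - sumsq_a, n_b)

    t_obs = t_for(np.arange(n_a)[None, :])[0]
    exceed = np.zeros(m)
    done = 0
    while done < n_perm:
        k = min(_PERM_CHUNK, n_perm - done)
        perm = np.argsort(rng.random((k, n)), axis=1)[:, :n_a]
        t_perm = t_for(perm)
        exceed += (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        done += k
    p = (1.0 + exceed) / (1.0 + n_perm)
    return t_obs, p


def permutation_ttest(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Two-sided permutation T-test on two samples of per-trial values.

    Returns ``(t_obs, p_perm)``.  Degenerate input with zero pooled
    variance (all values identical) yields t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pooled = np.concatenate([a, b])[:, None]
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    t_obs, p = _perm_pvalues(pooled, a.size, n_perm, rng)
    return float(t_obs[0]), float(p[0])


def fdr_correct(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(qvals, mask)`` where ``qvals`` are the monotone adjusted
    values and ``mask`` flags q <= alpha.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, qvals <= alpha


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Hedges' g: bias-corrected standardised mean difference.

    g = J * (mean_a - mean_b) / s_pooled with
    J = 1 - 3 / (4 * (n_a + n_b) - 9), appropriate for small samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("both samples need at least 2 observations")
    s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if s2 <= 0:
        raise ValueError("zero pooled variance; Hedges' g is undefined")
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(s2))


def compare_groups(
    trial_activation: dict[tuple[str, str], np.ndarray],
    atlas: AtlasSpec,
    pairs: tuple[tuple[str, str], ...] = (("M-AIG", "CG"), ("F-AIG", "CG"), ("M-AIG", "F-AIG")),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise group comparison of per-trial ROI activation, per band.

    Parameters
    ----------
    trial_activation
        Map ``(band, group) -> (n_trials x n_ROIs)`` activation values.
    pairs
        Ordered group pairs ``(a, b)``; positive t and g mean stronger
        activation in ``a``.

    One row per (ROI, band, pair); FDR is applied within each
    (band, pair) family of 130 ROI tests.  Seeded and reproducible:
    every family consumes an independent stream spawned from ``seed``.
    """
    bands = sorted({band for band, _ in trial_activation})
    groups = {g for _, g in trial_activation}
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise KeyError(f"pair ({a!r}, {b!r}) refers to a group without activation values")

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    streams = ss.spawn(len(bands) * len(pairs))
    rows = []
    k = 0
    for band in bands:
        for (ga, gb) in pairs:
            va = np.asarray(trial_activation[(band, ga)], dtype=float)
            vb = np.asarray(trial_activation[(band, gb)], dtype=float)
            rng = np.random.default_rng(streams[k])
            k += 1
            pooled = np.concatenate([va, vb], axis=0)
            t_obs, p = _perm_pvalues(pooled, va.shape[0], n_perm, rng)
            # constant columns: define p = 1, t = 0
            const = np.ptp(pooled, axis=0) == 0
            t_obs[const], p[const] = 0.0, 1.0
            q, sig = fdr_correct(p, alpha=alpha)
            g_eff = np.array(
                [
                    hedges_g(va[:, r], vb[:, r]) if not const[r] else 0.0
                    for r in range(va.shape[1])
                ]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "roi": atlas.roi_labels,
                        "system": atlas.system,
                        "band": band,
                        "pair": f"{ga}:{gb}",
                        "t_obs": t_obs,
                        "p_perm": p,
                        "q": q,
                        "significant": sig,
                        "g": g_eff,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
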