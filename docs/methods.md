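# Methods

This note documents the models, estimators and numerical choices behind
`oscinet`, and what the synthetic-data tests do and do not establish
about real recordings.

## Scope and data model

The pipeline begins at source-reconstructed ROI time series: a
`TrialDataset` holding a `trials × 130 ROIs × samples` array, per-trial
group labels (`CG`, `M-AIG`, `F-AIG`), a time axis in seconds relative
to task (imagery) onset, and paradigm metadata. Everything upstream —
sensor recordings, artifact removal, source reconstruction, atlas
registration — is out of scope; real data enter through the same
HDF5/NPZ container the generator writes (`/data`, `/time`, `/group`,
`/atlas/*`, paradigm attributes).

The default paradigm is a 19 s trial: 6 s rest (the final 2 s, −5..−3 s,
serve as baseline, keeping visual-transient interference out of it),
3 s cue (−3..0 s), 10 s task (0..10 s), sampled at 1200 Hz, with
40/20/20 trials in CG/M-AIG/F-AIG (80 total). Windows are half-open
`[start, end)` on the sample grid; the t = 0 sample belongs to the task
window. Trials are i.i.d. within group — no subject- or block-level
nesting (see Limitations).

The packaged atlas is a *synthetic stand-in*: 65 plausible gyral/sulcal
region names mirrored over both hemispheres and assigned to 8 functional
systems (frontoparietal, attention, motor/somatosensory,
cinguloopercular, visual, medial default mode, ventral temporal
association, auditory). Analyses of real data should construct an
`AtlasSpec` from their own parcellation's labels.

## Synthetic signal model

Per ROI and trial the generator sums one oscillator per band plus
broadband noise:

```
x(t) = Σ_bands env_b(t) · cos(2π (f_b + δ) t + φ) + σ · n_1/f(t)
```

* `f_b` is the band-center carrier (alpha 10.5 Hz, beta 21.5 Hz).
* `δ` is a per-trial uniform frequency jitter (default half-width
  0.5 Hz). Real oscillation peaks wander from trial to trial; the
  jitter also dephases *uncoupled* ROI pairs across the 10 s task
  window, so their across-trial resultant decorrelates over time and
  the time-averaged PLV chance floor concentrates at its mean
  `E[R_n] ≈ √π/(2√n)` instead of having the heavy Rayleigh tail a
  fixed-frequency model would produce. Without this the shared
  threshold (twice the mean PLV) would admit hundreds of spurious
  edges at n = 20 trials/group.
* `env_b(t)` is 1 outside the task window and the planted amplitude
  gain `g` inside it, so the planted true ERSP is `g² − 1` (power is
  amplitude squared).
* Phase coupling: each connected component of planted couplings shares
  a latent per-trial phase *and* frequency jitter. The component's
  reference ROI (smallest atlas index) carries the latent phase
  exactly; every other ROI adds von-Mises jitter with the concentration
  κ of the edge linking it toward the reference (breadth-first). A
  disjoint planted pair therefore attains exactly
  `PLV = I₁(κ)/I₀(κ)`; in a clique, pairs not involving the reference
  attain the square of that ratio (both still far above the floor for
  the κ used in tests). Symmetric jitter on both partners would square
  the Bessel ratio for every pair, which is why one side stays exact.
* `n_1/f` is unit-variance 1/f ("pink") noise, synthesized in the
  frequency domain with an analytic normalization (no per-realization
  rescaling, so samples stay exactly Gaussian); `σ = noise_level`
  (default 0.3) is relative to the unit oscillator amplitude.

Identical `(paradigm, atlas, truth, seed)` give bit-identical arrays.

What the generator does **not** emulate: subject-level random effects
and inter-subject variability, block structure, non-sinusoidal waveform
shape, amplitude dynamics within windows, artifacts (blinks, EMG,
unconscious swallows), spatial leakage between parcels, and
band-limited noise correlations between ROIs. Passing recovery tests
therefore show that the estimators are correct and calibrated under the
stated trial-exchangeable model — not that the pipeline is robust to
source-leakage or nested designs in real MEG.

## Spectral analysis (ERSP)

Morlet wavelets on a 1 Hz grid spanning 8–29 Hz with `max(3, f/2)`
cycles per frequency; coefficients come from
`mne.time_frequency.tfr_array_morlet` (the `morlet_tfr` wrapper), or —
in the streaming path used by `group_ersp` — from a batched FFT
convolution with the identical MNE wavelets, which never materialises
the 4-D coefficient array (memory stays at one frequency slab) and is
asserted equal to MNE in the test suite.

Band power is the mean `|coefficient|²` over the band's frequencies and
a window's samples. Samples within half a wavelet width
(`cycles/f/2`, e.g. 0.25 s at 8 Hz) of a window border are excluded to
avoid edge bias. Powers are averaged across trials per group *before*
the ERSP ratio (one ERSP per ROI/band/group); per-trial
baseline-normalised activation `E_t/E_b − 1` is retained separately as
the trial-level quantity the permutation test operates on. A
non-positive baseline power raises an error rather than producing
infinities. The ERSP lower bound is −1 by construction.

Broadband noise adds equally to task and baseline band power, so the
recovered ERSP of a planted gain is slightly diluted toward 0 (e.g.
~2.9 observed for a true 3 at `noise_level = 0.3`); ranking-based
conclusions (hot spots) are unaffected.

## Connectivity (PLV) and the shared threshold

The phase of an ROI is the argument of its Morlet coefficient at the
band-center frequency — invariant to amplitude scaling; a
bandpass-plus-Hilbert analytic-signal estimate serves as the
independent oracle in tests. The PLV estimator pools the phase
difference *across trials* at each task-window sample (the paradigm
randomises trial phases, so consistency across trials is the
signature of coupling) and averages the resultant length over samples.
A within-trial variant is intentionally not offered as the default
because trial-varying phase is what this paradigm randomises. Two
trials minimum; the diagonal is excluded from every mean and edge set.

The three group matrices (per band) share one threshold,
`2 × (mean_M + mean_F + mean_CG)/3`, computed from off-diagonal means.
Per-band thresholds are used (matrices are band-specific). The formula
can exceed the PLV ceiling of 1; this is allowed, logged as a warning
and yields empty networks rather than an error. Edges require PLV
*strictly greater* than the threshold.

## Networks and node classification

Graphs are undirected and weighted (edge weight = PLV), always contain
all 130 nodes, and never contain self-loops. Weighted degree is the
sum of incident edge weights (0 for isolated nodes). Eigenvector
centrality is computed by power iteration on the full, possibly
disconnected adjacency (tolerance 1e−10 on the iterate change, max
10,000 iterations, error on non-convergence), with a small diagonal
shift (1e−2 × max row sum) that leaves eigenvectors unchanged but
breaks the ±λ tie of bipartite components; the result is
max-normalised to [0, 1]. Values below 1e−9 of the maximum are set to
exactly 0: they are numerical residue on nodes outside the dominant
component. Agreement with a dense eigensolver is enforced to 1e−8 in
tests.

Hot spots are the top `floor(0.2 × N)` nodes (26 of 130) by signed
ERSP, descending — "strongly activated" means strongest ERS first.
Hubs are the same number of top-centrality nodes, except that
zero-centrality nodes are never hubs (an edgeless network reports 26
hot spots and 0 hubs; a sparse network's hub set may be smaller than
26). Ties break by atlas order for determinism. Classification is per
network (per band and group), crossing the two memberships into
hot hubs, non-hub hot spots, cold hubs and non-hub cold nodes — always
a partition of the 130 nodes. Classification depends only on the two
rankings (invariant to monotone transforms).

## Statistics

The test statistic is the pooled-variance two-sample t on per-trial
baseline-normalised activation. ERSP itself is a group-level ratio, so
the trial-level surrogate is what makes label permutation well defined;
trials are the exchangeable units. Two-sided testing (inhibitions are
as relevant as activations). The permutation p-value uses the add-one
estimator `p = (1 + #{|t_perm| ≥ |t_obs|})/(1 + n_perm)` — never 0,
resolution floor `1/(n_perm+1)`; 10,000 permutations by default.
All-identical pooled data define `t = 0, p = 1`. FDR correction is
Benjamini–Hochberg (via statsmodels) applied within each family of 130
ROI tests per (band, group-pair); Hedges' g uses the small-sample
correction `J = 1 − 3/(4(n_a+n_b) − 9)` (J = 1 − 3/151 ≈ 0.9801 at
20/20). Every family consumes an independent stream spawned from the
master seed, so results are reproducible and order-independent.

## Pipeline, configuration, provenance

`run_pipeline` executes simulate/load → ERSP → PLV → threshold →
networks → classification → comparisons from one `PipelineConfig`
(YAML-serialisable). All randomness derives from a single master seed
via named SHA-256 sub-seeds (`simulate`, `stats`), and the manifest
records the config hash, sub-seeds, thresholds and package version;
rerunning the same config reproduces every table bit-identically.
Outputs: tidy CSVs (ERSP, node attributes, comparisons), a long-format
edge TSV, square PLV CSVs, Pajek NET graphs (the hand-off point for
layout tools), and `manifest.json`.

## Problem sizes used in tests and acceptance runs

The package's own test policy: unit tests run a structurally complete
but shortened paradigm (6 s trials at 128 Hz, 8/6/6 trials); design
constants are checked on the full default paradigm (19 s, 1200 Hz,
40/20/20); PLV calibration uses 19 s trials at 256 Hz with 40 CG trials
over 10 seeds against Monte-Carlo oracles; statistical calibration uses
1000 null replicates with 999 permutations and 300 mixed-simulation
replicates; end-to-end recovery runs the full pipeline at 128 Hz
(alpha band, 40/20/20 trials) over 10 seeds. These sizes keep each
stage's Monte-Carlo error well inside the asserted bands.

## Limitations

* Trial exchangeability within groups is assumed throughout; with 12
  subjects pooled per group in the motivating design, subject-level
  dependence would widen real error bars relative to the calibrated
  ones here.
* The mean PLV entering the threshold is taken over *all* off-diagonal
  pairs (not only supra-chance pairs); with mostly uncoupled data the
  threshold sits near twice the chance floor and scales with trial
  counts.
* No directed or lagged connectivity (PLI, coherence, Granger), no
  community/efficiency graph metrics, and no figure rendering — the
  Pajek export is the boundary.
* PLV recovered through the Morlet phase is mildly biased downward by
  broadband noise (phase wobble); calibration tests quantify this at
  the default noise level and it is negligible for κ ≥ 2 effects.
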