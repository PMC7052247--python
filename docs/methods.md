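# Methods

## Vocal-tract model

The area function is the product of a squared vowel substrate and one
occlusion factor per plosive,

    A(x,t) = (π/4) [Ω(x) + q1(t)φ1(x) + q2(t)φ2(x)]² · Πk [1 − c_k(x) m(t−t_k)],

evaluated on a 101-point spatial grid over `L = 17.5` cm with a 1-ms time
step. The empirical profiles `Ω, φ1, φ2` come from orthogonal
decompositions of MRI anatomy in the literature and are not
redistributable; the package ships a **synthetic parametric stand-in**
(`data/default_tract.csv`): `Ω(x) = 1.5 + 0.4 sin(πx/L)` cm,
`φ1 = cos(πx/L)`, `φ2 = cos(2πx/L)`. Users with empirical tables can load
them with `tract_model.load_geometry`.

Gesture conventions:

* `m(t)` — raised-cosine activation of total width `w = 120` ms centred on
  the closure time (the data constrain only that it peaks at 1; a
  symmetric window was chosen; an asymmetric activation/deactivation split
  is a known open point).
* `c_k(x)` — Gaussian bump, half-width `σ = 1` cm, unit at the occlusion
  place. Places: bilabial at `L`, alveolar at `0.85 L`, velar at `0.60 L`,
  shared by each voiced/unvoiced pair. `c·m` is clamped to ≤ 1 so every
  factor, and hence the area, stays non-negative; closures on grid points
  are exact zeros.
* `q1, q2` evolve linearly from 0 (neutral) to the vowel target over the
  utterance duration `T = 490` ms (the mean measured CCV duration; the
  per-trial clock is in seconds throughout).

The vowel targets of the packaged configuration are `q1 = 0.48`,
`q2 = 0.38`. Under the effort functional below, the marginal cost of a
closure decreases as the vowel carries that place further from neutral
(the deviation `|A − A_Ω|` is capped at `A_Ω` once the tube is shut, so a
closure partially overwrites whatever deviation is already there). The
targets are therefore chosen so that the vowel's displacement magnitude
at the three closure places is ordered labial < alveolar < velar, which
realizes the observed place asymmetry — `E(bda) < E(dba)`,
`E(bga) < E(gba)`, `E(dga) < E(gda)`: interchanging the consonants so
that the closure nearer the mouth happens later always costs more. This
is a deliberate calibration of a stand-in geometry to the qualitative
anatomy, not a fit to any measured effort value.

## Effort functional

`E = E0 + ∫∫ |A − A_Ω| dx dt` with trapezoidal quadrature on both axes
(second order; halving both steps moves the default-gesture integral by
< 0.1%, and a 10× midpoint refinement agrees within 0.5%). The first
closure sits at `t1 = 100` ms; only the inter-closure interval `Δt`
matters for the comparisons, and the default `Δt = 200` ms equals the mean
measured transition. A sweep over `Δt = 100–300` ms in 25-ms steps covers
the plausible gesture overlaps; the effort–τ′ rank correlation is positive
at every interval.

`E0`, the laryngeal devoicing cost, has no published value. The default is
**calibrated**, not measured: it solves
`mean(E_devoiced) = (41.3 / 38.2) · mean(E_voiced)` over the 15 analysis
CCVs, i.e. the devoiced/voiced effort ratio is set to the measured ratio
of the group mean normalized transitions. Any positive `E0` preserves all
sign-level conclusions; `effort.EffortConfig(E0_value=...)` overrides it.

## Acoustic landmarks

All timing comes from zero-phase band-limited energy envelopes (4th-order
Butterworth, forward-backward, so estimates carry no filter delay):

* vocal onset — first sustained (≥ 30 ms) crossing of an adaptive
  threshold on the 75–300 Hz envelope (fundamental-frequency band) for
  voiced initials, or the 1–8 kHz band for fricative initials. The noise
  floor is the 10th envelope percentile; the threshold is the floor plus
  25% of the dynamic range (or 4× the floor, whichever is larger).
* release bursts — peaks of the 1–8 kHz envelope (5-ms smoothing, ≥ 30 ms
  separation, height ≥ 25% of the strongest burst).
* fricative spots — sustained (≥ 50 ms) supra-threshold broadband noise.

Transition rules per cluster type: plosive-plosive, first release to
second release; plosive-fricative, burst to noise-spot start;
fricative-plosive, noise-spot end to burst; fricative-fricative has no
rule and is rejected. `τ′ = τ/T` is invariant to time-stretching within
1%, which is the point of the normalization. Against the generator's
planted landmarks the detector recovers τ within ±5 ms at 30 dB SNR and
≥ 95% within ±10 ms at 20 dB. Real spectrogram annotation criteria are
not published, so the detector is validated only against synthesis;
mispronunciation and multi-attempt screening are metadata inputs, as in
manual screening.

## Gaze measures

Screens hold 6 three-character CCVs in a 24 px/character monospaced
layout with 4-space gaps, centred on a 1024×768 display. AOI boxes extend
the character box by one space width (24 px) horizontally and ±1° (24 px)
vertically; the central 48 px of each gap stays unassigned, so gap
fixations count for no item. Per AOI: FFD is the first fixation's
duration; FPRT sums fixations from first entry until any *other* AOI is
fixated (unassigned fixations do not end the first pass); TFT sums all
fixations on the AOI. A first fixation straddling stimulus onset is
clipped to the onset. The first and last CCVs of each screen are
discarded (edge effects), retaining 4/6 of presentations. First-pass
order is assumed for the first fixation (the standard definition); the
alternative is noted as a sensitivity point.

## Lip dynamics

Envelopes are centred 140-ms moving averages of |acceleration| with
shrink-at-edges (constants map to themselves). Traces align at the vocal
onset (oral block) or at their maximum (both blocks; earliest maximum on
ties, with a warning). The oral/silent comparison is the ratio of median
aligned-peak magnitudes — medians for robustness, means also derivable —
and only ratios are meaningful because accelerometer units are
uncalibrated. Clustering silent readers into "low" vs "null" activity
subgroups is out of scope (no criterion exists), though the generator can
emit both.

## Quality control

Cascade order: (1) participants with > 45% mispronounced CCVs (strict
inequality, computed over oral trials) are removed from both blocks;
(2) unfixated, mispronounced, and multi-attempt trials are dropped;
(3) a **single-pass** outlier filter removes any trial with FFD, FPRT,
TFT, Δ or τ′ outside the participant's own `x̄ ± 2s` band (sample SD,
n−1; bounds from the pre-removal data; zero-SD bands remove nothing;
variables with < 3 values per participant are skipped with a warning).
Intra-word frequency bins: low (f ≤ 10), medium (10 < f ≤ 50), high
(f > 50) — boundary values to the lower bin, and no packaged CCV sits on
a boundary. The packaged frequency table is synthetic (corpus mining is
out of scope): plosive-plosive clusters homogeneously low with *bta*
high and *dta*/*gta* medium, fricative-containing clusters higher and
more variable.

## Statistics

Two-sided tests throughout, α = 0.01 (chosen once to compensate for
multiple comparisons; no further correction). OLS with per-coefficient t
tests (residual df = n − p − 1); the cross-block regressions are WLS over
per-CCV aggregates with weights `1/SEM(y)²` — the SEM of the dependent
(ocular) variable; with 15 CCVs the slope test has df = 13, and equal
weights reduce the fit to OLS exactly. The voicing contrast is a
pooled-variance t test (df = n1 + n2 − 2); frequency effects use one-way
ANOVA. No mixed-effects modelling. The pipeline reports its own dfs,
which depend on the post-QC trial counts.

## Synthetic generator: what it emulates and what it does not

The generator reproduces the design arithmetic exactly (72-CCV
inventory; 15 voiced-initial plosive-plosive CCVs × 3 repetitions plus
57 fillers shown twice or three times — 21 of them three times, one
valid tiling of the stated 135 — giving 180 stimuli per block, 10 800
trials for 30 subjects, 7 200 after edge discard) and the measured group
structure of τ′: per-CCV means 0.373 (bda, bga, dga), 0.390 (dba, gba,
gda) and 0.413 (devoiced), assigned uniformly within subgroup because
per-CCV means are unpublished — users with the deposited data can refit
the calibration file. The trial-level τ′ SD is 0.065, a compromise
back-solve from the published group standard errors (±0.007 at the
subgroup n gives 0.083; ±0.003 at the full-group n gives 0.051–0.063).
`T ~ N(490, 50)` ms.

Couplings: `Δ = 0.25 + 0.50 τ′ + N(0, 0.15)` s on the trial's own τ′;
silent-block `FFD = −70 + 700 τ′_ccv + N(0, 40)` ms on the CCV's
calibrated mean (the articulatory code, not the oral realization), with
oral FFD at the matched 210-ms mean; FPRT and TFT add non-negative gap
draws whose means fall by 20 and 10 ms per repetition. The FFD coupling
strength is set so the cross-block regression's designed significance
survives the two attenuation channels a real analysis also faces —
errors-in-variables in the per-CCV τ′ means and trial loss to QC — while
keeping the implied FFD range across CCVs (≈ 28 ms) within what reading
studies report. Flag rates: 2% unfixated, 4% mispronounced, 1.5%
multi-attempt (no simulated over-threshold participants by default).

Not emulated: naturalistic audio (no formant synthesis — records carry
planted landmarks, buzz, and noise at a configurable SNR), saccade-level
gaze dynamics (fixation events are generated directly, in strict reading
order, and round-trip exactly through the measure definitions), skewed
reading-time distributions (draws are truncated Gaussians), corpus
frequencies, or participant-level heterogeneity in couplings. Passing
tests therefore demonstrate that the pipeline recovers planted structure
at realistic noise levels — not that real data contain that structure.
One realization subtlety: a re-read confined to the last fixated item of
a screen cannot be expressed as a separate pass (no later item ends its
first pass); the pipeline folds such re-reads (≈ 10⁻⁵ of screens) into
the first pass.

## Numerical and degenerate-case choices

Landmark ties break to the earliest time; detector thresholds all live in
`acoustic_timing.DetectorConfig`. τ = T is accepted with a warning;
negative Δ (voice before fixation) is returned and flagged downstream.
Effort integration errors are raised with the CCV label attached. All
generators are pure functions of (spec, seed); identical seeds give
byte-identical outputs, and every written table carries the seed and a
config hash in a header comment.

## Limitations

The geometry is a stand-in: absolute effort values are not comparable to
anatomically derived ones, and only sign/ordering claims are meaningful —
which is why the desk-scale checks assert the sign and significance
pattern rather than published correlation magnitudes on real data. The
replication entry point (`pipeline.replicate_deposited`) expects the
published dataset converted to the package's trial-table contract and is
exercised here only on synthetic tables.
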