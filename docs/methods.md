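# Methods

`remcortex` analyzes sleep-state-dependent global cortical dynamics in
mesoscale widefield Ca²⁺ imaging, together with the polysomnography
(EEG/EMG), pontine LFP, behavior traces and optogenetic trial schedules
recorded alongside it. Because suitable in-vivo recordings are rarely
shareable, the package ships a synthetic-session generator whose output has
the statistical structure every downstream stage assumes; all quantitative
tests are parameter-recovery tests against that generator's ground truth.

## Synthetic sessions

**Hypnogram.** Brain states (Wake/NREM/REM) are simulated directly on the
5-s scoring grid as a discretized semi-Markov chain: each state has a mean
bout duration `m` and exit weights, and the per-epoch exit hazard is
`1 − exp(−5/m)`, giving geometric (discretized-exponential) bout lengths.
REM is entered only from NREM and exits to Wake — transitions from Wake
directly into REM do not occur in healthy rodents. Defaults (Wake 54 s,
NREM 130 s, REM 80 s, NREM→REM weight 0.2) put the stationary occupancy at
Wake 27 %, NREM 65 %, REM 8 %, the canonical light-phase budget for
habituated head-fixed mice. Simulating on the epoch grid makes the
optogenetic manipulation exact: during laser-on epochs the NREM→REM branch
hazard is multiplied by a configurable factor (< 1 silencing, > 1
activation) and nothing else changes.

**Polysomnography.** EEG is a sum of 4th-order-Butterworth band-limited
noise components (δ 0.5–4, θ 6–10, σ 9–17 Hz) with per-state SDs: δ
dominates NREM, θ dominates REM, and the EMG (broadband noise) RMS is high
in Wake and low in sleep. Sigma amplitude in NREM is modulated by an
infra-slow 0.02-Hz sinusoid (the period is a modeling choice; reports of
the phenomenon give no standard number). Within REM, θ amplitude is
modulated (bounded to [0.5, 1.5]×) by a slow shared "REM drive" that also
feeds the occipital pattern coefficient, creating the within-REM coupling
between θ/δ and occipital activation that the correlation analysis
measures. The pontine LFP is a clipped-Gaussian noise floor (±3.5 SD; a
bounded background so that detector exactness is well-defined) plus large
negative deflections (P-waves; default 9× baseline SD, 15-ms width, 12/min)
at Poisson times inside REM bouts, away from bout edges.

**Movie.** `movie(t) = F₀ · bleach(t) · (1 + Σₖ cₖ(t)·mapₖ + g(t) + ε)`.
Two orthonormal planted maps over a nine-region elliptical atlas (MOs, MOp,
SSb, SSu, SSl, VISp, VISs, RSPd, RSPl): an occipital map (VIS + RSP) and a
somatomotor map (MO + SS). The occipital coefficient is high in REM,
oscillates in anti-phase with the somatomotor coefficient during NREM (in
phase with the sigma modulation), and ramps up linearly over the final 20 s
of NREM before each NREM→REM transition. Transient Gaussian events
(σ = 0.9 s) occur at Poisson times; during REM each occipital event follows
a planted P-wave by 0.9 s. Bleaching is a two-term exponential, `g(t)` a
low-pass shared global signal, `ε` white pixel noise, and the baseline image
carries dark curvilinear vessel streaks. Behavior traces: facial motion
energy high in Wake and bursty in a contiguous phasic block covering 30 % of
each REM bout; a smooth horizontal eye trace with saccade bumps co-timed
with REM occipital events.

One master seed feeds independent named substreams per signal, so e.g.
changing the pixel noise never changes the hypnogram; identical configs give
bit-identical output.

## Preprocessing

Fixed order: bleaching correction (fit `a₁e^{−t/τ₁}+a₂e^{−t/τ₂}+c` to the
per-frame mean and divide it out; non-convergence falls back to identity
with a warning) → ΔF/F₀ with F₀ the per-pixel mean over **all** frames →
vessel mask → global signal removal. GSR regresses every pixel trace on the
spatial mean over analyzable pixels (intercept included) and keeps the
residual; by the normal equations the residuals are exactly uncorrelated
with the removed trace, which the tests assert at 1e-10. The vessel mask
uses Sato Hessian-eigenvalue ridge enhancement of dark structures at scales
{1, 2, 3} px with a local-mean + `(1 − sensitivity)`·SD threshold, so the
mask grows monotonically with sensitivity (default 0.5). Atlas alignment is
a similarity transform (centroid + area-ratio scale with a small translation
refinement) of the reference map onto the binarized brain outline — an
elastic registration is out of scope here — and fails loudly when the
outline overlap (Jaccard) is below 0.5 or a region vanishes.

## Sleep scoring

Per 5-s epoch the EEG spectrum is computed by FFT zero-padded to a 0.18-Hz
grid, and band powers are half-open sums. The scoring cascade replaces a
semi-automatic manual workflow with a deterministic rule: EMG-RMS z-score
(per recording) above 0.5 ⇒ Wake; else θ/δ power ratio above 1 ⇒ REM; else
NREM. Ties go to the lower-arousal branch; a width-3 majority filter
removes single-epoch flickers. Substates: phasic REM (active wake) are REM
(Wake) epochs with above-average facial motion; microarousals are NREM
spans with EMG z above 1.0 lasting at most 15 s. These thresholds are
calibrated only on the synthetic generator — real recordings will need
recalibration, which is why they live in `ScoreConfig`.

## Pattern analysis

The 16×16 grid correlation uses mean ΔF/F₀ patch traces (patch size scales
with the image) restricted to one state's frames; clustering is
average-linkage agglomerative on `1 − corr(matrix rows)`, cut by requested
group count (default 2; a distance threshold is exposed as an alternative,
since absolute dendrogram distances are toolbox-specific), with groups under
4 patches merged into the most-correlated neighbor. PCA runs on the
(frames × analyzable pixels) matrix, optionally temporally decimated for
whole-recording runs and never decimated for REM-only runs; maps are
inpainted over the vessel mask by iterative neighborhood diffusion (a
deterministic stand-in for patch-based inpainting, adequate for thin vessel
strips), smoothed 5×5, brain-masked, and sign-fixed so a positive
coefficient means a fluorescence increase. PC events: 5-Hz coefficients,
20-s moving-average baseline, candidate local maxima above 1 SD of the
residual (global SD — the residual is near-stationary), ±2-s windows with
the larger peak winning overlaps, and a Gaussian fit whose σ is the event
half-width. The moving-average window is forced odd so the detector matches
a symmetric brute-force oracle sample for sample.

## REM-like dynamics

The REM template is the first PC of REM-only frames; its frame-wise Pearson
correlation (cc) labels frames REM-like (> +0.4) or REM-opponent (< −0.4),
strictly, so ±0.4 exactly is neutral. NREM periods: preREM/NR2 is the 20 s
immediately before a NREM→REM transition, NR1 the 20 s before that, NW1/NW2
the analogous windows before NREM→Wake, NREM1..4 equal bout quarters — the
20-s window extrapolates the preREM definition since only diagrams define
the others. Windows leaving NREM are skipped and counted. The preREM
time course (1-s bins averaged over transitions) gets a linear fit (slope,
Pearson r). P-waves: negative LFP peaks beyond 4× the REM-restricted SD,
≥100 ms apart; event-triggered averages align the template *coefficient*
projection (linear in the data, unlike the bounded cc) with per-recording
z-scoring before any cross-recording averaging. The sigma cross-correlogram
z-scores per qualifying NREM bout (≥120 s, microarousal-free, selected by
the automated microarousal rule) and pools lagged pairs across bouts;
smoothing of cc uses a centered 10-s window (centered vs causal was an open
choice; centered keeps zero lag interpretable).

## Optogenetic trial analysis

Trials are aligned on the 5-s grid over [−300 s, +2·duration). Transition
probabilities are y/x per ordered state pair and bin; bins with x = 0 are
undefined and excluded from the 12-bin (60-s) bars and from the 300-s
pre-laser baseline mean, rather than treated as zero. Per-trial
measurements are % time in a state during the 2-min stimulation vs the 2 min
immediately before onset. Inference is a hierarchical bootstrap honoring
the trials-within-mouse nesting: each iteration redraws mᵢ trials per mouse
with replacement (the same resampled trials feed the paired laser and
baseline values), averages within mouse and then across mice; 100,000
iterations give the percentile CI, and the two-sided p-value is
`2·min(tail fractions)` of the laser-minus-baseline distribution with a +1
continuity guard, so p ≥ 1/iterations and is never zero. Under a Gaussian
null the measured type-I error at nominal 0.05 is ≈ 0.057 (slightly
anticonservative, as expected for a percentile bootstrap with 5 subjects).
The EEG-spectrum comparison trims 10 s off both ends of every state bout
(bouts ≤ 20 s vanish), normalizes each condition's mean spectrum by its
0.5–18-Hz mean, and reports a Wilcoxon signed-rank statistic across in-band
frequency bins.

## Problem sizes and numerical choices

Tests and the acceptance script run 30-min 64×64 movies (the pattern/REM
analyses), 3-h trace-only sessions (scoring, transition and bootstrap
analyses, where no movie is needed), and 5-mice × 5-session designs for the
optogenetic power checks; these sizes keep a full run on one CPU in a few
minutes while leaving every estimate comfortably determined. The
acceptance script scans derived seeds for a 30-min hypnogram containing at
least two ≥30-s REM bouts before running the movie chain — a property of
the hypnogram only, decided before any analysis runs. GSR residuals are
kept in float64 so the orthogonality identity holds to 1e-10; movies are
float32. PCA uses scikit-learn's SVD (deterministic `random_state` when the
randomized solver engages). Degenerate inputs are defined, not crashed:
zero-variance frames get cc = 0/neutral, a constant correlation matrix
yields one flagged cluster, an all-equal regional profile z-scores to 0,
and a failed Gaussian event fit keeps the event with a missing width.

## What passing tests do and do not show

The generator reproduces the *structure* the analyses assume — state-
dependent band powers, planted spatial patterns, event timing and hazards —
but not real data's nonstationarity, hemodynamic contamination (no 405-nm
correction channel is modeled), movement artifacts, electrode drift, or
inter-animal variability beyond seed-to-seed differences. Parameter
recovery here therefore validates the implementation, not the biology;
thresholds (scoring cascade, ±0.4 cc, 1-SD events) transfer to real data
only after recalibration.
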