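# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `replicount`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Focus detection and intensity traces

Frames are aligned to the first frame at integer-pixel resolution by
maximizing circular cross-correlation (sub-pixel registration is
deliberately off: focus positions are refined sub-pixel later, and
integer shifts avoid interpolating intensities that will be summed in
3-px disks). The summed image (per-pixel sum over frames, 1-px Gaussian
blur) is watershed-partitioned around its local maxima, restricted to the
cell masks; cell segmentation itself is out of scope and masks are an
input. Up to four foci per cell are fit, brightest region first, with a
symmetric 2-D Gaussian over the union of the intensity region and a
3-px disk at the peak, intersected with a 17×17 window — a single
Gaussian fit over a whole elongated cell tracks the cell outline rather
than the spot. Ellipticity comes from a rotated elliptical-Gaussian refit
restricted to the spot core (radius 4.5 px) for the same reason; the QC
threshold is ellipticity > 1.2.

Per frame, the raw focus intensity `I_R` sums a 3-px-radius disk at the
(fixed) fitted position; the per-pixel cell background `I_B` and its
standard deviation `δI` are computed over the cell with every focus
excised (3-px mask radius); the focus intensity is `I_F = I_R − A_M·I_B`
and the score is `σ = I_A/(δI·√A_M)`. Two area conventions exist: the
printed formulas use the continuous `A_M = πr² ≈ 28.27`, while the pixel
disk at r = 3 contains 29 pixels. They differ by < 3% in the score; the
`area` argument of `extract_trace` selects the convention (`continuous`
default; `pixel` makes `I_F` exactly invariant under a constant image
offset). Coordinates are 0-based `(row, col)` with pixel centers at
integers.

The mid-cell "replication factory" localization rule is a configurable
band covering the central 50% of the cell's extent along its major axis.
No quantitative rule is published for this criterion; the band fraction
is exposed, not hard-coded.

## Change-point idealization

Bleaching traces are idealized by recursive binary segmentation. On each
segment the test statistic is the generalized log-likelihood ratio for a
single change in a Gaussian sequence with *segment-local variances*
(bleaching traces are strongly heteroscedastic: the variance is roughly
linear in intensity):

    LLR(c) = (n/2)·log v − (c/2)·log v_L − ((n−c)/2)·log v_R .

The statistic is location/scale invariant, so critical values depend only
on segment length and are calibrated once by Monte Carlo: for each length
on a grid, the 95th percentile of the max-LLR over splits of i.i.d.
Gaussian segments (log-length interpolation in between; lengths outside
the grid clamp). Because children of a rejected root are never tested,
the per-trace family-wise false-positive rate equals the root test's
level: ~5% of constant-mean traces gain at least one spurious level,
which the acceptance script verifies on 10,000 fresh nulls. Minimum level
duration is 2 frames (a 1-frame level has no variance estimate); ties in
the LLR break to the earliest frame.

The comparison baseline (`idealize_kv`) is greedy binary segmentation
under a global constant variance, accepting a split iff the Bayes
Information Criterion drops: `BIC = n·log(RSS/n) + (k+2)·log n` for k
change points, i.e. one parameter per added step, with steps admissible
anywhere including 1-frame levels. On 120-frame null traces this
criterion keeps a single level only ~55–58% of the time — the
over-segmentation that motivates the calibrated filter. (Counting two
parameters per step instead would raise one-state recovery to ~95% and
is inconsistent with the baseline's documented behaviour.)

Step-detection efficiency is measured as the fraction of *true steps*
matched by a detected change point within ±2 frames. A simulated
fluorophore whose exponential lifetime (mean 41 frames) exceeds the
120-frame window presents no transition and contributes no truth;
conditioning on the step occurring inside the window, efficiency at
Δµ/σ = 2.5 is ~90–91% (losses are steps shorter than ~2 frames or within
2 frames of the window end).

## Unitary step and copy number

The pairwise probability density distribution (PPDD) places one Gaussian
kernel per ordered level pair (i < j) at |mean_i − mean_j|, with width
√(u_i² + u_j²) from the Fisher information of the level means
(u = √(variance/duration)) and weight duration_i × duration_j — the
number of frame pairs straddling the two levels, so long-lived quiet
levels dominate and short noisy ones barely contribute. `pair_weight`
offers `min` and `sum` alternatives for sensitivity checks. Within-level
(zero-difference) pairs are excluded: including them adds a DC carrier
that selectively boosts half-frequency harmonics on noisy traces.

The power spectrum is the exact continuous Fourier transform of this
kernel mixture, `P(f) = |Σ w_k exp(−2πi f d_k − 2π² f² s_k²)|²`,
evaluated on 2,048 uniform frequencies spanning step sizes from
support/60 up to the full PPDD support (periods beyond the largest level
difference are the DC region and are excluded). The unitary step ΔI is
the period of the largest peak; the low-frequency band edge counts as a
candidate when the spectrum decays away from it (for a two-level trace
the single difference *is* the step), near-ties (0.1%) break toward the
larger step so a fundamental beats its harmonics, and the strongest
competing peak outside ±10% of the winner is recorded for the dominance
gate.

The initial intensity I₀ is a linear-scale least-squares fit of
`I(t) = I₀ exp(−t/t_b)` evaluated at the first frame (log-scale fitting
would be dominated by near-zero late frames). The highest idealized level
is biased low at high copy numbers — early steps merge — which the test
suite demonstrates directly. The copy number `n = I₀/ΔI` is kept
real-valued; population structure is assessed by the mixture fit, never
by rounding.

Data selection applies the six published gates: segmentation-error flag;
ellipticity > 1.2; ΔI outside a factor 2.5 of the in-vitro
single-fluorophore step; selected spectral peak not > 10% above its best
competitor; fitted I₀ differing from the first-frame intensity by > 30%;
localization outside the factory band. An optional high-copy gate
(`max_copies`) exists for datasets with aggregation artifacts and is off
by default. These gates are part of the method, not an afterthought: on
synthetic sweeps they remove the harmonic failure mode (ΔI picked at
twice the true step) that otherwise dominates the error budget.

## Synthetic bleaching traces

Two generators with different dwell conventions are provided, and the
distinction matters:

* `simulate_bleach_trace` — each fluorophore independently survives a
  geometric number of frames with per-frame bleaching probability 1/41,
  so a level with m fluorophores dwells ~41/m frames and the intensity
  envelope decays exponentially with t_b = 41 frames, as in real
  experiments. Noise std at level m is `(Δµ/noise_ratio)·√max(m,1)`
  (variance linear in intensity, with a one-fluorophore floor at the dark
  level — a camera never goes noiseless).
* `simulate_state_dwell_trace` — every occupancy state, including the
  dark state, dwells an exponential number of frames with mean 41, so all
  levels are equally resolvable.

Stoichiometry-sweep validation uses the state-dwell generator. Under the
per-fluorophore convention at 120 frames, levels above ~8 fluorophores
dwell only a handful of frames; their merged idealized levels sit at
fractional multiples of the unitary step, the spectrum's fundamental
decoheres, and the copy-number bias reaches several proteins regardless
of gating — no per-trace estimator can recover information the trace does
not contain. With per-state dwells the full pipeline plus gates keeps the
mean bias within ~half a protein across true stoichiometries 3–15 (small
positive bias at low-to-mid copy numbers, drifting slightly negative at
14–15 where residual harmonic errors survive the gates), with
single-peaked estimate distributions. Passing these sweeps therefore
validates the estimator on resolvable staircases; it does not certify
accuracy for complexes whose early steps are experimentally unresolvable.

## Lifetimes

Trajectory linking is greedy and deterministic: per frame, candidate
links (focus within 350 nm of a trajectory's last position, score ≥ 3)
are sorted by distance, then score, then cell id; a trajectory survives a
single-frame dropout. Accepted trajectories satisfy mean score ≥ 4, max
score ≥ 5 and span ≥ 3 frames, making τ_min = (3−1)·Δt = 4 min at the
2-min cadence. A trajectory reaching the final frame is censored at the
window T; one that ends earlier counts as disassembly only if the focus
stays absent for ≥ 2 further frames inside the series (otherwise it is
censored at its observed span). Left censoring (complexes already present
at frame 0) is ignored — a documented limitation consistent with how the
summary counts are defined.

The closed-form censored MLE above is exact (the test suite checks it
against numerical likelihood maximization to 1e-6 relative). Lifetimes
are frame-quantized downward — a complex seen in frames i..j contributes
(j−i)·Δt — which biases k̂ upward by ~10% at k = 0.12/min and 2-min
cadence; parameter-recovery tests therefore use a fine cadence, and the
parametric bootstrap (`rate_error`) simulates with the same quantization
so error bars and coverage remain honest (measured 2σ coverage ≈ 95%).
Survival curves are evaluated left-continuously, S(t) = P(τ ≥ t), which
makes the floor-quantized empirical curve directly comparable to
`exp(−k̂(t−τ_min))` at frame boundaries; a Kaplan–Meier option exists but
with pure right-censoring at a common window it coincides with the
simple curve.

`null_focus_probability` gives the no-disassembly control for
helicase-loader shutoff experiments: observing a random 2-min-cadence
window of an uninterrupted 40-min replication cycle, conditioned on a
focus in the first frame, the focus is still visible at frame j with
probability (40 − 2j)/40.

## Numerical and reproducibility choices

Variances are floored at 1e-300 inside logs so exactly-constant segments
behave (zero-noise steps force a split; fully constant traces do not).
Mixture fits run EM from five quantile-based initializations and keep the
best likelihood; fits with a vanishing weight (< 1e-3) or means closer
than one pooled width are reported as single-component with F_L = 0.
KDE bandwidth is the normal-reference AMISE rule,
`1.06·min(σ̂, IQR/1.34)·n^(−1/5)`. Every stochastic routine takes an
explicit integer seed; nothing touches global random state, and pipeline
runs persist their config so a run directory reproduces bit-identically.

## Problem sizes

Validation uses 10,000 null traces for calibration audits, ≥ 2,500
single-step traces for detection efficiency, 200–1,000 traces per true
stoichiometry for the sweep, and 300–500 complexes per lifetime dataset
— sizes at which the Monte-Carlo error of each reported statistic is
small compared to its tolerance.
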