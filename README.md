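# replicount

Single-molecule fluorescence analysis of bacterial replisomes: count the
protein subunits in a replication factory by photobleaching-step analysis,
and measure how long replisome complexes survive by rule-based focus
tracking with censored-exponential lifetime inference.

The package is aimed at microscopists and quantitative biologists working
with time-lapse fluorescence stacks of fluorescent-fusion strains
(helicase, polymerase, clamp-loader fusions in *B. subtilis* or
*E. coli*-style experiments). Every stage of the analysis is paired with a
synthetic-data generator carrying known ground truth, so the whole
pipeline is testable without proprietary microscopy data.

## What it computes

**Stoichiometry from bleaching traces.** Foci are detected in a summed,
drift-corrected image stack (watershed around intensity maxima inside
cell masks), fit with a Gaussian `G(x) = G_G exp(-|x-x0|²/2b²) + G_0`,
and scored by significance, `σ = I_A / (δI √A_M)`. The
background-subtracted intensity trace `I_F(t) = I_R - A_M·I_B` of each
focus is idealized by parameter-free change-point (CP) analysis — recursive
binary segmentation under a generalized likelihood-ratio test with
Monte-Carlo-calibrated critical values (5% per-trace false-positive rate
at the default 95% confidence). The unitary single-fluorophore step ΔI is
the period of the largest peak in the power spectrum of the pairwise
probability density distribution (PPDD) of idealized level differences;
the initial intensity I₀ comes from a fit to `I(t) = I₀ exp(-t/t_b)`; the
copy number is

```
n = I₀ / ΔI
```

Population structure (one vs two complexes per factory) is assessed by an
unbinned two-Gaussian mixture MLE with a parametric-bootstrap error on
the low-stoichiometry fraction F_L, and visualized with AMISE-bandwidth
kernel density estimates.

**Complex lifetimes.** Scored foci are linked into trajectories (members
score ≥ 3, ≤ 350 nm movement per frame, mean score ≥ 4, one member ≥ 5,
single-frame gaps tolerated, ≥ 3 frames). Modeling disassembly as a
Poisson process, lifetimes follow `p(τ|k) = k exp(-k(τ - τ_min))` with
right censoring at the observation window T, and the rate MLE has the
closed form

```
k̂ = N_{τ<T} / [ N_{τ<T}(τ̄ - τ_min) + N_{τ≥T}(T - τ_min) ]
```

Multiplying k̂ by the 40-min replication cycle gives the expected number
of replisome disassembly events (replication–transcription conflicts) per
cycle, with a parametric-bootstrap standard error.

## Worked example

`examples/lifetime_inference.py` feeds the summary counts of a 22-minute
helicase tracking experiment (296 observed disassemblies with mean
lifetime 10.4 min, 31 complexes persisting to the window end, τ_min =
4 min) to the estimator:

```
disassembly rate k = 0.1207 /min  (bootstrap std 0.0091)
mean complex lifetime 1/k = 8.3 min
expected disassembly events per 40-min replication cycle: 4.8
fraction persisting the full window (model): 0.114
model survival at 10 min: 0.48 -- the probability a complex observable at 4 min is still intact at 10 min
```

A complex lives ~8 minutes on average, so a 40-minute replication cycle
implies roughly five disassembly/reassembly events.

`examples/count_subunits_from_bleaching.py` runs the bleaching pipeline
end to end on a simulated hexamer:

```
simulated trace: 391 frames, true copy number 6, unit step 1.0
change-point idealization: 6 levels (truth had 7); level means [5.82 3.92 3.07 1.8  0.99 0.03]
unitary step from the PPDD power spectrum: 0.995 (intensity lost when one fluorophore bleaches; true value 1.0)
initial intensity from the exponential fit: I0 = 6.18 with bleaching time t_b = 287 frames
estimated stoichiometry n = I0 / dI = 6.21 copies (a hexamer should land near 6)
data-selection gates: pass
```

The other examples cover focus detection in image stacks
(`detect_foci_in_stack.py`), null-trace calibration of the change-point
filter against the BIC baseline (`null_calibration.py`), and mixture
fitting of copy-number populations (`population_mixture.py`).

There is also a thin CLI for shell use:

```bash
replicount simulate --kind lifetimes --seed 1 --n 300 --out sim/
replicount lifetime --lifetimes sim/lifetimes.csv --window 22 --out run/
replicount report run/
```

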