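# Methods

`memfluid` quantifies the assays used to study how silicate-biomaterial ion
products change cell-membrane fluidity, and simulates the downstream
consequence for membrane signaling. This note documents the models, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions taken where the procedures left
room for choice.

## Laurdan generalized polarization (GP)

Laurdan's emission spectrum red-shifts as the surrounding phospholipids move
from the gel to the liquid-crystalline phase, so the balance between a blue
(400–460 nm) and a red (470–530 nm) emission band reports membrane fluidity.
For an intensity pair the polarization is

    P = (I_blue − I_red) / (I_blue + I_red),

bounded in [−1, 1]; lower values mean a more fluid membrane, and the ratio
is independent of local dye concentration. `compute_gp` splits the two
registered channels into non-overlapping 4×4-pixel tiles anchored at pixel
(0, 0) (partial edge tiles dropped, so every tile statistic pools the same
number of pixels), takes the mean intensity of each channel per tile, forms
one polarization per tile, and reports GP as the unweighted mean over
included tiles. Per-pixel polarization averaged within a tile would weight
dim pixels equally with bright ones; the mean-intensity-first convention is
the one used for the published maps.

**Background handling.** Real fields of view contain non-cell regions, but
the masking used for the published images is unreported. The default here is
a stated convention, not a reconstruction: per-channel background is
estimated from the dimmest 1% of summed-channel pixels, and tiles whose
summed mean intensity is below twice the summed background are excluded
(recorded as NaN and counted). Images with no background region —
confluent fields, uniform synthetic images — would have their signal
subtracted away by that estimator, so when the dimmest-1% mean exceeds half
the median summed intensity the image is judged background-free and no
subtraction is applied. This keeps the closed-form oracle exact: a noiseless
constant-ratio image returns GP = (r−1)/(r+1) to machine precision.

The polarization histogram uses 100 bins over [−1, 1], density-normalized.
Pseudocolor maps render tiles on a fixed [−1, 1] scale with a designated
null color for excluded tiles, so maps are comparable across samples.

With Poisson (photon-counting) noise the tile polarization is conditionally
a rescaled binomial proportion given the tile's total count, so the
estimator is unbiased and a 256×256 image (4096 tiles, ~200 summed counts
per pixel) recovers GP to well within ±0.01.

## FRAP quantification

The model is a single-exponential recovery — the simplest form consistent
with smooth, saturating membrane-lipid recovery curves:

    N(t) = A · (1 − 2^(−t / t_half)),

with mobile fraction `A` and half-time `t_half`, t = 0 at the first
post-bleach frame. Normalization is the double-normalization convention:
optional background subtraction, optional whole-cell reference correction
F(t)·R_pre/R(t) for acquisition bleaching, then floor/pre-bleach scaling so
the pre-bleach mean is exactly 1 and the first post-bleach frame exactly 0.
The bleach floor is the single first post-bleach frame (not a fitted
value) — appropriate for a protocol with a discrete bleach event (default
protocol: 2 pre-bleach frames, 3 s bleach, 50 frames at 2 s). Normalization
is invariant to affine gain/offset changes of the raw intensities.

The *recovery rate* at a report time is 100·N at the nearest frame; the
frame actually used is reported. The default report time is the last frame
(endpoint rate); 50 s is a common earlier preset. Whether a published
"recovery rate" is the normalized endpoint or a fitted plateau is often
ambiguous — both are exposed, and the endpoint convention is the default.
The exponential fit runs over post-bleach frames with `A` constrained to
[0, 1.05] (small overshoot tolerated before clipping); for flat traces the
half-time is structurally unidentifiable and flagged rather than reported as
meaningful. Fit failure raises an error carrying the initial guesses and
data range.

## Emission spectra

Peaks are located on a moving-average-smoothed spectrum (5-point window,
nearest-edge padding) with parabolic interpolation through the three samples
around the argmax; published peak tables carry 0.5 nm precision, finer than
a typical 1 nm acquisition grid, so sub-grid interpolation is required.
Exact ties break toward the shorter wavelength. Band intensities are
trapezoidal integrals over 400–460 nm (blue) and 470–530 nm (red) with
interpolated band edges; the 460–470 nm gap belongs to neither band. A red
shift is flagged when the peak displacement reaches 50 nm — the
characteristic Laurdan shift under increased fluidity or lipid damage — and
the threshold is configurable because smaller shifts matter in other
contexts.

## Apoptosis quadrant statistics

Gating uses the standard annexin V-FITC/PI kit convention (early =
annexin⁺/PI⁻, late = annexin⁺/PI⁺, necrotic = annexin⁻/PI⁺) with
threshold-inclusive boundaries (≥ counts as positive): deterministic and
order-independent. Thresholds are inputs; instrument gates and compensation
are out of scope, and synthetic events are generated pre-compensated. The
early-apoptosis contribution statistic,

    100 · (early_t − early_c) / (total_t − total_c),

may legitimately exceed 100% (late apoptosis decreased under treatment); it
is reported as-is with a flag, and is undefined when total apoptosis did not
change. Group comparisons use Welch's unequal-variance t-test.

## Signaling-cascade simulator

Membrane proteins are 2-D Brownian particles on a periodic square patch. A
global ligand field activates free receptors to T1; T1 captures a free
scaffold on contact (within the interaction radius under the periodic
metric) to form T2; T2 captures a free functional protein to form T3, which
emits output events stochastically. Negative feedback: inhibitors activate
at a per-step rate proportional to the T3 fraction, deactivate first-order,
and an active inhibitor touching a T3 depolymerizes it, releasing all three
monomers (receptor deactivated) at positions jittered uniformly within one
interaction radius. Candidate reaction pairs are resolved greedily in seeded
random order with at most one pair reaction per particle per step; reaction
probability on contact is 1. The ligand is a field, not a particle species:
it acts only as the receptor activator, keeping the three-level cascade the
object of study.

Complexes diffuse slower than monomers, D/√(subunits) by default (a constant
rule is available). Neighbor search uses brute-force minimum-image distances
at the default particle counts and a periodic spatial index (cKDTree) for
larger problems; candidate pairs are canonically sorted before the seeded
shuffle, so both backends produce bit-identical traces, and equality is
tested against brute force.

**Defaults** (all config-exposed; order-of-magnitude plausible for a 1 µm²
membrane patch): 200 receptors/scaffolds/functionals and 50 inhibitors per
µm²; monomer diffusivity 0.05 µm²/s (typical membrane protein), superfluid
arm ×2; interaction radius 10 nm; dt = 0.1 ms (Brownian step RMS ≈ 4.5 nm,
well under box/10); step protocol with stimulus windows 100–200 ms and
400–500 ms over 600 ms; resting protocol 5 s. Per-step probabilities:
ligand-driven activation 0.05, basal activation 5·10⁻⁵, inhibitor
deactivation 0.01, output emission 0.5 per T3; feedback gain 0.2.

The basal rate deserves a note: receptors in this model deactivate only via
T3 depolymerization, so any basal rate fast relative to the protocol horizon
saturates the cascade before the stimulus arrives and buries the step
response. 5·10⁻⁵/step (activation timescale ~2 s) keeps the pre-stimulus
baseline near zero on the 100 ms step timescale while still driving the
resting-state dynamics; with this choice the step response rises from a
near-zero baseline after onset and decays after offset, the superfluid arm
shows a larger and no-later maximum output growth rate in paired runs, and
the resting protocol oscillates through the inhibitor feedback loop
(build-up → inhibitor activation → collapse → inhibitor decay; period of
order 0.5 s).

**Outputs.** Traces record T1/T2/T3 fractions, total receptor activation,
and the output signal — output events per recording interval (1 ms),
moving-average smoothed over 10 intervals and normalized by the theoretical
per-interval maximum, so it lives on [0, 1] and growth rates are comparable
across configurations. The output signal is a smoothed instantaneous rate,
not a cumulative count. The growth rate is a centered finite difference over
the smoothing half-window; its maximum is taken between stimulus onset and
the matching offset. Oscillation detection runs on the linearly detrended
T3-fraction autocorrelation: a secondary peak with prominence ≥ 0.1 and
height ≥ 0.05 flags periodicity, with two credibility rules — the first 10%
of the series (transient) is discarded, and the dominant period must fit at
least three times into the analyzed span — which reject slowly saturating
trends that survive linear detrending. These thresholds were calibrated on
designed positives (sines) and negatives (flat traces, white noise,
saturating exponentials). The fluidity comparison runs seed-paired
normal/superfluid simulations and summarizes them with medians, the
fraction of pairs in the expected direction, and paired sign tests.

Published response metrics for this kind of simulation cannot be targeted
quantitatively — the underlying parameter values were never printed — so the
simulator's claims are directional and structural (conservation, Brownian
statistics, determinism, fluidity ordering, feedback-dependent
oscillations), verified as properties.

## Synthetic data: what it does and does not emulate

Generators are deterministic given seed + parameters. Noise models follow
each acquisition type: Poisson for photon-counting images, additive Gaussian
for curves and spectra (clipped at zero), log-normal channel intensities for
cytometry events (negative median 30 a.u., positive 300 a.u., σ = 0.4 on the
log scale — about a decade of separation, with ~0.2% of events leaking
across a geometric-midpoint gate, as the tails of real stained populations
do). Default sizes are desk-scale: 256×256 images at ~200 summed counts per
pixel, 52-frame FRAP traces with 1 a.u. (1% of pre-bleach) noise, 0.5 nm
spectral grids, 10⁴-event tables.

Not emulated: optics and point-spread functions, cell morphology and
segmentation, spectral bleed-through, cytometry compensation and doublets,
multi-component FRAP recovery. Passing round-trip tests therefore
demonstrates that the analysis recovers known ground truth under the stated
noise models — not that it is robust to every artifact of real
acquisitions. Published cell-level measurements (recovery rates, GP values)
are used as realistic set-points for the generators, not as reproduction
targets: the raw acquisitions behind them do not exist in usable form.

## Problem sizes

The test suite and the reproduction script use: 20 seeds for GP/FRAP
parameter-recovery studies; 10–20 seed pairs for the fluidity comparison;
6–10 resting-state runs of 5 s for oscillation statistics; 2000 tracers ×
10⁴ steps for the Brownian oracle; 1000 random tables for the quadrant
partition property. These sizes give stable statistics for every directional
claim while keeping a full run at desk scale.
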