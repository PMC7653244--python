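# memfluid

Quantitative analysis of cell-membrane **fluidity** assays, built for
studies of how dissolved silicate (bioactive-glass ion products) changes
membrane physics and, downstream, cell signaling. The package is aimed at
cell biologists and biomaterials researchers who have two-channel Laurdan
micrographs, FRAP traces, liposome emission spectra, or annexin V/PI event
tables on disk — and at modelers who want a small, fully reproducible
particle simulator of a membrane signaling cascade.

## What it computes

**Laurdan generalized polarization (GP).** For registered blue
(400–460 nm) and red (470–530 nm) emission channels, the polarization of an
area is P = (I_blue − I_red)/(I_blue + I_red) ∈ [−1, 1]; lower values mean
a more fluid membrane. `laurdan_gp.compute_gp` tiles the image into 4×4-px
blocks, forms one polarization per tile from mean background-subtracted
intensities, and reports GP as the unweighted tile mean, plus the tile map,
a density histogram, and pseudocolor rendering.

**FRAP.** `frap.normalize` double-normalizes a bleached-ROI trace (pre-bleach
mean → 1, bleach floor → 0, optional background/reference correction);
`frap.recovery_rate` reads the recovery percentage at a report time, and
`frap.fit_recovery` fits N(t) = A·(1 − 2^(−t/t_half)) for the mobile
fraction A and half-time t_half.

**Spectra.** `spectra.find_peak` locates emission peaks with sub-grid
(parabolic) precision, `spectra.band_intensities` integrates the Laurdan
blue/red bands, and `spectra.detect_red_shift` flags the characteristic
~50 nm fluidity/damage shift.

**Apoptosis.** `apoptosis.gate` quadrant-gates annexin/PI event tables
(early = annexin⁺/PI⁻, late = annexin⁺/PI⁺), and
`apoptosis.early_contribution` computes the share of a treatment-induced
apoptosis increase carried by early apoptosis:
100·(early_t − early_c)/(total_t − total_c).

**Cascade simulator.** `memsim` runs a Monte Carlo model of 2-D Brownian
membrane proteins: ligand-activated receptors (T1) recruit scaffolds (T2)
then functional proteins (T3 — the output-emitting complex), with
inhibitor-mediated negative feedback that depolymerizes T3. Two arms differ
only in diffusivity ("normal" vs "superfluid" membrane);
`memsim.compare_fluidity` quantifies how higher fluidity sharpens and
speeds the output-signal response to a step stimulus.

**Synthetic data.** `synthetic` generates all of the above inputs with
known ground truth (Poisson image noise, Gaussian curve/spectrum noise,
log-normal cytometry channels), so every analysis stage is testable without
external acquisitions.

## Worked example

```python
import memfluid as mf

# a two-channel Laurdan image with known GP, Poisson photon noise
pair = mf.gen_gp_image_pair(gp_true=-0.349, shape=(256, 256), seed=1)
result = mf.compute_gp(pair, tile_size=4)
print(f"GP = {result.gp:.3f} from {result.n_tiles_used} tiles")

# a FRAP trace: 67.4% mobile pool, 10 s half-time, 1% noise
series = mf.gen_frap_series(mobile_fraction=0.674, half_time=10.0, seed=3)
trace = mf.normalize(series)
print(f"recovery at {trace.report_time or 98:.0f} s: "
      f"{mf.recovery_rate(trace):.1f}%")
fit = mf.fit_recovery(trace)
print(f"mobile fraction {fit.mobile_fraction:.3f}, "
      f"half-time {fit.half_time:.1f} s")

# early-apoptosis contribution from quadrant percentages
from memfluid.apoptosis import ApoptosisSummary, early_contribution
treated = ApoptosisSummary.from_percentages(27.0, pct_apoptotic=52.0)
control = ApoptosisSummary.from_percentages(21.7, pct_apoptotic=44.1)
print(f"early contribution: {early_contribution(treated, control).percent:.1f}%")
```

prints

```
GP = -0.349 from 4096 tiles
recovery at 98 s: 66.2%
mobile fraction 0.676, half-time 10.1 s
early contribution: 67.1%
```

The GP estimate lands on the ground truth because tile polarizations are
conditionally unbiased under Poisson noise; the FRAP fit recovers the
generator's parameters to within the noise; and the contribution statistic
says that two-thirds of the treatment-induced rise in apoptosis came from
the early (phosphatidylserine-externalization) quadrant.

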