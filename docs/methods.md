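# Methods

`xcquench` models the xanthophyll cycle of green algae — the reversible
de-epoxidation of violaxanthin (Vio) to zeaxanthin (Zea) via antheraxanthin
(Ant) — and the photoprotective quenching it drives, and provides the
analysis stages for the four instrument modalities used to study it:
saturating-pulse (PAM) fluorometry, 77 K emission spectroscopy,
time-resolved fluorescence, and HPLC pigment analysis. This note records
the model equations, the shipped default parameters and how they were
calibrated, what the synthetic-data generators do and do not emulate, and
the numerical choices that matter.

## Xanthophyll-cycle kinetics

**De-epoxidation index.** DI = ([Zea] + 0.5[Ant]) / ([Zea] + [Ant] + [Vio]);
0 for a fully epoxidated pool, 1 for a fully de-epoxidated one. DI is
undefined (an error, not 0) when all three pools are empty.

**In-vitro assay** (`simulate_in_vitro`, time in minutes). The
reconstituted system contains violaxanthin de-epoxidase (VDE), its
substrate and ascorbate at fixed pH, and no epoxidase:

    dVio/dt = −k_de1 · a(pH) · g · Vio
    dAnt/dt =  k_de1 · a(pH) · g · Vio − k_de2 · a(pH) · g · Ant
    dZea/dt =  k_de2 · a(pH) · g · Ant

where `a(pH)` is the normalized enzyme activity and `g` the inhibition
factor when dithiothreitol (DTT) is present (default 0: complete inhibition
at 1 mM, modelled as time-independent since only the endpoint effect is
characterized). The *conversion fraction* is 1 − Vio(t_end)/Vio(0)
(violaxanthin consumed); Zea(t_end)/Vio(0) is available as an alternative
basis and always lags it while the Ant intermediate is populated.

Because Vio(t) is a single exponential in k_de1·a, calibrating the default
rate constants to the measured 60-min conversion efficiencies has a closed
form, k_de1 = ln(1/(1−f))/60 with a(5.1) = 1:

| species | 60-min conversion f | k_de1 = k_de2 (min⁻¹) |
|---|---|---|
| *A. thaliana* | 0.95 | 0.0499 |
| *C. vulgaris* | 0.77 | 0.0245 |

k_de2 = k_de1 is a convention (the endpoint constrains only k_de1);
`calibrate_k_de` re-derives the constant by root-finding on the simulated
endpoint, which the tests check against the closed form.

**pH-activity profile** (`ph_activity`). Product of an acid-side rising and
an alkaline-side falling logistic, normalized to 1 at the optimum
(pH 5.1 for both enzymes). The alkaline-logistic center is placed
analytically so the continuous maximum sits exactly at the optimum: with
acid scale s₁, alkaline scale s₂ and acid half-rise offset d₁ below the
optimum, stationarity requires σ((pH_opt−c₂)/s₂) = s₂(1−σ(d₁/s₁))/s₁,
which is solved for c₂ in closed form. Defaults: s₁ = 0.35, d₁ = 1.0 for
both species; s₂ = 0.90 (*A. thaliana*) vs 0.45 (*C. vulgaris*), making
the algal enzyme lose activity much faster above the optimum (activity at
pH 7.0: 0.53 vs 0.19). The acid side below pH 5.1 is uncharacterized by
the calibration data; its defaults are a free choice and identical across
species so that cross-species comparisons reflect the alkaline side only.
Valid domain pH 3–9.

**In-vivo operation** (`simulate_in_vivo`, time in seconds). Irradiance I
sets a steady-state lumen pH, approached first-order:

    pH_ss(I) = pH_dark − ΔpH_max · I/(I + K_I),   τ_pH = 30 s

with pH_dark = 7.0, ΔpH_max = 2.0 (pH → 5.0 at saturation), K_I = 1000
µmol m⁻² s⁻¹. The lumen pH is a latent driver — the package fits or
measures no pH — so these are plumbing constants tuned only through their
observable consequences (below). VDE flux uses the same `a(pH)` rescaled
to vanish at pH_dark: the residual alkaline-tail activity of the free
enzyme (~19% at pH 7 for *C. vulgaris*) does not operate in dark-adapted
cells, and without this gate a dark simulation would slowly de-epoxidate,
which is not observed. Epoxidation (Zea→Ant→Vio, rate k_ep on both steps)
runs throughout.

Quenching components (npq_total = qE + qZ + qI pointwise, all ≥ 0):

* **qE** relaxes toward qE_max · f(pH) · (z₀+Zea)/(z₀+Zea+K_z) with
  induction τ 45 s and relaxation τ 90 s. f(pH) is a steep logistic gate
  (half 6.8, scale 0.1, rescaled to 0 at pH_dark): qE engages as soon as
  any trans-thylakoid ΔpH forms. K_z = 0.25 mol/100 Chl is small relative
  to the accessible Zea pool (~1–2/100 Chl), so few zeaxanthin molecules
  activate most of qE; z₀ = 0.03 provides the residual zeaxanthin-free qE
  seen under VDE inhibition (~15% of the control).
* **qZ** is driven in light by Zea/(Zea+0.8) toward a high ceiling
  (qZ_max = 4, rarely approached) with τ_ind = 600 s, and relaxes with
  τ_rel = 1800 s in light or darkness. The light gate means qZ, like qE,
  declines during dark recovery; its slow relaxation carries the
  zeaxanthin "memory" between light cycles.
* **qI** (photoinhibitory) is driven by I/(I+500) with τ_ind = 1200 s and
  relaxes with τ_rel = 3600 s.

In-vivo cycle rates (k_de1 = k_de2 = 0.070 min⁻¹, k_ep = 0.028 min⁻¹,
*C. vulgaris*) are calibrated jointly so that (i) a 40-min exposure at
2000 µmol m⁻² s⁻¹ reaches DI ≈ 0.6, (ii) less than 15% of accumulated
zeaxanthin re-epoxidates during a 5-min dark interval (the two-cycle
protocol therefore starts its second cycle with most of its zeaxanthin
retained), and (iii) the 200–2500 µmol m⁻² s⁻¹ sweep spans DI ≈ 0.1–0.5
with the component ordering described under *Correlation*. The in-vivo
rates are ~3× the in-vitro *C. vulgaris* rate: the enzyme works on its
native membrane substrate rather than micellar violaxanthin.

Solver: LSODA (stiff-capable), rtol 1e-8, atol 1e-10 × pool, fixed 1-s
output grid, integrated piecewise per constant-irradiance segment. The
pigment subsystem is exactly conservative; trajectories hold
|Σpools(t) − Σpools(0)| < 1e-6 relative (observed ~1e-15). The simulator
is fully deterministic; all stochasticity lives in the generators.

## PAM analysis

Fm is the maximum fluorescence within pulse windows (±0.4 s) of the
dark-adapted segment; Fm′ the in-window maximum of each later pulse (ties:
first occurrence, logged). NPQ = (Fm − Fm′)/Fm′; Fv/Fm = (Fm − Fo)/Fm with
Fo the median dark baseline outside pulse windows. The qE / qI(qZ) split
is the standard relaxation-based partition: the slowly relaxing fraction is
NPQ at the last dark-recovery pulse, qE the remainder at the last pulse in
light, so qE + q_slow reconstructs end-of-light NPQ exactly. Whether the
endpoint is the single last pulse or the mean of the last k pulses is
configurable (default k = 1). Far-red illumination during recovery is not
modelled; dark recovery is treated as quenching relaxation only.

## 77 K spectra

Spectra are normalized so the integrated GFP internal-standard band
(500–540 nm window) has unit area, then deconvolved over 660–780 nm into
four Gaussians: PSII at 686 and 698 nm, PSI at 720 nm, and one vibronic
satellite near 748 nm excluded from both sums. Bounded least squares
(lmfit): centers within ±5 nm of their initial guess, σ in 2–25 nm, areas
≥ 0. Photosystem quenching is (A_dark − A_light)/A_light on the summed
band areas — the denominator is the light-treated area by convention here;
the (A_dark − A_light)/A_dark alternative is a flag. The statistic is
invariant to any common rescaling of both spectra.

## Time-resolved fluorescence

The measured histogram is Σᵢ aᵢ e^(−t/τᵢ) convolved with the IRF and
wrapped at the laser repetition period (analytic steady-state factor
1/(1−e^(−T/τ)) per component; negligible for the 80 MHz / sub-ns regime
but kept for generality). With a Gaussian IRF the convolution is the
closed-form exponentially modified Gaussian; a measured IRF column is
convolved numerically with a continuous sub-bin shift. Default IRF FWHM:
30 ps (streak-style) or 120 ps (TCSPC-style). Fits are Poisson-weighted
(w = 1/√max(counts,1)), start from the IRF peak, and initialize lifetimes
staggered around the empirical post-peak centroid. Lifetimes at their
bounds or near-degenerate pairs are flagged, not silently dropped.

The *average lifetime* is amplitude-weighted, τ_avg = Σ aᵢτᵢ, the standard
choice for quenching analyses; the intensity-weighted mean
Σ aᵢτᵢ²/Σ aᵢτᵢ is always reported alongside. The shipped PSI parameter
sets, (55, 140) ps at fractions (0.8, 0.2) for zeaxanthin-free and
(35, 105) ps at (0.8, 0.2) for zeaxanthin-binding PSI, are calibrated to
amplitude-weighted averages of 72 ps and 49 ps — a 32% acceleration on
zeaxanthin binding — and are recovered by the full generate→fit path with
a bias under 2 ps at 10⁴ peak counts.

## HPLC and the spectrophotometric assay

Peak detection: local maxima above a prominence (default 5 mAU) and width
(default 0.02 min) threshold; each peak is integrated between the valleys
adjacent to its apex after subtracting the straight baseline joining them,
making areas invariant to uniform offsets. Quantification is linear:
concentration = area × response factor for the single peak in each
pigment's retention window; an empty window yields 0 with a
below-detection flag, two peaks in one window is an ambiguity error, and
unassigned peaks are reported. The shipped retention times and response
factors are synthetic conventions spaced over a 15-min gradient — the
separation method is standard but its constants are instrument-specific,
so real data require a calibration file.

The enzymatic-assay readout is (A505 − A540), normalized to its global
maximum over the time series; a series whose maximum difference is ≤ 0 is
returned unnormalized with a no-activity flag.

## Correlation of NPQ components with DI

`sweep_irradiance` runs the continuous NPQ protocol (1 min dark, 25 min
light, 10 min dark recovery) at each irradiance (default 200–2500
µmol m⁻² s⁻¹, 8 points) and tabulates end-of-light DI, zeaxanthin, NPQ and
its relaxation-based split. Each component is fitted with the saturating
exponential through the origin, y = y_max(1 − e^(−rate·x)) with x = DI
(or absolute zeaxanthin), non-negative bounds; an optional intercept is
available. On the defaults the fitted rates order qE > NPQ > qI/qZ
(≈ 2.0, 1.45, 0.44 per DI unit): qE saturates after few zeaxanthin
molecules while the slow component tracks zeaxanthin almost linearly. An
all-zero response returns y_max = 0 with the rate flagged unidentifiable.

## Synthetic-data generators

Each generator inverts exactly one analysis operation and takes all its
randomness from the single seed in `NoiseSpec` (per-modality independent
streams derived via CRC of the stream name; identical seed → identical
output). Noise models follow instrument physics: multiplicative Gaussian
for fluorescence and emission spectra (defaults 0.5% PAM, 1% spectra),
additive Gaussian for chromatogram baselines (0.2 mAU), Poisson counting
for decays (10⁴ peak counts).

* PAM: baseline Fo/(1+NPQ(t)) with 0.6-s pulse plateaus at Fm/(1+NPQ) —
  the exact inversion of the NPQ formula; NPQ is frozen at the
  pulse-center value across the brief plateau. Defaults Fm = 2.0,
  Fo = 0.4 (dark Fv/Fm = 0.8).
* 77 K: sum of the five Gaussian bands (GFP standard at 518 nm, σ 4.5 nm,
  fully inside the standard window).
* Decay: the reconvolution model itself, scaled to the peak expectation
  and Poisson-sampled; optional IRF column.
* HPLC: one Gaussian per pigment (σ 0.06 min) at its window center with
  area = concentration / response factor.

What the generators do **not** emulate — and hence what passing round-trip
tests do not establish about real data: spectral overlap between GFP and
chlorophyll emission, detector response and wavelength calibration drift,
HPLC retention drift and co-elution, baseline drift, PAM actinic-light
artefacts and far-red effects, IRF asymmetry and afterpulsing, and any
biological variability between replicates. Round-trip tolerances measure
the analysis stages under the stated noise models, nothing more.

## Problem sizes

The test suite and the acceptance script use the study-scale protocols
directly (25–40 min simulated protocols at 1-s resolution; 100-seed
recovery studies for decays, spectra and chromatograms; 200 replicates for
the asymptotic-fit recovery); the full suite runs in well under a minute
per heavy study and needs no down-scaling.

## Known limitations

* The lumen pH map and quenching couplings are effective, not mechanistic:
  they reproduce endpoint calibrations and qualitative orderings, not
  electron-transport physiology (no ΔpH/ATP thermodynamics, no qT/state
  transitions, no PSII repair).
* qE induction/relaxation uses a switched time constant (faster induction
  than relaxation), which makes the right-hand side discontinuous at the
  target crossing; LSODA handles it, but step-size control near the switch
  is heuristic.
* The in-vivo rate constants bundle enzyme activity with substrate
  accessibility; they are not transferable to other growth conditions.
* The two-exponential PSI description is an operational compression of
  multi-phase kinetics; with a 200-ps streak window the long component is
  truncated (fits remain unbiased for the shipped sets, but lifetime
  *pairs* are better determined on longer windows).
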