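# Methods

## The model

A leaf is treated as a pile of absorbing plates with rough, Lambertian
interfaces — the generalized plate model that underlies the PROSPECT family
of leaf radiative-transfer codes.  Light entering the top surface within a
cone of half-angle α is partially reflected by the Fresnel interface,
partially transmitted into the plate interior, attenuated by absorption, and
multiply scattered between the interfaces; the closed-form sum of all bounce
orders gives the plate's diffuse reflectance and transmittance.  A pile of
`N` identical plates (non-integer `N` allowed) follows Stokes' closed form:
with single-plate values `r`, `t`,

    δ = sqrt((t² − r² − 1)² − 4r²)
    a = (1 + r² − t² + δ) / 2r        b = (1 − r² + t² + δ) / 2t
    R(N) = a (b^{2N} − 1) / (a² b^{2N} − 1)
    T(N) = b^N (a² − 1) / (a² b^{2N} − 1)

with dedicated limits for the non-absorbing (`r + t = 1`) and
reflectionless (`r = 0`) regimes.

The homogeneous (uniform) leaf model uses one such pile with per-sublayer
optical depth `k(λ) = Σᵢ Kᵢ(λ) Cᵢ / N`, where `Kᵢ` are the specific
absorption coefficients of chlorophyll a+b (cm² µg⁻¹), water and dry matter
(cm² g⁻¹) and `Cᵢ` the corresponding contents.  The transmissivity of one
plate under diffuse illumination is

    τ(k) = (1 − k) e^{−k} + k² E₁(k),

with `E₁` the exponential integral (`scipy.special.exp1`).

The **two-layer model** reflects the anatomy of a rice leaf: a palisade-like
upper layer (densely packed, chloroplast-rich) over a spongy lower layer.
Each layer is its own pile, with structure parameters `N1`, `N2` and
partition ratios `Cab12`, `Cw12`, `Cm12` — the fraction of each constituent
total assigned to the upper layer:

    k1 = (Kcab·Cab12·Cab + Kcw·Cw12·Cw + Kcm·Cm12·Cm) / N1
    k2 = (Kcab·(1−Cab12)·Cab + Kcw·(1−Cw12)·Cw + Kcm·(1−Cm12)·Cm) / N2

so `N1·k1 + N2·k2` conserves the whole-leaf absorption spectrum band by
band.  The two layers are coupled by the adding–doubling closure over all
inter-layer bounces,

    R = R1↓ + T1↓ R2↓ T1↑ / (1 − R1↑ R2↓)
    T = T1↓ T2↓ / (1 − R1↑ R2↓),

which is associative; with a uniform partition
(`Cab12 = Cw12 = Cm12 = N1/(N1+N2)`) the two-layer model collapses exactly
onto the homogeneous model with `N = N1 + N2` (a unit-tested identity).
`Cw12` is fixed at 1 by default: inversions consistently drive the water
fraction to the upper layer, and freezing it removes one degree of freedom.

Assumptions worth keeping in mind: interfaces are Lambertian-rough and
unpolarized (Fresnel energy coefficients averaged over the incidence cone);
all internal illumination is fully diffuse; the interface between the two
layers behaves like every inter-plate gap in a Stokes pile (no special
index step); there is no bidirectional (specular) component and no surface
epidermis texture.

## Interface optics

The cone-averaged Fresnel transmittance
`t_av(α,1,n) = ∫₀^α T_F(θ;n) sinθ cosθ dθ / ∫₀^α sinθ cosθ dθ` is computed
by 128-node Gauss–Legendre quadrature of the unpolarized Fresnel factor
(agrees with brute-force trapezoid quadrature at 10⁵ nodes to better than
1e-8).  The reverse pass (leaf → air, diffuse) uses the Stern identity
`t_av(α,n,1) = n⁻² t_av(α,1,n)`.

## Parameters, units, defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| α | incidence-cone half-angle at the top surface | deg | 40 |
| N | whole-leaf structure parameter | – | 1 (inversion input) |
| Cab | chlorophyll a+b content | µg cm⁻² | sample-specific |
| Cw | equivalent water thickness | g cm⁻² | sample-specific |
| Cm | dry matter content | g cm⁻² | sample-specific |
| N1 | upper-layer structure | – | fitted, `N·(2 + 0.01·x)` |
| N2 | lower-layer structure | – | fitted, `N·(0.1 + 2.9·x)` |
| Cab12, Cm12 | upper-layer fractions | – | fitted in [0, 1] |
| Cw12 | upper-layer water fraction | – | 1 (fixed) |

α = 40° is the plate-model convention for direct illumination of a rough
epidermis; all internal and return passes are isotropic (90°).  Dry matter
is held in g cm⁻² internally (values of order 0.004–0.013); a µg-labelled
column of that magnitude in an input table is already in these units.
Structure parameters below 1 are accepted by the Stokes form
(extrapolated-structure regime, flagged with a warning for the directional
layer); they have no direct anatomical meaning and are calibration
quantities only.

## Inversion

The fitted quantity is the summed relative deviation over the 601-band grid,

    y = Σ_λ |R_mod(λ) − R_meas(λ)| / R_meas(λ),

with the measured reflectance floored at 1e-6 to guard near-zero blue
bands.  The optimizer is an in-repo NSGA-III (simulated binary crossover
η=30, polynomial mutation η=20 with probability 1/d, population 100,
200 generations, Das–Dennis reference points, adaptive normalization by
ideal point and achievement-scalarized intercepts).  Two modes exist:

* **scalar** (default): one objective, `y` over the full grid.  NSGA-III
  degenerates to elitist rank truncation, which is exactly what a
  single-scalar fitness needs.
* **bands**: three objectives, `y` evaluated separately over the blue-green
  [400, 560], yellow-red (560, 780] and near-infrared (780, 1000] bands;
  the reported solution is the best compromise (minimal total).

Within niche-preserving selection the member closest to its reference line
is taken; the random stream only breaks ties between equally crowded niches,
which keeps runs bit-reproducible from the seed.  Non-finite objective
values are replaced by a large penalty (1e18) and logged.

The homogeneous baseline fits only `N ∈ [1, 3]` with the same optimizer
budget, so two-layer vs uniform comparisons are like-for-like; the
spectrometer-style accuracy metric is the relative RMSE
(RMS difference / band-mean measured reflectance), reported over the full
grid and per band.  Band edges belong to the left band so the 601 bands
partition as 161 + 220 + 220.

## Synthetic data

No field data ship with the package.  The cohort generator emulates the
study design the model targets: four growth periods
(tillering/jointing/heading/grouting, 38/60/60/60 samples), per-period
biochemistry envelopes (see `leaflayers.cohort`), ground-truth partitions
drawn from the envelope of field-inverted values (N1 ∈ [2, 2.0373],
N2 ∈ [0.1, 3], Cab12 ∈ [0.1157, 1], Cm12 ∈ [0, 1]), spectra from the
two-layer forward model plus additive i.i.d. Gaussian noise (default
σ = 0.01 reflectance, a typical field-spectrometer level), clipped to
[0, 1].  Sampling is uniform within the envelopes; a triangular option
peaks each period's distribution at its published mean.

The synthetic optical-constants table places the two chlorophyll absorption
Gaussians at 450 and 650 nm, a water absorption curve rising toward
1000 nm, a small flat dry-matter term and a slowly drifting refractive
index in 1.3–1.5.  It is smooth and physically plausible but *not* a
calibrated coefficient set: absolute reflectance levels, the exact depth of
the 690 nm chlorophyll shoulder and NIR water features differ from real
leaves.  Consequently, passing recovery tests demonstrate the correctness
and identifiability of the machinery (forward physics, optimizer, metrics)
under the study's sampling conditions — not field accuracy with real rice
spectra, which requires a measured coefficient table supplied as CSV.

What the generator does not emulate: wavelength-correlated sensor noise,
splice artefacts, illumination drift, biochemistry measurement error, or
any correlation between biochemistry and partition (draws are independent).

## Numerical choices

* Gauss–Legendre (128 nodes) for cone averages; exact 1.0 at n = 1.
* `τ(k)` via `exp1`, with the k → 0 limit set explicitly to 1 and results
  clipped to [0, 1] against rounding.
* Stokes branches: conservation branch for `r + t ≥ 1 − 1e-12`,
  reflectionless branch for `r ≤ 1e-12`; `r + t > 1 + 1e-9` raises
  (gain medium / complex root).
* Adding denominators `1 − R↑R↓ ≤ 0` raise rather than return nonsense.
* Intercept solve falls back to per-axis maxima (and then to 1) when the
  extreme-point system is singular or yields nonpositive intercepts.
* SG smoothing defaults to window 11, order 3 (mild at 1 nm resolution);
  the interpolating case window = order + 1 is the identity.
* Per-sample optimizer seeds are derived with `numpy.random.SeedSequence`
  from the run seed and the sample index, keeping every seed below 2³¹.

## Problem sizes used in the shipped checks

Recovery checks run 20-sample cohorts with population 100 × 200
generations (noiseless and σ = 0.01); the end-to-end CLI check uses a
20-sample cohort at population 60 × 60 generations; the acceptance script
defaults to 12 samples per cohort.  These sizes were chosen to make the
statistics stable while keeping a full run of the suite comfortable on a
single CPU; all of them are parameters, not constants.

## Known limitations

* The structure parameters (especially N2) are weakly identified from
  reflectance alone; different (N2, Cm12) combinations can fit a spectrum
  almost equally well.  Cab12 is well identified through the visible bands.
* The fitness is L1-relative while the accuracy metric is L2-relative; the
  y-optimal solution is not exactly the RMSE-optimal one (differences are
  below 1% of the metric in practice).
* No transmittance measurements are used in fitting (field protocol is
  reflectance-only); T is computed and exposed for physics checks.
* Carotenoids/anthocyanins are not separated from the chlorophyll term, and
  no canopy-level transfer is included.
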