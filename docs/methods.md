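# Methods

`pcdnoise` models signal and noise formation in direct-conversion
photon-counting x-ray detectors (CdTe/CZT) from first principles: photon
interactions in the converter, lateral spreading of the liberated charge,
K-fluorescence transport, energy thresholding into counting bins, and the
spatial statistics of the resulting count images.  This note records the
model, its assumptions, the numerical choices, and the limits of what the
test suite demonstrates.

## Physical model

### Interactions and element mixing

A photon of energy E interacts with probability α = 1 − exp(−μ(E) L)
(total narrow-beam attenuation at converter thickness L; coherent
scatter, ≲2% of removals, is counted as an interaction but its deposit is
not modeled separately).  Given an interaction, the element (Cd or Te)
is chosen proportionally to the mass-fraction-weighted photoelectric +
incoherent cross sections, and the interaction type (photoelectric vs
Compton) by the photoelectric fraction ξPE of that element.  At the RQA
mean energies Compton is below 5% of interactions; it is modeled through
the local-deposition path at Klein–Nishina-distributed recoil energies,
with the scattered photon assumed to escape.

Attenuation tables are embedded plain-text files generated from
first-principles ingredients (Cromer–Liberman photoabsorption via the
optical theorem, Klein–Nishina incoherent scattering with a one-parameter
Thomas–Fermi-scaled screening function, Thomson × IT92 form-factor
coherent scattering), anchored to standard NIST/XCOM reference totals for
Al and W.  The unanchored Cd/Te tables reproduce the published
quantum-efficiency-matched converter thicknesses for all six
(beam, QE-level) combinations within ±2.1%.

### Photoelectric cascade

A photoelectric interaction follows one of three parallel paths:

* **A** — no K x ray: E deposits at the interaction site;
* **B** — a K x ray is emitted (probability P_K ω_K) and escapes:
  E − E_K deposits locally;
* **B+C** — the K x ray is reabsorbed (probability f_K): E − E_K deposits
  locally, E_K at a site displaced by a draw from the relocation kernel
  p_K(r).

P_K (K-shell participation) is derived from the photoelectric jump of the
embedded tables (Cd 0.845, Te 0.840); fluorescence yields are ω_K = 0.843
(Cd) and 0.875 (Te); each element emits a single mean K-energy photon
(intensity-weighted Kα/Kβ mixture: 23.62 / 28.02 keV).  Kα/Kβ splitting
is not modeled; at the 2-keV electronic noise of imaging ASICs the lines
blur together.

f_K and p_K come from a semianalytic ray trace: primary interaction depth
weighted by Beer–Lambert attenuation, isotropic emission, exponential
free path at the K energy truncated at the slab faces, reabsorbed energy
deposited photoelectrically at one point.  A Monte Carlo ray-tracing
oracle with the same geometry validates both to sampling precision.
Second-generation fluorescence and Compton transport of K photons are
neglected.

### Charge transport and the charge-sharing kernel

Only the electron cloud is tracked (electron mobility ~10× hole
mobility).  The spherically symmetric cloud about the drifting centroid
obeys the enclosed-charge transport equation combining Coulomb
self-repulsion (Gauss' law + mobility) and diffusion (Einstein relation):

    dQ/dt = −(μe/(8πε r²)) ∂(Q²)/∂r + D [∂²Q/∂r² − (2/r) ∂Q/∂r],

with D = μe k T / q, total charge (E/w) q (w = 5 eV per pair), and a
uniform-sphere initial condition of radius r0(E) = 17 (E/60 keV)^{1/3} μm.
Integration runs to the full-thickness drift time t = L²/(μe V); the
final radial density is Abel-projected onto the imaging plane to give the
2D charge-sharing kernel, whose radius is quoted as the HWHM.

Numerics: uniform radial grid (0.25 μm default), explicit Heun stepping
with a diffusion/advection CFL limit, first-order upwinding of the
(outward) repulsion advection, monotonicity enforced against roundoff.
Two closed forms pin the solver: the pure-repulsion uniform ball
(r³ = r0³ + 3 μe Q t/(4πε)) and the point-source diffusion Gaussian
(σ = √(2Dt)); the projection is checked against the uniform-ball HWHM
(√3/2) r0.  Note the equation is invariant under (μe, t) → (c μe, t/c):
only the product μe·t is identifiable from a kernel shape, which is why
the energy-response calibration fit reports a ridge in (μe, t_drift).

A measurement-driven calibration broadens the kernel with an isotropic
Gaussian of σ = (R_em − R_th)/√(2 ln 2); the default σ = 8 μm reproduces
the gap between bench-measured and theoretical radii of a 2-mm CZT
detector at 900 V.  All NPS/DQE results use the calibrated kernels.

The solver reproduces the published theoretical bench radii (26/32 μm at
59/136 keV) exactly within tolerance.  For the thinnest
quantum-efficiency-matched converter (52 keV, 200 μm, 3333 V/cm, 6 ns
drift) it yields 15 μm; the repulsion closed form caps the cloud edge at
18.9 μm (projected HWHM ≤ 16.4 μm before diffusion dome-shaping), so
substantially larger radii are not obtainable from the stated drift time.

### Energy response, gains, thresholds

For an interaction at lateral position r relative to an element center,
the collected energy is normal with mean E_X · P_CS(r), where
P_CS = Π(r/a) ∗ p_CS (aperture rect convolved with the kernel), and
variance F w ε̄ + σe² — conversion-gain statistics written in energy
units plus electronic noise (σe = 2 keV; F = 1, Poisson gain, is the
default; the physical Fano factor ~0.1 changes the 63-keV photopeak FWHM
from 4.89 to 4.73 keV and is negligible for imaging).  Position-averaging
over incidence locations (a histogram-of-means mixture, 800 bins) gives
the pulse-height spectrum; for the fluorescence path, relocation is
averaged over radial-quantile × angular nodes of p_K.  Bin integrals of
the response give per-bin large-area gains; counts per element are
c̄ = q̄0 a Ḡ.  Counting bins default to a 10-keV floor (the assumed
electronic-noise floor); two-bin configurations place the split by
bisection for equal counts (imbalance < 0.5%).

### Pair covariance and noise power spectra

The covariance of counts in bins i, j at element lag τ is assembled from
windowed counting-probability maps Φ_{X,i}(x) (the probability that an
interaction at x delivers a bin-i count to an element at the origin) as
position cross-correlations Φ_i ⋆ Φ_j, evaluated with FFTs and summed
over paths, elements, interaction types, and (for the polyenergetic case)
fluence-weighted energy nodes; the fluorescence path integrates the
relocation displacement over p_K quadrature nodes.  The construction
assumes independent thinning of the two elements' quanta, which fails as
the elements approach complete overlap: inside the half-aperture box the
covariance is interpolated along rays between the τ = 0 anchor
δ_ij c̄_j (single-element counts are Poisson) and the computed boundary
value.

The presampling NPS is the continuous Fourier transform of the covariance
(evaluated by 2D zoom FFT on the band of interest).  The digital NPS —
what a sampled image exhibits — adds noise aliasing; it is computed
exactly as the DTFT of the covariance sampled on the element lattice
(equivalently, the alias sum of the presampling NPS over all
reciprocal-lattice shifts; both routes are implemented and agree to
<1%).  All covariances are carried per unit incident fluence, making
DQE, NNPS, and multiplicity fluence-invariant.

Zero-frequency metrics: DQE(0) = c̄²/(q̄0 W_dig(0)), also obtainable from
the lattice sum of covariances and from multiplicity moments
(DQE(0) = α m̄²/m²̄); the three routes agree to 10⁻³ and the
pixel-SNR inequality DQE(0) ≤ c̄/(q̄0 a) holds in every configuration.
Spectral imaging combines two bins by log subtraction with a
bone-suppression parameter λ = μ_L,B/μ_H,B (bin-response-weighted bone
attenuation averages); the spectral NPS is
W_S = W_L/c̄_L² + λ² W_H/c̄_H² + 2λ W_LH/(c̄_L c̄_H), and
GDQE(0) = (1+λ²)/(q̄0 W_S,dig(0)), normalized by the ideal equal-split
value 0.5.

## Tube spectra

The tungsten-anode model uses thin-target Kramers production
(∝ 1/(T E) per unit path) along the Thomson–Whiddington depth–energy
relation (C = 7.4×10⁵ keV² cm²/g), target self-filtration at a 12° anode
angle, inherent filtration of 2.5 mm Al, W K lines above 69.5 keV, and
external Al filtration by Beer–Lambert, on a 1-keV grid from 10 keV.
The characteristic-line amplitude is the one free constant; it is set so
the heavily filtered 120-kV beam carries ~14% K-line fluence, which
reproduces the RQA5/7/9 mean energies (51.6/62.8/76.0 keV) within 1 keV.
Computed air-kerma HVLs are 6.6/9.1/11.5 mm Al; the RQA7 value matches
the nominal beam quality, the outer two deviate (the model spectrum shape
is not an exact stand-in for standardized RQA beams), which affects no
downstream result since all detector calculations consume the fluence
spectrum itself.

## Monte Carlo validator

The simulator replays the same cascade stochastically per photon:
Bernoulli(α) interaction; element/type mixing; K emission, escape, or
reabsorption at a sampled relocation; Poisson(E/w) secondary quanta
partitioned multinomially over neighboring elements with
kernel-integrated probabilities (an exact equivalent of relocating each
quantum independently); per-deposit Gaussian electronic noise; and
thresholding.  Ablation modes disable fluorescence or the charge cloud;
Compton sampling is off by default to mirror the ablation studies (the
analytic model accepts the same switch for like-for-like comparisons).
Flat fields land photons uniformly; statistics exclude a 3-element
border.  Seeded runs are bit-reproducible.

What MC agreement does and does not show: the simulator shares the
analytic chain's physics parameters (kernels, f_K, p_K), so agreement
validates the covariance/NPS/aliasing mathematics and the counting
statistics — not the underlying interaction physics, which is validated
separately against published attenuation-derived quantities and bench
kernel radii.  Real detectors add effects deliberately out of scope:
pulse pile-up, threshold dispersion, incomplete charge collection,
small-pixel weighting-potential effects, and Compton reabsorption.

## Problem sizes and tolerances

Default analysis sizes (chosen for converged results on a single CPU):
12 fluence-quantile energy nodes per spectrum; lag grids of 16–64 cells
per pitch (≤ 8 μm); fluorescence relocation quadrature of 12 radial
quantiles × 3 octant angles with dihedral symmetrization; 16 Compton
recoil nodes.  Doubling any of these moves DQE(0) by < 0.001.  Monte
Carlo defaults in the tests use 64×64-element grids with 10⁴–10⁵ photons
per image and ~100 images per ensemble; periodogram agreement is asserted
within 3× the sampling standard error plus a 3% systematic allowance.

Kernel PDE: dr = 0.25 μm, CFL safety 0.4; kernel integral conserved to
10⁻⁴; projection grid 0.5 μm with ≥8 samples inside the HWHM enforced.
Covariance boundary decay is < 10⁻⁶ of the zero-lag value at the default
extents; relocation displacements are clamped to 85% of the grid
half-extent (conserving counts, slightly compressing the outermost ~2% of
relocation mass).

## Known limitations

* Idealized detector: no pile-up, threshold dispersion, trapping, or
  weighting-potential effects; results are upper bounds on performance.
* Single mean K-emission energy per element; no L fluorescence.
* One kernel per (energy, geometry) at the full-thickness drift time;
  no depth-resolved kernel family.
* The tube model is semi-empirical; its spectra match the RQA mean
  energies but are not certified RQA realizations.
* The (μe, t_drift) calibration fit is ridge-degenerate by construction;
  only μe·t_drift and σe are identifiable from a single spectrum.
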