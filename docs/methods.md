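# Methods

## Scope and model chain

`bnctbeam` evaluates candidate epithermal neutron beams for BNCT in three
tiers: in-air physical figures of merit at the beam port, radiobiological
outcome (UTCP) in a cylindrical mucosa phantom, and out-of-field organ
dosimetry on a simplified whole-body model.  The package contains no
neutron transport: all spatially resolved inputs come from the synthetic
beamline module, an analytic kernel family built to have the structure —
and only the structure — that the analysis tiers assume.

## Energy bands and in-air figures of merit

Neutron energies divide into thermal (E < 0.5 eV), epithermal
(0.5 eV ≤ E ≤ 10 keV) and fast (E > 10 keV); both boundaries belong to the
epithermal band, matching the convention that thermal and fast are defined
by strict inequalities.  Spectra are stored as per-bin tallies on a
log-spaced energy grid; band integrals classify each bin wholly by its
geometric-mean center (no partial-bin splitting), which converges to the
continuum value as the grid refines and keeps the operation exactly
invertible by a per-bin loop.

The five figures of merit are formed directly from the tallies:
φ_epi; φ_th/φ_epi; Ḋ_fast/φ_epi; Ḋ_γ/φ_epi; J/φ_epi.  J is the *total*
directed neutron current over the port (all energy bins), a deliberate
resolution of an ambiguity in common usage; users needing a different
convention can construct `BeamSpectrum.current_per_bin` accordingly.  The
gamma and fast dose tallies are accepted as scalars because kerma-factor
tables are facility-specific; `fom.apply_kerma` folds a user-supplied
per-bin kerma table with the flux when energy-resolved tallies are
preferred.  Compliance uses strict inequalities against the recommended
limits (>10⁹ cm⁻² s⁻¹, <0.05, <2·10⁻¹³ cm² Gy ×2, >0.7), all overridable.

## Dose components and weighting

A BNCT dose separates into boron (n,α), thermal-neutron nitrogen capture
(n,p), fast recoil (n,n′) and gamma components.  Component dose rates are
in Gy/min, with the boron component stored *per ppm of ¹⁰B* so tissue
boron concentrations (blood 15, mucosa 30, tumor 52.5, skin 22.5,
kidneys 75 ppm; bladder wall 15 ppm — boron in urine acts only over the
~10 µm particle range and is excluded) are applied at weighting time.

Two conversions are shipped:

* **Fixed RBE/CBE** (Gy-Eq): D_w = RBE_γ·D_γ + RBE_n·(D_th + D_fast) +
  CBE·D_B.  One RBE_n covers both neutron components because standard
  tissue tables list a single neutron factor.  With all factors 1 the
  weighted dose equals the absorbed total (tested).
* **ICRP equivalent dose** (Sv): photon weight 1, boron weight 20, and the
  continuous three-piece log-normal neutron weighting w_R(E) of ICRP 103
  (peak ≈ 20.7 near 1 MeV; the published pieces meet to within ~0.05%,
  which is the continuity tolerance the tests assert).  The neutron dose
  may be energy-resolved; otherwise the thermal component is weighted at
  0.0253 eV and the fast component at a caller-supplied mean-energy proxy,
  and omitting that proxy is an error rather than a silent default.

The photon iso-effective dose model used in clinical BNCT planning is not
reimplemented; the pipeline's conversion step (`weighted_rate_field`) is a
plain function that can be swapped for any per-voxel converter with the
same signature.  Fixed-RBE weighting is the shipped default.

## Radiobiological models

TCP uses the Poisson / linear-quadratic form for inhomogeneous dose,
exp(−Σ ρ vᵢ exp(−αDᵢ − βDᵢ²)).  It is exactly invariant under voxel
subdivision and reduces to the single-voxel closed form for uniform dose
(both tested).  NTCP is the standard logistic parameterisation
1/(1 + exp(4γ₅₀(1 − D/D₅₀))) evaluated at the healthy-tissue limiting
point — the mucosa voxel with the highest weighted dose rate — rather than
at a mucosa DVH reduction, matching clinical practice of prescribing to a
dose-limiting point.

Defaults: α = 0.35 Gy⁻¹, β = 0.035 Gy⁻² (α/β = 10 Gy), clonogen density
ρ = 10⁷ cm⁻³, D₅₀ = 7 Gy-Eq, γ₅₀ = 2.  These are representative
head-and-neck values on the weighted-dose scale, chosen once as the
package defaults; the clinically published TCP/NTCP parameter sets are not
in the open literature in closed form, so both models take their
parameters from configuration and any published set can be loaded.

UTCP(t) = TCP(t)·(1 − NTCP(t)) with dose linear in time (constant dose
rates over a single-field irradiation; two-fraction plans are modelled as
a weighted sum of field dose-rate maps with no inter-fraction repair).
The optimiser is an exhaustive search on a uniform 0.5-minute grid
followed by golden-section refinement within one grid step; ties always
resolve to the smaller time.  When TCP is non-decreasing and NTCP
non-decreasing with NTCP(∞) = 1, UTCP is unimodal and the grid+refine
result coincides with exhaustive search (tested against a brute-force
oracle).  An all-zero tumor dose rate leaves TCP flat at exp(−ρV); the
result is still returned, flagged with `flat_tcp_warning`.

DVHs are cumulative (fraction of structure volume receiving at least each
threshold, equal voxel volumes), computed by binary search on the sorted
dose array and verified against a per-threshold counting loop.

## Synthetic beamline

The generator emulates four structural features of a realistic
accelerator-based epithermal beam; defaults describe the selected-beam
study conditions (φ_epi ≈ 1.08·10⁹ cm⁻² s⁻¹, φ_th/φ_epi ≈ 0.009,
Ḋ_fast/φ_epi ≈ 9.5·10⁻¹³ and Ḋ_γ/φ_epi ≈ 4.2·10⁻¹³ cm² Gy,
J/φ_epi = 0.74, 6 cm port).

* **Spectrum**: thermal Maxwellian at 293 K, epithermal 1/E slowing-down
  spectrum modulated by a log-normal bump (log-width 1) at the peak energy
  (default 1 keV, the moderator design target), fast exponential tail
  (e-folding 150 keV).  Each part is truncated to its own band and
  renormalised to the requested band fraction, so generated fractions are
  exact on any grid that covers the bands — also under the optional
  per-bin log-normal noise, which is renormalised per band.  The
  per-lethargy spectral mode is estimated with log-log parabolic sub-bin
  refinement; without it, a peak lying exactly on a bin edge (1 keV does,
  on decade-aligned grids) would be reported half a bin away.
* **Radial profile**: 1/(1 + ripple·(r/R)²) inside the port — the in-beam
  max/min ratio is exactly 1 + ripple (default 0.2) — continued outside by
  an exponential with 1 cm length: continuous, strictly decreasing, (0, 1].
* **In-phantom deposition**: separable depth × lateral kernels on the
  cylinder (axis = beam axis, depth z from the irradiated face, voxel
  centers at (i+0.5)·Δ).  The thermal/boron depth shape is a difference of
  exponentials e^(−z/λ_fall) − e^(−z/λ_rise) (λ_rise = 0.8 cm,
  λ_fall = 6 cm), zero at the surface with a closed-form maximum at
  z* = λ_r λ_f/(λ_f − λ_r) · ln(λ_f/λ_r) ≈ 1.86 cm, against which the
  voxelised argmax is tested to within one voxel.  Fast and gamma
  components attenuate exponentially (4 cm, 15 cm).  The lateral shape is
  the port disk convolved with a 1 cm Gaussian, evaluated by stable
  quadrature with the exponentially scaled Bessel function I₀.  Surface
  normalisations (2.75·10⁻³ Gy/min/ppm boron, 1.2·10⁻², 8·10⁻³,
  3·10⁻² Gy/min) are quoted at a reference total flux of 10⁹ cm⁻² s⁻¹ and
  chosen so the limiting-point component mix approximates the clinical
  62/9/6/23% (boron/thermal/fast/gamma) pattern and treatment times and
  mucosa doses come out at clinical magnitudes (tens of minutes, ~6 Gy-Eq).
  Neutron-driven components scale with total flux, the gamma component
  with the gamma tally, so beam-intensity scaling is exactly linear and a
  switched-off beam deposits nothing.
* **Organ doses**: organ-averaged components decay exponentially with the
  organ centroid's distance from the field (length 20 cm, set so
  head-region organs exceed pelvic organs by the ~20× spread seen in
  whole-body BNCT dosimetry); the mean neutron energy softens toward the
  thermal floor with a 30 cm length, feeding the w_R weighting.  The
  19-organ default set uses distinct distances down the body axis of a
  stylised adult; organ volume is carried as metadata only.  Optional
  log-normal noise is seeded and off by default.

What the generator does *not* emulate: cross-sections, spectral change
with depth, scatter between organs, anatomical heterogeneity, and any
coupling between beam spectrum and kernel shapes.  Green tests therefore
certify the analysis chain (band accounting, weighting arithmetic, outcome
models, optimisation, ranking) on inputs with realistic structure — they
do not validate transport accuracy on real beams.

## Out-of-beam safety ranking

Organ tables are assembled at the UTCP-optimal time; organs missing from
the tissue table take generic factors (RBE_γ = 1, RBE_n = 3.2, CBE = 1.3,
15 ppm).  The table's DH column is mapped to the thermal-capture
component — the acronym is ambiguous in common usage (thermal capture vs
hydrogen recoil), and this package fixes the former.  Optional per-organ
relative errors propagate to DEq in quadrature over the weighted
components.  The out-of-field statistic is the sum of DEq over organs not
in the in-field set (default {brain, head, pharynx, thyroid} for a head
irradiation); max and mean are selectable, and all three preserve
organ-wise dominance.  No absolute dose threshold is applied — the ranking
is comparative, minimum wins, ties broken by higher UTCP then beam id.

## Determinism and numerics

Every stochastic element draws from `numpy.random.default_rng(seed)` with
an explicit seed; noise defaults to off, so reruns are byte-identical
(tested on the serialized JSON reports, which use sorted keys and no
timestamps).  Probabilities are rendered at two decimals and figures of
merit at three significant figures in the CSV tables; all underlying JSON
values are unrounded.  Degenerate inputs fail loudly: zero epithermal flux
(undefined ratios), zero total dose (undefined percentages), empty masks,
organ lists or beam sets, voxel grids coarser than the tumor radius, and
negative times, radii or factors all raise.

Problem sizes used throughout the tests and examples — a 0.5 cm voxel grid
(40×40×48 voxels), 120-bin spectra, 19 organs, 0.5-minute time grids —
keep a full multi-beam evaluation under a second while leaving every
spatial feature (tumor, build-up peak, port edge) resolved by several
samples.
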