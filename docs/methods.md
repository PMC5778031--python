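# Methods

## Spectral estimator

The IR absorption lineshape is computed per Cartesian direction α as the
Fourier transform of the dipole-derivative autocorrelation,
A_αα(ω) ∝ ∫⟨μ̇_α(0) μ̇_α(t)⟩ e^{−iωt} dt.  We evaluate it by the
Wiener–Khinchin route: μ̇ by central differences (one-sided at the series
ends), mean removal (`detrend`, on by default, suppresses the
zero-frequency bin), then the one-sided periodogram
S(f) = (2Δt/N)|Σₙ μ̇ₙ e^{−2πifnΔt}|², mapped to the wavenumber axis
ν = f/(100c).  The overall proportionality constant is fixed by the
convention

    Σ_ν A_αα(ν) Δν = ⟨μ̇_α²⟩   (unsmoothed, per component),

a discrete Parseval sum rule that makes intensities comparable across
runs and geometries.  The periodogram of μ̇ equals the cosine transform of
the *biased* autocovariance estimator, which is guaranteed nonnegative.
An optional Hann window is available but off by default; no quantum
(harmonic) correction factor is applied — the hook exists but defaults to
identity, since the classical generator makes no claim about nuclear
quantum effects.

Numerical consequences a user should know:

* central differences attenuate a spectral line at angular frequency ω by
  (sin ωΔt / ωΔt)²; at 3400 cm⁻¹ with Δt = 1 fs sampling this is ≈3%,
* a pure cosine at ν₀ is recovered at the argmax within one grid spacing
  Δν = 1/(100c·NΔt),
* an Ornstein–Uhlenbeck μ̇ with SD σ and correlation time τ has the
  analytic one-sided spectrum 4σ²τ·100c/(1+(2πfτ)²) in these units
  (`protir.spectra.ou_lorentzian`), used as the estimator's oracle.

Smoothing convolves each component on the uniform ν grid with a
normalized Gaussian of SD σ_ν (default 50 cm⁻¹, the visualization width)
using reflective edges, which preserves band integrals to better than
1e-6 and never introduces negative values.  Smoothing is applied after
segment averaging.  Segment statistics: spectra of NVE segments sharing a
grid are averaged componentwise; the standard error over segments is
reported per component.  For uniaxial systems A_xy = (A_xx + A_yy)/2 and
the half difference |A_xx − A_yy|/2 is the equivalent-direction error
estimate.  Band anisotropy is the trapezoidal integral ratio
∫A_zz dν / ∫A_xy dν over a stated window (1800–2200 cm⁻¹ for the
continuum band), +∞-flagged if the denominator vanishes.

## Dipole models and defect tracking

Two charge models build μ(t) = Σ qᵢ rᵢ(t):

* `nuclear_effective`: nuclei only, q_H = +1e, q_O = −2e.  Every water is
  neutral and one excess proton carries exactly +1e.  This overestimates
  the neutral-water dipole (and hence the molecular bands) but gives the
  defect the correct charge.
* `wannier_full`: valence cores O +6e, H +1e plus −2e per Wannier center
  (four electron pairs per water), adding electronic polarization.

Hydrogens and Wannier centers are re-assigned to their nearest oxygen on
every frame (ties to the lower atom index; centers farther than 1 Å from
any O are flagged, not fatal).  No bond topology is remembered between
frames — geometric re-assignment is the standard tracker for a defect
that migrates by hydrogen-bond rearrangement.  The hydronium is the
unique O with three assigned H (zero → neutral frame, two or more → a
defect-multiplicity error signalling an unphysical frame).  The shared
proton H* is the hydronium H minimizing δ = |d(O₁–H*) − d(O₂–H*)| with O₂
its nearest foreign oxygen; the state is classified Zundel-like when
δ < 0.25 Å (configurable; 0.25 Å is a common Zundel/Eigen discriminator —
the choice is a package convention, and the toy generator below is
Eigen-dominated under it because its hydronium hydrogens are harmonically
bound).  Subgroup spectra select, per frame, the O₂H₅⁺ sites (and their
assigned Wannier centers); selections with net charge are referenced to
the selection's instantaneous geometric center of the nuclei, which makes
the +1e subgroup dipole translation independent.  Cross-correlations
between subgroup and remainder are excluded by construction — the
subgroup spectrum is the autocorrelation of the subgroup dipole alone.

## Synthetic-data generator

The generator emulates the study conditions at desk scale; it makes no
claim of reproducing ab initio band shapes.

**Clusters.** 15-water chains (O spaced 2.7 Å along z, one O–H donated to
the next oxygen, azimuths randomized), 15-water discs (triangular lattice,
2.8 Å), 26-water droplets (compact cubic packing, 2.9 Å), all with
seeded random orientations.  Protonation adds one H 1.0 Å from the most
central oxygen on its lone-pair side.  Harmonic confinement acts on
oxygens only: K_xy = 2000 (narrow chain) / 20 (wide chain),
K_z = 2000 with K_xy = 30 (disc), K_r = 40 (droplet), all in
kJ mol⁻¹ nm⁻².

**Force field.** Flexible water with harmonic O–H bonds
(r₀ = 0.9572 Å, k = 3890 kJ mol⁻¹ Å⁻²) and harmonic H–O–H angles
(θ₀ = 104.52°, k = 413 kJ mol⁻¹ rad⁻²), SPC-like charges
(q_O = −0.82e, q_H = +0.41e; the hydronium stand-in uses −0.5/+0.5 for a
net +1e), Lennard-Jones on oxygen (σ = 3.166 Å, ε = 0.65 kJ mol⁻¹), no
cutoffs (small non-periodic clusters).  The spring constants were set by
normal-mode analysis of a single water so the bend sits at 1645 cm⁻¹ and
the stretches at 3377/3425 cm⁻¹; `water_normal_modes()` recomputes these
from the force-field Hessian and is the oracle the band-position tests
use.  Internal units are amu, Å, fs, e (1 amu Å² fs⁻² = 10⁴ kJ mol⁻¹).

**Protocol.** Velocities are drawn at T = 300 K; a BAOAB Langevin
thermostat (friction 0.02 fs⁻¹) equilibrates the cluster, then
velocity-Verlet NVE segments are launched from successive snapshots of
the continuing thermostatted run, Δt = 0.5 fs, frames recorded every
second step (1 fs sampling, Nyquist far above the stretch band).  The
full-scale protocol is 15 ps equilibration and 26 × 5 ps segments; the
package's desk-scale default used in the analysis scripts and tests is
2 ps equilibration and four 2 ps segments, which resolves the continuum
window at Δν ≈ 17 cm⁻¹ before smoothing.  NVE drift is defined as the
difference of 10%-window means of total energy at either end of a
segment, normalized by mean kinetic energy — windowing separates genuine
drift from the bounded energy oscillation of the symplectic integrator.
A velocity guard (0.5 Å/fs) raises a stability error suggesting a
smaller timestep.

**Proton-hop emulator.** The continuum band is emulated, not simulated:
a +1e defect charge occupies an oxygen site and performs Poisson-timed
hops (default rate 20 ps⁻¹) to an adjacent oxygen — the z-neighbour for
chains (reflecting at the ends), an in-plane neighbour for discs, any
neighbour within 3.5 Å for droplets — moving linearly over a transit
time drawn uniformly from 5–20 fs.  Short transits put the injected
dipole power exactly in the 1800–2200 cm⁻¹ window (a 2.7 Å glide over τ
carries the sinc²(πfτ) energy spectrum).  The defect dipole is referenced
to the instantaneous oxygen centroid and projected onto the policy's axis
subspace, so a chain defect has strictly zero x,y dipole components and a
disc defect zero z.  The emulator models only the defect's translational
dipole; electronic amplification of the continuum (the n+e vs n
comparison) is exercised structurally through the two charge-model paths,
not quantitatively.

**Synthetic Wannier centers.** Per water: two bond centers 0.5 Å from O
along each O–H bond and two lone-pair centers 0.3 Å from O along ± the
HOH-plane normal (three bond centers and one counter-bisector lone pair
for hydronium), optional seeded Gaussian jitter.  The template keeps every
molecule's wannier_full charge at 0 (+1 for hydronium); its closed-form
dipole is asserted to 1e-10 in the tests.  Note the template is a
bookkeeping fixture: its neutral-water dipole is small and points toward
the oxygen side, unlike real water — downstream code only relies on
counts, assignment, and charge sums.

**What passing tests do not show.**  The generator has harmonic
intramolecular dynamics (no Grotthuss chemistry, no proton rattling
between hops, no polarizability, no nuclear quantum effects), so the
Zundel occupation of its hydronium is ~0 and its continuum band exists
only through the hop emulator.  Tests passing on this generator validate
the *pipeline* — estimator conventions, defect bookkeeping, polarization
logic — not the chemistry of real protonated water.

## ATR formalism

Two-phase (sample-as-bulk) Harrick thick-film approximation; no
three-phase thin-film Fresnel treatment and no dispersion or
Kramers–Kronig correction.  With n31 = n3/n1, s = sin²α, c2 = cos²α and
D = (1−n31²)((1+n31²)s − n31²):

    Ey² = 4c2/(1−n31²),  Ex² = 4c2(s−n31²)/D,  Ez² = 4c2·s/D.

Uniaxial film (a_x = a_y = a_xy): A_perp = Ey²a_xy and
A_par = Ex²a_xy + Ez²a_z, inverted as A_xy = A_perp/Ey² and
A_z = (A_par − (Ex²/Ey²)A_perp)/Ez², normalized so an isotropic absorber
gives A_xy = A_z.  The isotropic dichroic ratio
R = (Ex²+Ez²)/Ey² = (2s−n31²)/((1+n31²)s−n31²) is strictly decreasing in
α from 1/n31² (at the critical angle) to 2−n31² (grazing), so the
incidence angle is recovered by bracketed root-finding (Brent, 1e-6 deg).
Shipped index constants: n_Si = 3.42 and n_water = 1.32 (standard mid-IR
values, used for the angle calibration) and n = 1.6 for a rehydrated
membrane protein film.  At R = 2.1 the root is 39.05°; since the
measured ratio is itself quoted to one decimal, the angle is meaningful
to the nearest degree.  The sensitivity scan re-resolves the spectra over
α ∈ {37°, 39°, 41°} × n ∈ {1.5, 1.6, 1.7} and reports maximum deviations
from the reference geometry.

## Design choices and degenerate inputs

* File formats: multi-frame XYZ / extended XYZ (Wannier centers inline as
  `X` pseudo-atoms or as a parallel block file — both CP2K-style dialects
  are treated as equivalent), spectra and absorbances as CSV with fixed
  headers, configuration as YAML.  Coordinates are Å, times fs,
  wavenumbers cm⁻¹; non-periodic systems only.  Readers never reorder
  frames or atoms and report malformed blocks by 1-based frame index.
* Equidistant H between two O resolves to the lower atom index; an empty
  site selection, a sub-16-sample series, a nonuniform time grid, an
  empty spectrum table, mismatched grids, and sub-critical ATR angles all
  raise immediately with specific errors rather than propagating NaNs.
* Statistical error of the droplet-isotropy check: the pointwise bound
  |A_zz − A_xy| ≤ 3·|A_xx − A_yy|/2 is not a calibrated test (for
  independent equal-variance components it holds with probability
  exactly (2/π)·arctan√3 = 2/3 regardless of averaging depth), so the
  isotropy test combines the per-segment equivalent-direction spread into
  a standard error of the z−xy difference and checks 3σ coverage.
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence` substreams; identical config + seed gives
  byte-identical outputs, and manifests record seed, config hash and
  SHA-256 checksums.

## Known limitations

Toy dynamics (see above); hop-emulator defects do not back-react on the
waters; the Zundel-subgroup projection is a geometric-selection stand-in
for a full projection formalism and omits subgroup–environment
cross-terms; the ATR model ignores film-thickness interference and
optical dispersion; absorbance scale is per unit effective path (fixed
only up to the isotropy normalization).
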