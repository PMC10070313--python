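# Methods

## Scope and model

`lh2exciton` models the Qy excitons of LH2 antenna rings.  Pigments are
point sites with transition dipoles; the aggregate Hamiltonian is a real
symmetric matrix over N_p locally excited states plus N_CT charge-transfer
(CT) states restricted to adjacent pigment pairs of the αβ (B850) ring.
CT–CT couplings are zero and CT states carry no transition dipole and no
rotational strength — the standard dark-CT approximation.  All energies are
cm⁻¹, coordinates Å, dipoles Debye, temperatures K, times fs; units are
fixed and never configurable.

## Geometry

Idealized rings are exactly C_n-symmetric: a per-unit specification (radial,
angular, axial offsets; dipole polar/azimuth in the co-rotating local frame)
is replicated by rotation.  For the packaged two-ring LH2 geometries the
2n-membered B850 ring is uniform with nearest-neighbor spacing 9.2 Å (the
Mg–Mg distance scale of LH2 structures), giving radii of ~20.7 Å (n = 7) and
~26.4 Å (n = 9); α and β dipoles are tangential and antiparallel with an
alternating out-of-plane tilt of ±0.15 rad.  The tilt matters only for CD:
perfectly in-plane dipoles of a flat ring give identically zero rotational
strengths, while the alternating tilt produces the conservative exciton
couplet.  B800 pigments sit 5 Å outside the B850 radius and 16.5 Å below the
plane, with in-plane dipoles.  These geometric choices affect dipole
directions (hence CD shapes and dipole-strength distribution) but not the
energies, which come from the parameter bundles.

Structure files are parsed with biotite: the pigment center is the NB/ND
midpoint and the dipole axis the normalized NB→ND vector; both ATOM and
HETATM records are accepted, altloc resolved by occupancy.  Pigments are
ordered by azimuth about the principal axis of their centers with ties
broken by the axial coordinate; the starting azimuth tolerance (1e-3 rad) is
far below any pigment spacing but above coordinate-precision noise.  The
point-dipole coupling uses the vacuum constant C = 5034.1 cm⁻¹·Å³·D⁻² with
no implicit screening — published QM/MMPol couplings already include the
environment, so any screening factor must be an explicit user choice.
The O···H ≤ 2.5 Å threshold used by the hydrogen-bond occupancy summary is a
package convention for summarizing distance distributions, not a literature
value.

## Parameter bundles

Bundles carry per-class site energies, six named couplings (intra-dimer αβ,
inter-dimer αβ, αα, ββ, B800–B800, inter-ring) and optional CT parameters.
The topology places the inter-ring coupling between each B800 and the two
B850 pigments of its own repeating unit.  Site energies and the
inter-dimer/B800–B800 couplings of the packaged LH2purp and LH2acid bundles
are transcribed inputs; the remaining couplings and all CT parameters were
never published and ship as flagged defaults (`provenance: default`) with
magnitudes chosen to be structurally plausible: intra-dimer slightly above
the inter-dimer value for the heptamer, small negative second-neighbor
couplings, inter-ring couplings larger than the B800–B800 coupling.  The
quantitative analyses (site-energy differences, mixed-model site
substitution) do not depend on these defaults; analyses that do (absolute
peak positions, CT shift magnitudes) should be read as qualitative.

One effective CT state per adjacent pair is used (2n states per ring), with
energy 15300 cm⁻¹ and pair couplings of opposite sign on the two sites, so
the CT state mixes with the antisymmetric local combination that dominates
the low-energy bright excitons of a positively coupled ring.  The opposite-
sign structure is the regime choice that reproduces the observed behavior —
CT mixing red-shifts the B850 band, more strongly when the inter-dimer CT
coupling is large; the overall per-pair sign is a gauge.  Two CT states per
pair (both charge-separation directions) can be represented through the
`CTManifold` type directly.

## Disorder model

The static/dynamic separation attributes the environment effect on site
energies to static disorder: `E_static = E_env − E_vac + ⟨E_vac⟩`, which has
the mean of E_env and the standard deviation of E_env − E_vac (verified as
an ensemble contract in the tests).  Synthesized MD-like ensembles draw
per-frame site energies Normal(class mean, σ_static(class)) and couplings
Normal(base, σ_V), independently — the joint distribution of the real MD
output is unknown, and a site–site correlation matrix hook exists for future
use.  Additional per-class diagonal disorder (σ_add) is drawn on top of each
frame without touching couplings.  Default pipeline width is σ_static =
60 cm⁻¹ per class, a typical inhomogeneous width for BChl Qy bands at room
temperature; the recovery tests use 2000 realizations so the sample
standard deviation estimates σ within ~1.6% (1/√(2n)) and the 5% acceptance
band is comfortably non-trivial.  Ensembles are reproducible bitwise from
(model, seed) and serialize to plain-text matrices plus a YAML manifest.

What the synthetic ensembles do **not** emulate: non-Gaussian tails, slow
conformational substates, correlated site–coupling fluctuations, or the
frame-to-frame geometry changes that move dipole orientations.  Passing
tests therefore validate the statistical machinery and the spectroscopy
pipeline, not the fidelity of any particular MD force field.

## Lineshapes

J(ω) = Drude–Lorentz environment (2λω ω_c/(ω² + ω_c²)) plus underdamped
Brownian oscillators (2λ_j ω_j² γ_j ω/((ω² − ω_j²)² + γ_j²ω²)); each term
integrates to its reorganization energy via (1/π)∫J/ω dω.  The default
pipeline bath is λ_env = 180 cm⁻¹, ω_c = 60 cm⁻¹ with three compact
vibrational modes (340, 740, 1200 cm⁻¹) standing in for the dense BChl
intramolecular spectrum; all parameters are config-exposed.

g(t) is the standard second-order cumulant double integral with the
coth(ħω/2kT) thermal factor, evaluated by frequency quadrature.  The linear
term −λt of Im g is applied analytically because the Drude tail (∝1/ω²)
converges too slowly in quadrature; the oscillatory sin/cos transforms
converge on a grid extending to max(6·ω_max, 60·ω_c).  Per-exciton
lineshape functions use the participation approximation g_k = Σ_i c_ki⁴ g_i
(site coefficients only; CT amplitude reduces the dynamic broadening of
strongly mixed states), which yields exchange narrowing of delocalized
states.  This is a secular cumulant treatment with optional secular Redfield
lifetime broadening; full non-secular/non-Markovian corrections are an
extension point, and no packaged analysis depends on quantities sensitive to
the difference.

Spectra are computed by zero-padded FFT (≥8× padding) of the dephasing
function with trapezoidal end-correction, in a rotating frame at the mean
state energy snapped to the FFT bin grid — snapping makes a state's sampled
lineshape independent of which other states are present, so the
zero-coupling additivity limit holds to machine-interpolation precision.
Aliasing is a hard error: the time step must resolve both the highest bath
frequency and the largest detuning from the frame reference.  Default grids
(dt = 2 fs, t_max = 1.5 ps, δω = 2 cm⁻¹) resolve B850-scale linewidths; the
tests use these sizes, and a full two-complex ensemble run (≥50 frames)
takes seconds.

## Pipeline conventions

- Bright-state energy: dipole-strength-weighted mean of the two
  largest-dipole states.  For an ideal ring these are the degenerate k = ±1
  pair; the weighted mean is robust to small symmetry breaking by disorder.
- Band windows (pre-shift axis): B850 [12000, 13400] cm⁻¹, B800
  [13400, 14250] cm⁻¹, bracketing the bands produced by the packaged average
  Hamiltonians; configurable per run.
- The global shift (e.g. −980 cm⁻¹, compensating the systematic error of
  the underlying QM excitation energies) is applied once to the output
  energy axis after averaging, and recorded in the manifest.
- Ensemble absorption is normalized to its maximum, CD to its largest band
  (positive or negative); rotational strengths are therefore reported in
  model units (Å·D²·cm⁻¹ scale) without the absolute CD prefactor.
- Mixed models substitute per-class parameters of one bundle into the
  other's topology; only mode `full` changes the ring size.  Disorder-free
  average Hamiltonians are used, so mixed-model shifts are deterministic.
- Degenerate eigenpairs are returned in a fixed gauge (first significant
  coefficient positive); k labels fold ±k Fourier power and report |k|,
  with "mixed" below 0.6 dominance.

## Known limitations

- CD is conservative by construction (cross terms only); non-conservative
  contributions from higher excited states or carotenoids are out of scope.
  The ω-weighting of the couplet leaves a residual net CD of order
  linewidth/transition-energy, visible in the conservativity tests.
- No vibronic (polaron) structure, no Qx or carotenoid states, no
  fluorescence or transport observables beyond secular lifetimes.
- Absolute peak positions inherit the uncertainty of the unpublished
  coupling defaults and the QM-error shift; differences and trends between
  the two complexes are the robust outputs.
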