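# Methods

This note documents the model implemented by `vibexciton`, its assumptions,
the numerical choices, and what the synthetic inputs do and do not emulate.

## Vibronic monomer

A pigment is described by its electronic ground state and four singlet
transitions: Qy (the energy origin), Qx at ΔE = 1640 cm⁻¹, and the purely
electronic Soret transitions By/Bx at 7570 / 8740 cm⁻¹.  Transition dipole
strengths are carried as ratios to Qy (f_Qx = 0.1, f_By = 2.52,
f_Bx = 2.43); amplitudes are their square roots, and the Qy dipole magnitude
is the unit of the intensity scale.

Qy and Qx carry displaced-oscillator progressions in ten effective
intramolecular modes.  The catalog (frequencies 169–1511 cm⁻¹, total
Huang–Rhys factor 0.278) is the canonical coarse-graining of a larger
normal-mode set: consecutive frequency-sorted groups are replaced by one mode
with the summed Huang–Rhys factor and the S-weighted mean frequency
(`group_modes` implements the operation generically and rejects groups with
zero total S, whose weighted mean would be undefined).  In the Qx state the
displacement of the three lowest modes is three times the Qy value
(Huang–Rhys factors ×9), raising the intramolecular reorganization energy
from 262 cm⁻¹ (Qy) to 379 cm⁻¹ (Qx).  Displacements are never stored;
d = √(2S/ω) is derived on demand because every observable depends on the
modes only through S.  Vibrational frequencies are state-independent, and
there is no anharmonicity or Duschinsky rotation.

The vibronic coupling mode (ω_VC = 1500 cm⁻¹) is undisplaced in every
electronic state and acts only through the coordinate-linear off-diagonal
term α_VC·q̂_VC(|Qy⟩⟨Qx| + h.c.).  Working with the frequency-scaled
constant α̃_VC = α_VC/√ω_VC = 750 cm⁻¹ and the harmonic ladder rule
⟨n|q̂|n+1⟩ = √((n+1)/(2ω)), the matrix element between VC levels n and n+1
is α̃_VC·√((n+1)/2), independent of ω_VC.  Because the VC oscillator is
undisplaced, basis states with VC quanta carry no direct transition dipole
and borrow all intensity through the mixing — the mechanism that splits the
near-resonant Qy(0-1)/Qx(0-0) pair by √(ΔE−ω_VC)² + 4(α̃/√2)² ≈ 1070 cm⁻¹
into the mixed bands near +1000 and +2000 cm⁻¹.

Basis truncation: up to four VC quanta and at most one intramolecular mode
excited to its first level, including simultaneous VC + intramolecular
excitation (112 states with B included).  Both cutoffs reflect the small
Huang–Rhys factors; a test doubles the VC cutoff and requires the monomer
spectrum to change by less than 1% of its peak.  Diagonal energies are
measured from the Qy 0-0 transition; the ground-state zero-point energy
cancels from every transition frequency and is dropped.

`effective_vc_huang_rhys` reports a diagnostic effective Huang–Rhys factor
of the VC mode, defined operationally as in a Franck–Condon progression: the
summed dipole strength of eigenstates carrying the first VC satellite of the
lowest adiabat (dominant |Qy, n_VC = 1⟩ character above a 0.25 threshold)
divided by the 0-0 intensity.  It is zero without coupling, grows
quadratically with α̃ in the perturbative regime (unit-tested against the
closed-form two-level mixing angle), evaluates to ≈ 0.066 for the default
parameters — larger than any individual intramolecular factor — and enters
no downstream observable.

## Dimer in the one-particle approximation

The dimer basis is the union of the two monomer bases: one pigment excited
(with vibronic structure), the partner in its vibrational ground state.  The
inter-pigment block is V[i,j] = J(m_i, n_j)·fc_i·fc_j, where fc is the
Franck–Condon amplitude of the excited-side state from the ground state (the
de-excited partner contributes its ground-state overlap, which is unity in
this basis).  A *coupling mask* restricts which vibronic transitions couple:
`all`, `zero-zero` (only states without vibrational quanta — used to isolate
the role of vibrationally excited states in the excitonic coupling), or
`none`.

Couplings are anchored to the fitted J(Qy,Qy) = 83 cm⁻¹ and scaled as
J_mn = J_QyQy·f_m·f_n·ζ_mn/ζ_QyQy with the point-dipole orientation factor
ζ = e_m·e_n − 3(e_m·e_ab)(e_n·e_ab).  This removes the absolute dipole
magnitudes and the vacuum constant (κ = 5034 cm⁻¹·Å³/D², used only by the
optional raw point-dipole route) from the default pathway; no screening
factor is applied.  Short-range/exchange contributions are neglected.

Magnetic transition dipoles are m = i·R_pigment × μ with unit
proportionality constant, so CD is reported in relative units; the small
intrinsic single-pigment CD is neglected (a localized state has
μ·(R×μ) = 0 identically, which also makes the total rotational strength
vanish exactly and the computed CD origin-independent — both are enforced by
tests).

When the inter-pigment block vanishes exactly, the two blocks are
diagonalized separately.  This keeps the degenerate eigenstates of identical
uncoupled pigments localized, which is the physically correct limit for
independent per-pigment baths (an arbitrary rotation within the degenerate
subspace would change the exciton–bath weights γ; static disorder removes
the degeneracy in all non-trivial runs).

## Bath, line broadening, lifetimes

The low-frequency environment enters through a two-term super-Ohmic spectral
density J(ω) = Σ_k s_k ω³/(7!·2·ω_k⁴)·exp(−√(ω/ω_k)) with s₁ = 0.402,
s₂ = 0.398, ω₁ = 0.557 cm⁻¹, ω₂ = 1.94 cm⁻¹.  This normalisation makes
∫J dω = s₁+s₂ = 0.800 (the total bath Huang–Rhys factor) exactly and the
reorganization energy λ = 72(s₁ω₁+s₂ω₂) ≈ 71.7 cm⁻¹ — the printed parameter
pairs are only consistent with this convention, which is verified by a unit
test.  Each pigment couples to its own, statistically identical bath,
diagonally in the local electronic basis and equally for all its excited
states; in the exciton basis this gives the weights
γ_αββα = Σ_pigments (⟨α|P_pigment|β⟩)², whose diagonal is the inverse
participation ratio over pigments (1 for a monomer, 1/2 for a delocalized
homodimer state).

Observables use the closed-form lineshape: per exciton state,
exp(γ_αααα(G(t)−G(0)))·exp(−iω̃_α t)·exp(−t/τ_α), with

* G(t) = ∫J(ω)[(1+n(ω))e^(−iωt) + n(ω)e^(iωt)]dω (zero-phonon line plus
  phonon wing; G(0) is the coth-weighted bath Huang–Rhys factor, ≈ 9.3 at
  300 K, so room-temperature lines are wing-dominated);
* ω̃_α = ω_α − γ_αααα·λ + Σ_{β≠α} γ_αββα·Im C̃(ω_αβ);
* τ_α from Γ_αβ = 2γ_αββα·Re C̃(ω_αβ), with
  Re C̃(ω) = π ω²(1+n(ω))(J(ω)−J(−ω)), which obeys detailed balance, and
  Im C̃ from the principal-value (Kramers–Kronig) transform of Re C̃.

Frequencies are treated as angular (ħ = 1): a rate Γ in cm⁻¹ is a Lorentzian
half-width, and τ[fs] = 1/(2πc·HWHM).  The absolute prefactor linking C̃ to
J is a convention choice (the standard one for this spectral density); it is
validated against a time-domain quadrature oracle and by the qualitative
anchors (the upper 0-0 exciton state of the dimer relaxes in ≈ 50 fs, far
faster than the mixed Qy–Qx states whose inter-pigment coupling is
Franck–Condon-suppressed).  Absolute homogeneous widths therefore carry this
convention.

Numerics: Re C̃ is evaluated in closed form; Im C̃ is tabulated once by a
singularity-subtracted principal-value sum on a 0.25 cm⁻¹ grid over the bath
support (±2500 cm⁻¹) and interpolated (cross-checked against adaptive
quadrature to 2×10⁻³ relative).  G(t) is computed by trapezoid quadrature on
a graded frequency grid (relative error ~10⁻⁴ against adaptive quadrature)
and cached per (bath, temperature, grid).

The dephasing time is capped at 3 ps by default.  The cap matters only for
states with no bath relaxation channel — all monomer states, and the Soret
excitons, whose gaps to the Q band (≈ 7500 cm⁻¹) lie far outside the bath
support.  A 1.8 cm⁻¹ half-width floor is negligible against every other
broadening in the model (the B states alone carry 1800 cm⁻¹ of
inhomogeneous width) and guarantees that correlation functions decay on the
default time grid; a longer cap is config-exposed.

## Spectra, grids, disorder

Internally time is measured in cm, conjugate to cm⁻¹ under e^(2πiνt).  The
default grid has 2¹⁵ points with dt = 1/16384 cm: 0.5 cm⁻¹ resolution and a
±8192 cm⁻¹ Nyquist range around a rotating-frame center chosen from the
undisordered eigenvalue range, wide enough for the B band plus disorder
tails.  One-sided FFTs with a half-weighted first sample give
σ_abs = Re{∫e^(iωt)C_abs} and σ_CD = Im{∫e^(iωt)C_CD}; on-grid the
absorption integral equals C_abs(0)/2 exactly, which is the lever for the
sum-rule tests.  Exciton states whose absorption *and* rotational weights
are below 10⁻⁷ of the respective maxima are skipped; the sum rules are
conserved to that accuracy.  A warning is emitted if a correlation function
has not decayed to 10⁻⁴ of its reference amplitude at the end of the grid
(for CD the reference is the incoherent sum of |rotational strengths|, since
the coherent t = 0 value vanishes by the sum rule).

Site-energy disorder adds an independent Gaussian draw per pigment and per
electronic state (FWHM presets: Qy/Qx = 240/720 cm⁻¹ for the solvated
monomer, 170/340 cm⁻¹ for the protein-bound dimer, 1800 cm⁻¹ for By/Bx
whenever B states are included).  Shifts enter the Hamiltonian diagonal
*before* diagonalization, so a realization with detuned sites genuinely
localizes the exciton states — the mechanism behind the disorder-induced
suppression of the high-energy CD, quantified by the ratio of integrated
|CD| above +500 cm⁻¹ to the 0-0 region (drops by ≳2.5× at 1000 samples for
the dimer preset).  A correlated mode (one draw per pigment scaled by the
FWHM ratios) is config-selectable but off by default, as the per-state
widths are quoted independently.  Averages are deterministic for a fixed
seed.

## Synthetic geometry

The canonical test geometry is a parametric "open sandwich" dimer: pigment B
is a rigid rotation (z-x-z Euler angles) of pigment A with its center at a
configurable distance and direction.  Dipole frames follow the nitrogen
convention: Qy/By along the N_D→N_B axis, Qx/Bx along the negative
N_C→N_A axis, each rotated in the ring plane by (−7°, 20°, 20°, −20°).  The
default angles were calibrated once, by least squares, so that couplings
scaled from J(Qy,Qy) = 83 cm⁻¹ reproduce the reference coupling table of
the protein-bound chlorophyll-a dimer — the Q-band couplings
(J_QxQx = −2.8, J_QxQy = 4.9 cm⁻¹) within 5%, most B-band couplings within
a few percent (worst: J_BxBx, 28%) — while the Qy dipoles subtend
cos θ = 0.8, putting 90% of the 0-0 dipole strength into the upper exciton
state.  The sign conventions (x-axis sense, rotation direction, center
direction) are fixed by this calibration plus the requirement of a positive
high-energy / negative low-energy 0-0 CD couplet; only relative orientations
are observable.  The coupling table under-determines the full geometry, so
the fixture is *a* realisation consistent with it, not a crystal structure:
real coordinates can be supplied as a TSV nitrogen table or a PDB file
(CLA/CHL residues, atoms NA–ND, ring center = nitrogen mean).

What the synthetic inputs do not emulate: real site-to-site asymmetries of
the protein, non-Gaussian disorder, correlated pigment–pigment fluctuations,
vibrations in the electronic ground state of the de-excited pigment
(two-particle terms), and the quantum-chemical magnitudes of transition
dipoles.  Passing tests therefore validate the mechanisms (vibronic mixing,
intensity redistribution, disorder localisation, CD sum rules) rather than
absolute agreement with any measured spectrum.

## Known limitations

* Absorption is in relative dipole-strength units and CD in relative
  rotational-strength units; no absolute extinction scale is computed.
* The homogeneous linewidth scale depends on the C̃ prefactor convention
  (above); relative widths and detailed balance are convention-free.
* No density-matrix propagation: observables come from the closed-form
  correlation functions, which is exact for linear spectra within the model
  but provides no kinetics beyond the lifetime rates.
* The one-particle approximation omits ground-state vibrational resonances
  that would mainly reshape the sideband region.
* The Qx intramolecular reorganization energy from the shipped (rounded)
  mode table evaluates to 378.9 cm⁻¹; quoting 379 or "≈380" both refer to
  the same catalog.
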