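# vibexciton

Absorption and circular-dichroism (CD) spectra of chlorophyll-like pigments
and strongly coupled pigment dimers from a vibronic Frenkel-exciton model.

Chlorophyll *a* has two low-energy singlet transitions, Q<sub>y</sub>
(S<sub>0</sub>→S<sub>1</sub>) and Q<sub>x</sub> (S<sub>0</sub>→S<sub>2</sub>),
polarised along roughly orthogonal in-plane axes, plus the Soret transitions
B<sub>y</sub>/B<sub>x</sub> at higher energy.  Because the 0-1 vibrational
satellite of Q<sub>y</sub> is nearly resonant with the 0-0 line of
Q<sub>x</sub>, a single non-adiabatic *vibronic coupling mode* — linear in
its coordinate, like the coupling mode of a conical intersection — mixes the
two transitions and splits the sideband into bands near +1000 and
+2000 cm⁻¹ above the Q<sub>y</sub> origin.  In a strongly coupled dimer
(the model system is the chlorophyll-*a* pair of the water-soluble
chlorophyll-binding protein, WSCP) the same vibronic structure interacts with
inter-pigment excitonic coupling: oscillator strength is redistributed to
the upper 0-0 exciton state, and Gaussian site-energy disorder localises the
weakly coupled vibronic transitions, which suppresses the high-energy part of
the CD spectrum.  This package implements that model end-to-end and makes
every mechanism individually switchable.

## Model

* **Monomer.**  Electronic states m ∈ {Q<sub>y</sub>, Q<sub>x</sub>,
  B<sub>y</sub>, B<sub>x</sub>} with 0-0 energies ε_m; ten effective
  intramolecular modes (ω_i, S_i) giving Franck–Condon progressions for
  Q<sub>y</sub>/Q<sub>x</sub> (B states are purely electronic); a vibronic
  coupling mode ω_VC = 1500 cm⁻¹ coupling |Q<sub>y</sub>⟩ and
  |Q<sub>x</sub>⟩ through α̃_VC·q̂_VC with α̃_VC = 750 cm⁻¹.  The truncated
  basis allows up to four VC quanta and one quantum in one intramolecular
  mode (112 states with B included).
* **Dimer.**  One-particle approximation: products of one excited vibronic
  monomer state with the partner's vibrational ground state.  Electronic
  couplings J_mn are anchored to the fitted J(Q<sub>y</sub>,Q<sub>y</sub>) =
  83 cm⁻¹ and scaled by transition-dipole ratios and point-dipole orientation
  factors ζ; the off-diagonal blocks carry the Franck–Condon amplitudes of
  both excited-side states.
* **Lineshape.**  A two-term super-Ohmic bath spectral density (total
  Huang–Rhys factor 0.8, reorganization energy ≈ 72 cm⁻¹) provides the
  line-broadening function G(t), renormalized exciton energies, and
  lifetime-broadening rates Γ_αβ = 2 γ_αββα Re C̃(ω_αβ) obeying detailed
  balance.  Spectra are one-sided Fourier transforms of
  Σ_α w_α · e^(−iω̃_α t) · e^(G_α(t)−G_α(0)) · e^(−t/τ_α), with w_α the
  dipole strength (absorption) or rotational strength Im(**μ**_α·**m**_α)
  (CD, with **m** = i**R**×**μ**).
* **Disorder.**  Site energies of every pigment and electronic state are
  shifted by independent Gaussian draws (per-state FWHM), the system is
  re-diagonalized per realization, and spectra are Monte-Carlo averaged.

## Worked example

```python
import numpy as np
import vibexciton as vx

cfg = vx.preset_config("wscp")          # chlorophyll-a dimer in WSCP
system = vx.build_system(cfg)           # 224-state vibronic exciton system
engine = vx.build_engine(cfg)

couplings = vx.build_couplings(cfg)
print(f"J(Qy,Qy) = {couplings.get('Qy','Qy'):6.1f} cm^-1   "
      f"J(Qx,Qx) = {couplings.get('Qx','Qx'):5.1f} cm^-1   "
      f"J(Qx,Qy) = {couplings.get('Qx','Qy'):4.1f} cm^-1")

dec = vx.diagonalize(system)
terms = engine.lineshape_terms(dec)
mask00 = np.array([b.electronic == "Qy" and b.vibrationless
                   for b in system.basis])
char00 = (dec.coefficients[mask00, :] ** 2).sum(axis=0)
lo, hi = sorted(np.argsort(char00)[-2:], key=lambda i: dec.energies[i])
ds = dec.dipole_strength
print(f"0-0 exciton pair: E = {dec.energies[lo]:7.1f} / "
      f"{dec.energies[hi]:7.1f} cm^-1 "
      f"(splitting {dec.energies[hi] - dec.energies[lo]:5.1f} cm^-1)")
print(f"upper-state share of 0-0 dipole strength: {ds[hi]/(ds[lo]+ds[hi]):.2f}")
print(f"lifetime broadening (HWHM): lower {terms.dephasing_hwhm[lo]:5.1f}, "
      f"upper {terms.dephasing_hwhm[hi]:5.1f} cm^-1 "
      f"(tau = {terms.tau_fs[hi]:.0f} fs)")

hom = engine.spectrum(system)                                  # homogeneous
avg = vx.disorder_average(engine, system, vx.build_disorder(cfg),
                          n_samples=200, seed=7)               # averaged
print(f"CD sideband/origin ratio: homogeneous {vx.cd_sideband_ratio(hom):.2f}, "
      f"disorder-averaged {vx.cd_sideband_ratio(avg):.2f}")
```

which prints:

```
J(Qy,Qy) =   83.0 cm^-1   J(Qx,Qx) =  -2.7 cm^-1   J(Qx,Qy) =  4.8 cm^-1
0-0 exciton pair: E =  -157.2 /   -35.6 cm^-1 (splitting 121.5 cm^-1)
upper-state share of 0-0 dipole strength: 0.88
lifetime broadening (HWHM): lower  60.9, upper 109.4 cm^-1 (tau = 49 fs)
CD sideband/origin ratio: homogeneous 5.13, disorder-averaged 2.01
```

Reading the numbers: the synthetic open-sandwich geometry reproduces the
dimer coupling table scaled from J(Q<sub>y</sub>,Q<sub>y</sub>) = 83 cm⁻¹;
the two 0-0 exciton states are split by ≈ 122 cm⁻¹ (2J dressed by the
Franck–Condon factor e^(−ΣS)), the upper one carries ~90% of the 0-0 dipole
strength and relaxes in ~50 fs, hence is strongly lifetime-broadened; and
already 200 disorder realizations halve the relative CD intensity of the
vibronic sideband region — the disorder-localisation mechanism that empties
the high-energy CD.

Energies are reported relative to the nominal Q<sub>y</sub> 0-0 line
(`vx.wavenumber_to_nm(14940)` → 669.3 nm for the WSCP preset anchor).

## Command line

```bash
vibexciton monomer --out out/           # ether preset, disorder-averaged
vibexciton dimer --samples 1000 --seed 7 --out out/
vibexciton dimer --coupling-mask zero-zero --out out/   # 0-0 couplings only
vibexciton ablation --variant vibronic --variant full --out out/
```

Each run writes a TSV spectrum (`wavenumber_cm-1  absorption  cd`), a JSON
sidecar with the resolved parameters, seed and variant label, and a resolved
YAML config for provenance.  Configurations are YAML with presets `ether`
(monomer) and `wscp` (dimer); every section (states, modes, vc_mode, bath,
disorder, coupling, geometry, grid) is schema-validated and unknown keys are
rejected.

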