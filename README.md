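# oecspin

Spin-Hamiltonian analysis of exchange-coupled tetramanganese clusters,
built for screening structural models of the oxygen-evolving complex
(OEC) of photosystem II — in particular ammonia-bound variants of its
S₂ state — against pulsed-EPR observables.

## Who this is for

Quantum chemists and EPR spectroscopists who have pairwise exchange
couplings (or the broken-symmetry DFT determinant energies they are
fitted from) and on-site hyperfine parameters for a candidate cluster
geometry, and who want to know whether that candidate is compatible
with the g ≈ 2 multiline EPR signal, ⁵⁵Mn ENDOR, ¹⁴N ESEEM and ¹⁷O
EDNMR data of ammonia-treated S₂ samples.

## What it computes

Everything downstream of the electronic-structure step:

1. **Exchange couplings from broken-symmetry energies.**  Each collinear
   determinant with local projections mᵢ = ±Sᵢ has the Ising energy
   E = E₀ − 2 Σ_{i<j} J_ij mᵢmⱼ; given ≥ (pairs + 1) determinant
   energies, (J_ij, E₀) is recovered by least squares via a
   truncated-SVD pseudo-inverse, with residuals and the condition
   number reported (`oecspin.extract_couplings`).
2. **The complete spin ladder.**  The isotropic Heisenberg Hamiltonian
   Ĥ = −2 Σ_{i<j} J_ij Ŝᵢ·Ŝⱼ (J > 0 ferromagnetic) is diagonalized
   exactly.  Ĥ commutes with total Ŝz, so the product basis splits
   into M_S blocks; each total-spin-S multiplet places exactly one
   state in the minimal-|M| block, which therefore yields the full
   ladder from one dense eigenproblem.  States are classified by
   ⟨Ŝ²⟩ (`oecspin.spin_ladder`).  For a Mn(III)Mn(IV)₃ cluster with
   site spins (2, 3/2, 3/2, 3/2) the Hilbert space has dimension 320.
3. **Spin projection coefficients and effective hyperfine couplings.**
   In the maximal-M_S component of the ground multiplet,
   ρᵢ = ⟨Ŝᵢz⟩ / M_S (so Σρᵢ = 1), and the observable hyperfine
   coupling of a nucleus attached to site i is Aᵢ = ρᵢ·αᵢ, with αᵢ the
   on-site value in MHz.  ⁵⁵Mn couplings are sorted descending and
   summarized by the scale-invariant ratios A₁/A₂, A₂/A₃, A₃/A₄
   (`oecspin.projection_coefficients`, `oecspin.sort_and_ratio`).
4. **Multi-criteria screening.**  A hard doublet (S_GS = 1/2) criterion,
   plus soft criteria on the first excited-state gap (~30 cm⁻¹,
   window 16–46), RMS distance of the ⁵⁵Mn ratio triple from ENDOR
   references, the bound-¹⁴N quadrupole asymmetry η (window 0.4–0.6),
   ¹⁷O range checks, and optionally the electron-affinity difference
   vs the 2.70 kcal/mol experimental estimate.  Models are ranked by a
   weighted sum of deviations (`oecspin.screen_models`).

Transcribed coupling tables, projected hyperfine tables and
experimental reference values for 31 cluster models (29 ammonia-bound
S₂ variants, the untreated S₂, and its W2-protonated form) ship as
checksummed fixtures (`oecspin.published_fixtures`), and a synthetic-data
module generates Ising-consistent determinant energies (optionally
noisy) and class-appropriate on-site hyperfine values for testing any
stage in isolation (`oecspin.simulate_bs_energies`,
`oecspin.simulate_onsite_hfcs`).

## Worked example

```python
from oecspin import (published_fixtures, spin_ladder, projection_coefficients,
                     screen_models)

bundle = published_fixtures()
b3 = bundle.models["B3"]          # NH3 replacing W1, W2 aquo, open cubane

ladder = spin_ladder(b3)
for m in ladder.multiplets[:4]:
    print(f"S={m.total_spin}  E={m.energy:.1f} cm-1  g={m.degeneracy}")

rho = projection_coefficients(b3)
print("rho:", [round(r, 2) for r in rho.rho], "sum:", round(rho.total, 6))

report = screen_models(bundle.screening_inputs(), bundle.ammonia_references())
print(report.ranking()[:3])
```

prints

```
S=1/2  E=0.0 cm-1  g=2
S=3/2  E=16.0 cm-1  g=4
S=1/2  E=37.4 cm-1  g=2
S=5/2  E=42.4 cm-1  g=6
rho: [1.67, -0.97, -0.98, 1.27] sum: 1.0
['C2', 'C1', 'B1']
```

The B3 coupling set gives a doublet ground state with the first excited
quartet 16.0 cm⁻¹ above it — inside the 16–46 cm⁻¹ window expected for
the ammonia-treated S₂ state.  The projection coefficients carry the
αββα sign pattern of the lowest broken-symmetry determinant, with Mn1
(the lone Mn(III)) carrying the largest share of the effective spin.
In the default screening, W2- and W1-substitution models (C2, C1, B1,
B3, …) occupy the top ranks, while models with high-spin ground states
are excluded outright.

A command-line interface mirrors the library:

```bash
oecspin ladder --model src/oecspin/data/models/B3.json --out ladder.tsv
oecspin simulate --model src/oecspin/data/models/B3.json --noise-sd 0.1 --seed 1 --out bs.csv
oecspin extract-j --model src/oecspin/data/models/B3.json --energies bs.csv --out fit.json
oecspin screen --models src/oecspin/data/models --out report.tsv
```

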