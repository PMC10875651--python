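# Methods

## Model

The package treats an exchange-coupled cluster of N localized spins
(here: the four Mn ions of the Mn₄CaO₅ core; Mn(III) → S = 2,
Mn(IV) → S = 3/2) with the isotropic Heisenberg Hamiltonian

    Ĥ = −2 Σ_{i<j} J_ij Ŝᵢ·Ŝⱼ ,

in which J_ij > 0 is ferromagnetic.  Under this convention a dimer obeys
the Landé interval rule E(S) = −J[S(S+1) − S₁(S₁+1) − S₂(S₂+1)], and an
antiferromagnetic spin-1/2 pair has a singlet–triplet gap of 2|J|.
Conventions differ across the literature, so the prefactor is exposed as
a flag (`minus2J` default, `minusJ`, `plusJ`); the default was fixed by
checking that published coupling sets reproduce their published
spin-state descriptors under −2J (and do not under the alternatives).

Anisotropic and antisymmetric exchange, zero-field splitting, Zeeman
terms and finite-temperature populations are all out of scope: the
model's purpose is ground/low-lying multiplet energetics and composition.

## Exact diagonalization

Ĥ conserves total Ŝz, so the product basis |m₁…m_N⟩ block-diagonalizes
by M = Σmᵢ.  Every total-spin-S multiplet contributes exactly one state
to each block with |M| ≤ S; the minimal-|M| block (M = 0 for integer
total spin, otherwise M = 1/2) therefore contains one representative of
every multiplet, and a single dense symmetric eigenproblem in that block
yields the complete ladder.  For the 320-dimensional Mn(III)Mn(IV)₃
problem the largest needed block has a few tens of rows; dense `eigh`
is used throughout and a configurable dimension cap (default 10⁶)
refuses pathological inputs rather than silently thrashing.

Each eigenstate is assigned a total spin from ⟨Ŝ²⟩, matched to the
nearest S(S+1) with tolerance 10⁻⁶.  Eigenvalues closer than
10⁻⁶ × (ladder span) (absolute floor 10⁻⁹ cm⁻¹) are treated as one
degenerate subspace in which Ŝ² is diagonalized first, so accidentally
degenerate multiplets of different S are separated cleanly instead of
producing classification failures.  This matters in practice: one
fixture model (A10) has a doublet–quartet gap of under 1 cm⁻¹ that must
survive without merging.  Energies are stored relative to the ground
multiplet at full precision and rounded (1 decimal) only when printed.

## Coupling extraction from broken-symmetry energies

A broken-symmetry determinant is represented by a sign pattern
sᵢ = ±1 (mᵢ = sᵢSᵢ), canonicalized so site 1 is spin-up (patterns are
physically equivalent under global inversion).  For N sites all
2^(N−1) distinct patterns are enumerated, high-spin first — for a
tetramer, the high-spin determinant plus seven spin-inverted ones.
On such a configuration the Hamiltonian is purely Ising:
E = E₀ − 2 Σ J_ij mᵢmⱼ, which equals the diagonal matrix element of the
corresponding product basis state (tested as an invariant).

Given determinant energies, the linear system in (E₀, J_ij) is solved
by least squares via SVD; singular values below 10⁻¹⁰ of the largest
are truncated, and if any are truncated the fit aborts with an error
naming the pairs whose couplings are unidentifiable (read off the
truncated right-singular vectors).  The 8-determinant tetramer system
is overdetermined by one equation; per-determinant residuals and the
design-matrix condition number are always reported rather than
discarded.  Hartree-tagged inputs are converted at
219474.63 cm⁻¹/Hartree before fitting so condition numbers are
comparable across input units.

## Spin projection and effective hyperfine couplings

For a ground multiplet with S > 0, the maximal-M_S component is
extracted from the M = S block and the projection coefficients are
ρᵢ = ⟨Ŝᵢz⟩/M_S, which satisfy Σρᵢ = 1 identically.  This is the
standard definition consistent with the effective-spin relation
Aᵢ = ρᵢαᵢ for a nucleus attached to site i.  A singlet ground state has
no projection and is an error; a ground level that is accidentally
degenerate beyond its 2S+1 Zeeman components is flagged as ambiguous
and one member is reported.

On-site values αᵢ (MHz) are inputs — transcribed from quantum-chemistry
output, or synthetic — never computed here.  Ligand nuclei (¹⁴N, ¹⁷O)
are projected with the ρ of a user-declared attached Mn site; how
multi-Mn bridging ligands (e.g. the O5 bridge) should be weighted is
not experimentally settled, so a single attached site must be declared
explicitly rather than guessed.  The quadrupole asymmetry η is carried
through untouched and only compared, never computed.

The empirical ×1.78 scaling used when comparing computed ⁵⁵Mn couplings
to experiment is available as an explicit, logged operation
(`apply_mn_scaling`); it is deliberately not baked into projection.
The shipped on-site range defaults (below) are comparison-ready values
for which no additional scaling is appropriate, as confirmed by
back-computing α = A/ρ from the shipped projected tables.  Since
A₁/A₂, A₂/A₃, A₃/A₄ are invariant under any global scaling, the
ratio-based screening criterion is unaffected either way.  Descending
sorts break magnitude ties by site index, keeping reports
deterministic.

## Screening

Criteria, each producing a pass/fail status plus a soft deviation:

| criterion | reference | default window | deviation |
|---|---|---|---|
| ground spin | S_GS = 1/2 (g ≈ 2 multiline signal) | exact | hard: fail ⇒ excluded |
| excited gap | ~30 cm⁻¹ | 16–46 cm⁻¹ | |ΔE − 30|/30 |
| ⁵⁵Mn ratios | ENDOR ratio triples per organism | — | min-over-references RMS of the 3 ratios |
| ¹⁴N η | 0.4–0.6 experimental spread | [0.4, 0.6] | distance to window |
| ¹⁷O ranges | exchangeable ~7 MHz, terminal ~3 MHz | flags: any >16 MHz, or all <4 MHz | 1 if flagged else 0 |
| EA difference | 2.70 kcal/mol | Δ > 0 required | |Δ − 2.70|/2.70 |

EA values are caller-supplied (they are electronic-structure outputs);
with none provided the criterion reads "not evaluated" — criteria are
never silently passed.  The composite score is the weighted sum of the
deviations above (all weights 1.0 by default).  No numeric composite is
defined by the underlying experiments; the score is a package
convention for producing a deterministic ranking, is labelled as such
in reports, and is monotone: worsening any single deviation can only
worsen (never improve) a model's rank.  Models failing the hard
criterion are excluded regardless of soft scores and trail the ranking
in name order.

RMS over the three hyperfine ratios is used because the ratio triple is
dimensionless, organism-stable (unlike absolute couplings, which vary
by up to ~27 MHz between organisms), and scaling-independent; the
minimum over supplied reference organisms is scored so a model
consistent with any one organism's data is not penalized.

## Synthetic data

`simulate_bs_energies` draws determinant sets that are exactly
Ising-consistent for a stated ground truth (J, E₀), plus optional
i.i.d. Gaussian noise of configurable σ (cm⁻¹).  Real DFT errors
relative to the Ising mapping are systematic, not white; Gaussian noise
is a documented stand-in that suffices to exercise the least-squares
machinery (unbiasedness of the fit under noise is verified against the
analytic design covariance).  Randomness uses numpy's PCG64 generator
with an explicit seed recorded in the output metadata.

`simulate_onsite_hfcs` draws |α_iso| and |α_aniso| uniformly from
valence/coordination class ranges: octahedral Mn(IV) 219–301 MHz
(anisotropy < 49 MHz), five-coordinate square-pyramidal Mn(III)
130–150 MHz, six-coordinate Mn(III) 191–231 MHz (Mn(III) anisotropy
141–150 MHz), signs negative by convention.  These are effective,
comparison-ready on-site magnitudes.  What the generator does **not**
emulate: correlations between coupling errors and hyperfine errors,
anisotropic tensor orientations, and site-to-site correlations — so
passing synthetic tests demonstrates the correctness of the spin
algebra and estimators, not the accuracy of any electronic-structure
protocol.

The fixture bundle transcribes the published coupling, hyperfine and
reference tables once; every file is SHA-256 checksummed and verified
at load.  Valence patterns carry a provenance tag: 27 models are stated
in prose, two (C3, D8) are read off structure-figure coloring, and the
two ammonia-free reference models are inferred from their doublet
ground state; all 31 reproduce their printed spin-state descriptors.

## Numerical choices and edge cases

- Site spins are exact `Fraction`s; 3/2 is never 1.4999….  Energies and
  couplings are floats in cm⁻¹.
- Degeneracy grouping: relative 10⁻⁶ of ladder span, floor 10⁻⁹ cm⁻¹.
  Spin classification: |⟨Ŝ²⟩ − S(S+1)| < 10⁻⁶.
- SVD truncation at 10⁻¹⁰σ_max; rank deficiency is an error naming the
  unidentifiable parameters, not a silent pseudo-inverse.
- Unlisted coupling pairs are J = 0; self-couplings are rejected.
- Ties in hyperfine magnitude sort by ascending site index.
- File indices are 1-based (Mn1…Mn4); the internal representation is
  0-based, converted only at I/O boundaries.

## Known limitations

- Printed couplings are rounded to 0.1 cm⁻¹; gaps computed from them
  can deviate from gaps computed from unrounded values by a few tenths
  of cm⁻¹ (amplified where the ladder is sensitive), and near-degenerate
  models make projection coefficients similarly sensitive.  The test
  suite's tolerances account for this input rounding, not for solver
  error (the solver is exact to ~10⁻⁸ against a brute-force oracle).
- Single-attached-site projection of bridging ligands is a declared
  simplification; no weighted multi-site projection is offered because
  no established weighting exists.
- The screening score ranks models; it is not a statistical test and
  carries no probability interpretation.
- Only isotropic hyperfine values plus a scalar anisotropy tag are
  handled — no full tensors, no quadrupole tensor computation, no
  spectral simulation.
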