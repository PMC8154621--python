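# Methods

## Model

The package computes degenerate two-photon absorption (2PA) transition
strengths for finite electronic state spaces and decomposes them with
generalized few-state models (GFSM).

**Rotationally averaged strength.** For a transition from the ground state 0
to a final state J excited by one linearly polarized monochromatic beam
(two photons of energy ω = E_J/2), the orientationally averaged strength is

    δ_0J = (1/15) Σ_ab [ F S^L_aa S^R_bb + G S^L_ab S^R_ab + H S^L_ab S^R_ba ]

with polarization weights F = G = H = 2 for parallel linear polarization.
S^L and S^R are the left and right second-order transition moments

    S_ab = Σ_K [ μ_a^{0K} μ_b^{KJ} + μ_b^{0K} μ_a^{KJ} ] / (E_K − E_J/2)

summed over every state K of the set, ground state included; for a Hermitian
theory the two sides coincide and δ ≥ 0 (it is a full contraction of a
symmetric tensor with itself). Non-Hermitian (coupled-cluster-like) data is
supported through a separate left dipole matrix; the packaged analyses use
the Hermitian path, since the reference dataset supplies symmetrized moments
only.

**Few-state models.** Truncating the K-sum to a subset containing 0, J and
chosen intermediates and inserting the truncated moments into the average
gives the closed-form GFSM decomposition into ordered-pair terms

    δ_0JKL = (8/15) · |μ^{0K}||μ^{KJ}||μ^{0L}||μ^{LJ}| / (ΔE_K ΔE_L) ·
             [ cosθ(0K,KJ) cosθ(0L,LJ) + cosθ(0K,0L) cosθ(KJ,LJ)
               + cosθ(0K,LJ) cosθ(KJ,0L) ]

with ΔE_X = E_X − E_J/2 for every X (so ΔE_0 = −E_J/2 and ΔE_J = +E_J/2) and
θ(PQ,RS) the angle between the two dipole vectors. The 8/15 constant is not
a free choice: expanding the (1/15)[2 S_aa S_bb + 2 S_ab S_ab + 2 S_ab S_ba]
contraction of the symmetrized moments into dipole dot products yields
4(F+G+H)/45 per ordered intermediate pair, and the all-states GFSM then
reproduces the full sum-over-states value identically — the equivalence is
asserted to 1e-10 relative over a 200-system random ensemble in the test
suite. The two-state model (2SM, intermediates = {0, J}) has 4 terms; the
three-state model (3SM, one extra intermediate) has 9.

**Diagonal-dipole convention.** Permanent dipoles enter the sums as raw
state dipoles μ^{KK}. At the degenerate photon energy the full SOS and every
few-state total are exactly invariant under a uniform shift of all diagonal
dipoles (the K = 0 and K = J shift contributions cancel because the two
denominators are ±E_J/2), so the alternative fluctuation convention
(μ̄^{KK} = μ^{KK} − μ^{00}, available via
`ElectronicStateSet.with_fluctuation_dipoles()`) changes only the per-term
attribution, never a total; a test asserts this equivalence. Raw diagonals
are the default because the dipolar-chromophore decomposition analysis is
conventionally stated in them: the dominant 2SM term δ_0111 carries
|μ^{01}|²|μ^{11}|², and the cross term δ_0101 — whose denominator product is
negative — is the destructive-interference channel. Under the fluctuation
convention those ground-state-bearing terms are identically zero and all
diagonal weight collapses onto δ_0JJJ ∝ |Δμ|².

## Numerical choices

- **Units.** Atomic units everywhere inside the core; eV (and nm) only at
  the I/O boundary. hc = 1239.84198 eV·nm, 1 hartree = 27.211386245988 eV
  (CODATA). Two-photon wavelengths are reported to the nearest nm, which
  maps the reference energies 4.16 and 3.20 eV to 596 and 775 nm.
- **Resonance guard.** No linewidth/damping is modelled; any denominator
  with |E_K − E_J/2| < 1e-8 au raises `ResonanceError` rather than returning
  a huge number.
- **Zero-dipole terms.** A GFSM term containing a dipole of magnitude
  < 1e-12 au is set to exactly 0 with its angular channels recorded as
  absent: the magnitude prefactor vanishes before the cosines become 0/0.
- **Dominant term.** Largest |value|; ties broken lexicographically by term
  label; undefined (None) when every term is zero.
- **Best intermediate.** The candidate minimizing |δ(3SM) − reference|, ties
  to the lowest state index; verified against exhaustive enumeration.
- **Biological window.** 650–1100 nm, bounds inclusive.
- **Term keys.** Ordered pairs (K, L); for Hermitian systems (K, L) and
  (L, K) coincide in value, which is asserted, not assumed.

## Synthetic systems

The generator emulates the *shape* of CC2-like excited-state data for the
two chromophore architectures, not any specific molecule:

- **dipolar** (donor–acceptor): transition dipoles between all state pairs
  with magnitudes drawn in 0.5–3.5 au, a ground permanent dipole, and
  excited permanent dipoles offset from it by fluctuation dipoles of
  0.5–5 au;
- **quadrupolar** (centrosymmetric D–A–A–D): parity labels g, u, g, …
  (ground gerade, S1 ungerade, S2 gerade), transition dipoles only between
  opposite-parity states, no permanent dipoles — which makes S1 one-photon
  bright but two-photon dark, and S2 the reverse, by construction.

Excitation energies are drawn uniformly in 2.6–4.2 eV (the span of the
reference compounds) and sorted; the dipole ranges imply oscillator
strengths below ~2, bracketing the reference values (0–1.97). One integer
seed fully determines a draw through an explicit `numpy` Generator; no
global RNG state is used. Property ensembles use up to 6 states and energy
denominators bounded away from resonance by 1e-3 au — the physical
precondition of the undamped theory, and the regime where the 1e-10
relative oracle tolerance is meaningful.

What the generator does **not** emulate: real CC2 left/right moment
asymmetry, correlated energy/dipole structure across a conjugated series,
vibronic structure, or solvent effects. Passing tests therefore demonstrate
the correctness of the tensor algebra, the model decomposition and the
selection rules — not predictive accuracy for any real chromophore; the
reference δ values themselves are carried as data, not recomputed (that
would require the unpublished correlated transition moments).

## Reference dataset

`gfsm/data/bophy_cc2_reference.tsv` carries the 13-compound BOPHY-derivative
RI-CC2/cc-pVDZ dataset: per compound, the S0→S1 and S0→S2 excitation
energies (eV), oscillator strengths, 2PA strengths (10⁴ au), plus 2SM
(S0→S1) and 3SM (S0→S2) strengths where available; blank model cells are
stored as absent, not zero. Compounds 3–5, 10 and 12 are dipolar, the rest
quadrupolar. The cohort analysis derives from it the energy extrema
(2.62–3.28 and 2.94–4.16 eV), the strongest-vs-reference S0→S2 fold change
(40.94/1.36 ≈ 30.1), the red-shift pair of two-photon wavelengths
(596 → 775 nm) and the biological-window flags.

## Known limitations

- δ (au) is not converted to macroscopic GM cross sections: that requires a
  lineshape convention the workflow deliberately leaves out of scope.
- Only degenerate (equal-photon) 2PA; no frequency-scanned spectra, no
  lifetime broadening.
- No parser for quantum-chemistry program output; the JSON state-set schema
  is the single ingestion point and excited-state blocks are transcribed
  into it by hand.
- The observation that δ_0211 can exceed the 3SM total for dipolar systems
  is data-dependent; reports surface it when it occurs but it is not an
  invariant.
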