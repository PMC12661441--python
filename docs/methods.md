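# Methods

## The physical picture

The *E. coli* transcription termination factor Rho (protomer average mass
47,198.40 Da) populates every oligomeric state from monomer to hexamer at
biochemically relevant concentrations. A complete ATP-binding site sits at
the interface between two subunits — one contributing ~80% of the buried
ligand surface, the neighbour the remaining ~20% — so an open-washer j-mer
carries j − 1 intact sites plus two partially formed sites at its exposed
edges. The package models ATP binding, oligomer assembly, and the two
single-molecule/-ion readouts (native MS, mass photometry) that observe
them, and fits the binding model back to the reduced data.

## Lattice binding model

A j-mer's sites form a 1-D lattice (`open_chain`: PARTIAL_A, FULL×(j−1),
PARTIAL_B; `uniform_linear(n)`: n identical FULL sites; `closed_ring`:
cyclic). The statistical weight of an occupancy configuration *s* is

    W(s) = Π_i (K_class(i) · L)^{s_i} · ω^{#adjacent occupied pairs}

with `L` the free-ligand concentration, `K_full`, `K_partial_a/b` intrinsic
association constants (M⁻¹) and a single dimensionless nearest-neighbor
factor ω applied to every adjacency, including full–partial edges (per-pair
couplings would be a straightforward extension but are not identifiable at
this data scale). ω < 1 is anti-cooperative. The binding polynomial
Z(L) = Σ_k a_k L^k is evaluated by exact enumeration (≤ 2⁷ configurations for
these lattices, guarded at 2²⁴) in linear space — log-space evaluation is
unnecessary at these sizes — and cross-checked against an independent 2×2
transfer-matrix sweep (trace form for rings). P(k) = a_k L^k / Z, and the
mean occupancy equals d ln Z / d ln L, which the tests verify by finite
differences.

The six-site hexamer fit is taken as a *linear* chain
of six identical sites (`uniform_linear(6)`); the open-ring (7-site)
topology is the default for simulation and extraction because
superstoichiometric binding (k = 7) requires the edge sites. Whether the six
sites are better viewed as subunits or interfaces of a closed ring is left
open by the data; the `closed_ring` mode covers the alternative.

## Assembly equilibria and linkage

Oligomers form with overall constants β_j (β₁ ≡ 1), parameterized either
isodesmically (β_j = K_step^{j−1}) or as a nucleated-cooperative ladder
(β_j = σ·K_step^{j−1}, j ≥ 2; σ < 1 penalizes the nucleating dimer). With
ligand, c(j,k) = β_j m^j a_k^{(j)} l^k. `speciate` solves the protomer and
ligand totals for (m, l) by nested bracketed root finding (outer on m,
inner on l; both balances are monotone in their own variable), with
residuals at machine precision (asserted ≤ 1e−9 relative). Only
stoichiometries 1..6 are modeled; equilibrium is assumed (whether dilute
distributions are kinetically trapped is not addressed).

The operational **apparent K_d** is the protomer total at which monomer and
hexamer *particle* fractions cross, found by bisection on log₁₀ P_tot. For
the nucleated ladder at L = 0 it has the closed form m* = (σK⁵)^{−1/5},
P* = Σ_j j β_j m*^j, used as an independent oracle in the tests. The default
generator values K_step = 2×10⁸ M⁻¹, σ = 0.1 were chosen by inverting this
closed form so that the crossover lands at ~1.0×10⁻⁷ M (0.1 μM), matching
the observed assembly scale; they also reproduce the U-shaped
(monomer/hexamer-dominant) particle histograms near the crossover. The model
does not force ATP insensitivity of assembly — weak linkage emerges only
when K_full ≫ K_partial does not hold strongly at the sampled ligand range.

## Native-MS forward model

Species (j, k) have average mass j·47,198.40 + k·507.18 (+22.99 per sodium)
Da; a configurable uniform offset stands in for the small noncovalent-adduct
excess seen under soft ionization (default 0, as its magnitude is not
characterized). Charge envelopes are discretized Gaussians centered at
z̄ = 0.0778·√M with σ_z = 0.9 charges (empirical native-ESI scaling;
coefficient configurable), truncated at ±4σ and renormalized. The envelope
is evaluated at the oligomer's *apo* mass: charging scales with the surface
area of the complex, which bound nucleotide barely changes — this also makes
single-charge-state population readout exact rather than ~1% biased.
Peaks are Gaussians of σ = 0.15 m/z (constant; a width at which the ~23/z
sodium satellites of large oligomers are just resolved), sodiation is
binomial per bound ATP (p = 0.15, reflecting the disodium ATP salt), and
noise is optional (default for scenarios: additive Gaussian with σ = 0.2% of
the base-peak intensity, the S/N class of averaged native-MS scans; Poisson
counting noise available). Fixed seeds give bit-identical spectra.

Relative ion response **across** oligomers is deliberately arbitrary: the
default `equalized` mode gives every oligomer the same total ion count
regardless of its solution fraction, mirroring the observation that
cross-oligomer ion counts do not report solution populations. Within an
oligomer, intensities are strictly proportional to species concentrations.

## Windowed extraction

Expected m/z positions are computed for every (j, k ≤ n_sites(j),
n_Na ≤ k) at one representative charge per oligomer (the apo-envelope mode
by default; any charge list can be configured).
Around each position a ±1 m/z window (total 2 m/z) is searched; the
statistic is the **local maximum nearest the expected position** with
3-point log-parabolic apex refinement, falling back to the value at the
expected position when the segment has no interior maximum. Within one
(j, k, z) window the sodiation satellites partition the window at midpoints
so a taller neighbour's tail is never claimed twice; sodiated and
unsodiated intensity for the same k are merged (ATP+23 counts as bound
ATP). Sub-window values below 5× a robust noise estimate (median absolute
first difference / 0.954) are treated as empty — without this, the
extreme-value bias of max-statistics over many empty sodiation sub-windows
systematically inflates high-k cells; the threshold is exactly zero for
noiseless spectra. Windows of different (j, k) must be ≥ 2 half-widths
apart, validated at grid construction with the colliding species named.

Each oligomer row is normalized to unit sum (zero rows are flagged missing,
never imputed), and only these within-oligomer fractions are exposed
downstream. Deconvolution workflows apply such windows in the deconvolved
mass domain; extracting per known charge directly in m/z is equivalent when
species and charges are known a priori, and deconvolution itself is out of
scope here.

## Mass photometry

Particles land with probability proportional to oligomer particle fractions
and are observed at Gaussian-blurred masses (σ default 6 kDa, the typical MP
resolution class; not a measured value). Assignment back to counts uses a
six-component Gaussian mixture with means *fixed* at j·protomer mass, a
shared width floored at 10 Da, and maximum-responsibility labels; fixing the
means removes label switching for these 47-kDa-spaced species.

## Fitting

The objective is the multinomial negative log-likelihood of each non-missing
oligomer row at a configurable effective count per row (default N = 5000;
raw ion statistics are not Poisson-calibrated, so N is a modeling choice;
least-squares on fractions is a config fallback). Model probabilities are
floored at 1e−12 with a warning when data contradict them. Free ligand per
point is resolved by `speciate` (default), a hexamer-only balance, or
l = L_tot under a flag — at 10 μM protomer the sites materially deplete
≤ 100 μM ATP, so the balance matters. Optimization is L-BFGS-B in log₁₀
space, bounds log₁₀K ∈ [2, 8] and log₁₀ω ∈ [−3, 3] (spanning the 10–100 μM
K_d scale with margin), best of ≥ 8 seeded multistarts. Omega
identifiability is checked by profiling it at both bounds: if either leaves
the NLL within the 95% χ² half-width after re-optimizing the other
parameters, ω is reported unidentified instead of as a point estimate.
Uncertainty comes from a seeded parametric bootstrap (resimulate multinomial
rows at the fitted model, refit, percentile intervals), with a reliability
warning above 20% refit failures. The assembly ladder is fitted the same way
to MP oligomer counts at ≥ 2 concentrations (σ is unidentifiable from one),
reporting the derived apparent K_d.

## What the generator does and does not emulate

The synthetic data reproduce the *structure* of the experiments: narrow
native charge-state envelopes of all six oligomers, ATP/sodium adduct
ladders, within-oligomer intensity linearity, arbitrary cross-oligomer
response, particle-count histograms with realistic mass blur, and ligand
depletion at titration scale. They do not emulate: m/z-dependent peak-width
growth or chemical baseline, in-source activation effects, uncharacterized
noncovalent adduct tails (beyond a constant offset), detector saturation,
MP landing-rate kinetics, or any kinetic trapping of oligomers. Passing
round-trip and recovery tests therefore demonstrates internal consistency
of the inference chain under known-model conditions, not robustness to
every instrumental artifact of real spectra.

## Problem sizes

Default analyses run at desk scale: 7-point titrations at 10 μM protomer,
effective N = 5000 per row, 20-replicate recovery experiments, 5000-particle
MP simulations, and ≤ 128-configuration lattices — sizes at which every
computation is exact or statistically well-resolved within seconds.
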