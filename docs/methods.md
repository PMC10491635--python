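# Methods

## Model

`mixsep` simulates mixtures of coarse-grained biopolymers on a periodic
cubic lattice with one bead per residue.  Vacant sites are implicit
solvent: they occupy volume but carry no interaction parameters.  Bonds
between consecutive beads of a chain, and nonbonded contacts between any
two beads, both live on the 26-site neighborhood of the cubic lattice
(generalized bond-fluctuation conventions): two sites interact or may be
bonded when every coordinate differs by at most one under the periodic
minimum image.  Bonded neighbors are excluded from contact energy.

The contact energy between beads `a` and `b` is

    E(a, b) = iso[r_a, r_b] + aniso[r_a, r_b]·[a, b partnered] + λ·n̄²

where `r_a` is the residue type, `iso`/`aniso` are symmetric residue-pair
matrices in reduced energy units (negative = attractive), and the last
term is the mean-field electrostatic penalty with `n̄` the average net
charge per residue (NCPR) of the two chains the beads belong to.  For a
single-component system `n̄` reduces to that species' NCPR, so the mixture
rule is backward-compatible.  The quadratic form `λ·n̄²` is a deliberate
design choice: it is the simplest nonnegative penalty that vanishes when
chain charges balance, so oppositely charged chain pairs pay nothing and
like-charged pairs are penalized — qualitatively producing the
electrostatic enhancement of co-phase separation for charge-complementary
mixtures.  The form is registered under the name `mean_ncpr_squared` and
is swappable, because bespoke parameterizations of PLCD models define
their own expression; any callable `(ncpr_i, ncpr_j, λ) -> energy` can be
dropped in.

Anisotropic interactions are realized as exclusive pairwise partnerships:
a bead has at most one partner, partners must be lattice neighbors, and a
dedicated rewire move forms or breaks partnerships with Metropolis
acceptance.  This captures valence-limited (sticker-like) bonds without
orientation vectors.  A single-bead displacement that separates partners
breaks the partnership as part of the move; this is a documented
convention rather than an exactly balanced kinetic scheme, and all
quantitative tests in this repository run with zero anisotropic energies.

## Monte Carlo sampling

Moves are accepted with probability min[1, exp(−ΔE/T)], with reduced
temperature T (k_B = 1, energies in contact units).  The move set is
{single-bead local displacement, end-bead regrowth, reptation,
crank-shaft, whole-chain translation, cluster translation, anisotropic
rewire} with configurable weights defaulting to
local:end:reptation:crank:translation:cluster:rewire = 4:2:2:1:1:1:2.
Weights are sampling parameters, not physics.  Two implementation
restrictions: reptation applies only to homopolymer chains (for a
heteropolymer the move would permute the residue-to-position map) and only
when the chain carries no anisotropic partnerships (bead indices shift
under the move); cluster translation aborts, as a rejected attempt, when
the connected cluster exceeds one eighth of all chains — rigid translation
of a system-spanning condensate carries no physical information and would
otherwise dominate the runtime.  Geometry-invalid proposals count as
attempted, rejected moves.

Systems are initialized by self-avoiding growth (with backtracking) of all
chains inside a centered sub-box (edge 35 by default, clipped to the
lattice), which nucleates a single dense region and shortens equilibration
of the two-phase system.  Each temperature runs independently from a fresh
seed configuration, with its RNG stream derived from the campaign seed, so
runs are reproducible bit for bit.  The cached total energy is updated by
ΔE at every acceptance and compared against a full recomputation at every
snapshot (tolerance 1e−9); excluded-volume, bond and partnership
invariants are checked at the same cadence.

## Chain counts and concentrations

Volume fractions (beads per lattice site) are the concentration unit
everywhere; they are unitless.  Chain counts for a target total volume
fraction are chosen by scaling the smallest integer repeat unit of the
molecule-number ratio by the integer multiplier that minimizes the
distance to the target (ties toward fewer chains).  For the production
geometry — equal numbers of 214-mers and 135-mers on a 120³ lattice with
target 0.016 — this yields 79 chain pairs and a realized fraction of
27571/1728000 ≈ 0.016.  Mixing ratios are by molecule number; equal-mass
mixtures of homopolymers translate to equal bead counts (molecule counts
inversely proportional to length).

## Condensate analysis

The condensate is the largest connected component of the chain contact
graph (chains linked by any inter-chain bead contact; ties broken toward
the lowest chain index), with a periodic center of mass computed by the
circular mean per axis.  A run is flagged "no condensate" when the largest
component holds less than half the chains.

Radial densities use shells of 0.25 lattice units.  Every lattice site is
assigned to a shell by its exact distance to the (fractional) center, so
each shell's density is a bead count divided by the exact site count of a
cubic lattice — the exact prior — and a uniformly filled box yields a flat
profile at the global volume fraction.  The interface is characterized by
a least-squares fit of

    ρ(r) = ρ_dil + (ρ_den − ρ_dil) / (1 + exp((r − r₀)/w))

per species.  Shells are weighted by their site counts (σ ∝ 1/√sites), so
the innermost shells — which contain only a handful of sites and are
dominated by counting noise — cannot dominate the fit.  Initialization:
ρ_den from the maximum shell density, ρ_dil from the outer 20 % of shells,
r₀ at half maximum, w = 0.5; bounds keep levels in [0, 1] and w in
(0, L/2).  Degenerate (flat) profiles and non-converged fits are returned
flagged, never silently replaced.  The interfacial region is the logistic
10–90 % band [r₀ − w ln 9, r₀ + w ln 9]; its width is 2w ln 9 ≈ 4.39 w.

Dense-phase concentrations average the species volume fraction over shells
interior to the band; dilute-phase concentrations divide the species bead
count in the entire exterior region by the exact exterior site count, so
free chains anywhere in the box are counted (an asymptote-based estimate
would miss them).  Chain-dimension profiles bin every bead independently:
each bead contributes its chain's Rg/√N (Rg on exactly unwrapped
coordinates, N the chain length) to its own shell, and shell values are
bead-weighted means, undefined below a minimum bead count (default 10).
Frame- and replicate-averaged profiles (`mean_profile`) pool bead and site
counts on the common shell grid before fitting; single snapshots of small
droplets are otherwise too noisy for stable interface fits.

## Phase boundaries and tie lines

Binodal points average coexistence concentrations over replicates with
standard errors about the mean; temperatures where every replicate is
flagged single-phase are omitted, so the binodal terminates at the
two-phase boundary.  Two-component dilute arms are classified against the
additivity line c_dilute = a·c_sat,A + (1−a)·c_sat,B by the error-weighted
mean of signed chord deviations, measured along the total-concentration
direction: below the chord is concave (heterotypic enhancement), above is
convex, and "linear" means the deviation is smaller than `linear_z`
standard errors (default 1; a significance threshold, configurable like
the tie-line z).  A chord-deviation sign statistic is used instead of a
curve fit because typical boundaries carry only 3–5 stoichiometries.  The
signed-area statistic reported alongside is a package metric.

Tie lines join (c_dilute, c_tot, c_dense) in the (c_A, c_B) plane.  The
two segment slopes (dilute→total, total→dense) are computed from point
pairs — not a regression — with first-order error propagation, and
compared by z = |Δslope|/σ; the system is consistent with precisely two
coexisting phases when z < 2 (configurable).  Only then is the whole-line
slope interpreted: ≈1 balanced/heterotypic, <1 the abscissa component's
homotypic interactions dominate, >1 the ordinate component's.  The
analysis is unit-agnostic (volume fractions or mg/mL) and axis exchange
maps s → 1/s with the verdicts swapped.

## Crosslinking statistic

Within the condensate, intermolecular contacts (any nonbonded inter-chain
bead pair in the 26-neighborhood; anisotropic-partnership-only counting
available as a flag) are accumulated per species pair with an endpoint
convention: a same-species contact has two same-species endpoints and
counts twice on the diagonal.  The observed share f_contact(i,j) =
N[i][j]/Σ_k N[i][k] is compared with the random-mixing share
f_expected(i,j) = (N_mol[j] − δ_ij)/(Σ_k N_mol[k] − 1), which excludes the
molecule from whose perspective the share is computed.  Their ratio
L[i][j] equals 1 exactly in expectation when every molecule's partners are
drawn uniformly from the other molecules — the endpoint convention is what
makes this identity hold, and it is verified both by Monte Carlo sampling
of the null model and against a brute-force recomputation from raw contact
multigraphs.  Bead-pair counting is the default because the total contact
count maximizes statistics; molecule-pair-style counting can be emulated
through the anisotropic-only flag.

## Synthetic fixtures and presets

Closed-loop test inputs are generated with recorded ground truth:
random-mixed droplets (labels assigned uniformly to chain slots grown
inside a ball; E[L] = 1), core-shell droplets (species A in an inner ball,
B in an annulus; homotypic enrichment and A's interface midpoint inside
B's), logistic radial fields with additive Gaussian noise, and lever-rule
tie-line tables (totals on the segment joining two fixed phases).
Droplets pack to an interior volume fraction of ≈0.6 — a typical lattice
dense-phase density, chosen as a fixture convention, not a physics claim.

Preset systems cover the homopolymer scenario suite (all-equal −3.3;
heterotypic −3.6 vs homotypic −3.0; the reverse; weak A-A −3.0 with all
else −3.6; the 150/300-mer and 200/300/400-mer length mixtures with their
published species-pair energies), a pseudo-binary control (one sequence,
two labels, identical interactions) and a two-sequence mixture of a
214-mer with negative NCPR and a 135-mer with positive NCPR.  Sequence
presets use synthetic PLCD-proxy sequences (polar-rich, ~12 % aromatic,
~10 % proline, prescribed net charge), because real PLCD sequences and
their bespoke interaction table are runtime inputs (FASTA plus an
interaction-table CSV); the proxies are labelled synthetic wherever they
appear.  The uniform −3.3 proxy contact energy and the default
electrostatic coupling λ = 100 in the mixture preset are documented
fixture conventions chosen to put the systems in an accessible two-phase
regime, not fitted parameters.

## Scaled-down study conditions

Production-scale campaigns (120³–150³ lattices, 3×10¹⁰ steps, 5–10
replicates) are configuration-reachable but are not what the test suite
runs.  The shipped tests use systems chosen once as desk-scale analogues:
25-mers (36+36 chains, ~1800 beads) on 48³ lattices for the interaction
scenarios, 50/100-mers for the length effect, 4–12×10⁶ steps with
analysis after the halfway point, and 2–5 replicates.  Temperatures
(40–55) were chosen from a Flory-style estimate of how the critical
temperature falls with chain length, combined with the same retention rule
the analysis applies anyway: temperatures without a condensate are
excluded.  Statistical acceptance bands (3 standard errors for the
random-mixing identity, 2 for tie-line consistency and arm linearity)
reflect replicate scatter at this scale.  What passing these tests shows
is that the statistics, fits and classifications behave correctly on
systems whose ground truth is known or strongly constrained; it does not
certify quantitative values for production-scale PLCD systems, whose
energies are an external input.

## Known limitations

- The electrostatic form is a stand-in for bespoke parameterizations; λ
  has no calibrated magnitude here.
- Detailed balance is mildly violated by the partnership-breaking
  displacement convention and the cluster-size cap; both are inert in the
  quantitative tests (no anisotropic energies; capped moves are rejected
  attempts).
- Small droplets (radius ≲ 6 lattice units) do not support stable
  interface fits frame by frame; frame-averaged profiles are required.
- Interfacial chain expansion (the Rg/√N peak inside the interfacial
  band) requires droplets much larger than a chain's own Rg.  Desk-scale
  droplets (radius ~12 lattice units, chain Rg 4–7) lack that separation
  of scales, so the profiling machinery is validated on constructed
  droplets with known core/surface chain dimensions rather than on
  simulations.
- The dilute-arm classifier needs measured endpoints; it does not
  extrapolate missing saturation concentrations.
- Trajectory TSVs store species labels but not charge descriptors;
  analyses that need NCPR (energy recomputation) require the original
  config, while all geometric and crosslink analyses work from the TSV
  alone.
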