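# Methods

`micellemix` implements the computational analysis of mixed micellisation in
the sodium cholate (NaCA) / sodium dodecylsulphate (SDS) 1:1 system: the
regular-solution thermodynamics of the binary mixture, cmc extraction from
raw measurement curves, and the structural/statistical analysis of
coarse-grained self-assembly trajectories. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Mixed-micelle thermodynamics (`thermo`)

For bulk mole fractions α₁, α₂ = 1 − α₁ and pure-component critical micelle
concentrations cmc₁ (NaCA), cmc₂ (SDS), ideal mixing predicts the Clint cmc

    1/cmc_id = α₁/cmc₁ + α₂/cmc₂.

Rubingh's regular-solution treatment gives the micellar mole fraction x₁ of
the more hydrophobic component as the root in (0, 1) of

    x₁² ln(α₁·cmc_mix/(x₁·cmc₁)) = (1 − x₁)² ln(α₂·cmc_mix/((1 − x₁)·cmc₂)),

and the interaction parameter

    β₁,₂ = ln(α₁·cmc_mix/(x₁·cmc₁)) / (1 − x₁)².

β < 0 marks synergism (net attraction between the unlike head groups);
for NaCA/SDS it stems from the biplanar steroid skeleton packing between
the sulfate heads and hydrogen bonding between hydroxyls and sulfates.

Numerics. The root is found with Brent's method on the bracket
(10⁻⁹, 1 − 10⁻⁹); a missing sign change is reported as "no physical
solution" (this happens when cmc₁ < α₁·cmc_mix < cmc₂, i.e. the inputs are
inconsistent with a regular-solution mixed micelle). The accepted root must
leave a residual below 10⁻¹⁰; an independent 10⁻⁶-grid scan of the residual
is used as the test oracle. At the root, β computed from either component's
expression agrees to 10⁻⁶ — that identity *is* the implicit equation.

The packaged reference table (fluorimetric cmc values, 0–50 °C) carries
printed, rounded inputs; its x₁ values have a stated uncertainty of ±0.015.
Re-deriving the table from those rounded inputs reproduces cmc_id to ±0.005
everywhere and x₁/β to about ±0.002/±0.04 — the residual spread is the
input rounding, not the solver, whose residuals are at machine level.
The fluorimetric (not tensiometric) mixture cmc feeds the Rubingh analysis;
it reproduces the derived columns distinctly better. Experimental ± values
are carried as metadata and never propagated, matching the source analysis.

## cmc extraction from curves (`cmcfit`)

*Titration.* Pyrene I₁/I₃ vs total concentration is fitted with the
Boltzmann sigmoid y = a_low + (a_high − a_low)/(1 + exp((x − x₀)/dx)) by
least squares (`scipy.optimize.curve_fit`), initialised from the
first/last-quartile plateau means and the steepest finite-difference point.
The cmc is defined as the inflection x₀ — the conventional choice, symmetric
in the plateaus; the fit is equivariant under affine rescaling of the
response. Negative fitted widths are canonicalised by swapping plateaus.

*Conductivity / tension.* A two-segment line is fitted by grid search over
candidate splits (every interior abscissa plus midpoints, at least 3 points
per side) and compared with a single line through an F-test
(α = 0.05). Because the candidate is itself chosen to minimise RSS, this
F-test is anti-conservative; the verdict therefore also requires the slope
ratio S₂/S₁ to differ from 1 by more than 5%. The reported breakpoint is
the intersection of the two fitted lines, and the counterion binding
fraction is 1 − S₂/S₁ (clipped to [0, 1]). Surface-tension series are
analysed against log₁₀(concentration), the standard γ–log c treatment, with
the breakpoint mapped back to mM. A breakpoint-free conductivity curve is
the expected signature of a mixed micelle whose surface charge is not
neutralised by counterions.

## Coarse-grained data model (`cgmodel`)

SDS is four beads (tail C4, C2, C1; head SO3, charge −1), cholate eight
(convex hydrophobic face R1–R3, hydroxyl face RO2/RO3/ROH, tail C1,
carboxylate OCO, charge −1), Na⁺ one bead (+1). The cholate C1 bead is
classed hydrophobic (a tail site); only R1–R3 vs RO2/RO3/ROH have an
explicit published classification, so this assignment is a documented knob.
All beads carry equal unit mass for centre-of-mass purposes (coarse-grained
bead masses are near-uniform); water beads are dropped on ingest unless
requested, since no analysis uses them.

Internal units are Å and µs. GRO files (nm) are converted on read (via
MDAnalysis) and write; multi-frame trajectories use an extended-XYZ dialect
carrying molecule kind and bead name per line. All distances use the cubic
minimum-image convention; an explicit 27-image enumeration serves as the
test oracle.

## Cluster, shape and ion analyses (`cluster`, `shape`, `ions`)

Two surfactants share a cluster when their closest beads are strictly
within 7 Å (ties at the cutoff do not join — pinned by test). Clusters are
connected components of that contact graph; Na⁺ and water never
participate. Windowed statistics use 100 ns block averages over a default
0.6–10 µs window (after the association transient); the reported mean ± sd
are over block means (sd with ddof = 1). Trailing partial blocks are
dropped with a warning. Per-size sd at sizes observed once is reported
absent (NaN), not zero; the overall SDS content x₂ weights clusters
equally, following the "averaged over all aggregates" convention.

Shape: the gyration tensor is the unweighted second-moment tensor of the
unwrapped cluster; K² = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₁λ₃)/(λ₁+λ₂+λ₃)² with
eigenvalues sorted descending. A cluster with all beads coincident has
K² ≡ 0 (documented degenerate case). Clusters are unwrapped by minimum
image relative to their first bead before any COM computation, valid while
a cluster fits within half a box.

Radial profiles are raw normalised histograms (1 Å bins by default) of
bead–COM distances over clusters of at least 20 molecules; no r²
normalisation is applied (switchable choice — the reference curves'
normalisation is unspecified, and the raw histogram preserves peak
positions, which is all that is compared). Orientation: Θ is the angle
between the SDS molecular axis SO3→C4 and the radial direction SO3→COM, so
Θ = 0 means the tail points at the micelle centre. This vector pair is the
unique simple definition under which "Θ ≈ 0 ⇔ radially oriented inward"
holds; alternatives can be swapped in by computing on the returned blocks.

Ions: a Na⁺ is condensed iff it lies strictly within 7 Å of *any* SO3 or
OCO bead (per-ion, not per-micelle), mirroring the cluster criterion;
condensed + free = total in every frame by construction.

## Synthetic data (`synth`)

*Curves* are exact model evaluations plus additive Gaussian noise, seeded.
Default titration truth (x₀ = 4.07 mM, width 0.3 mM, plateaus 1.75 → 1.20)
matches the room-temperature mixed system; the default noise (σ = 0.01 on
I₁/I₃, ~0.5% of signal on conductivity) is set so that single-fit cmc
errors stay at the few-percent level reported for the experiments.

*Constructed configurations* plant an exact ground truth: molecules of a
cluster form a 4.5 Å anchor chain inside their geometry (sphere or rod), so
the 7 Å criterion provably connects them; distinct entities are separated
by > 16 Å closest-bead distance, so nothing merges; planted condensed Na⁺
sit 2.5–6.5 Å from a charged bead and free Na⁺ beyond 10 Å of all of them.
Cluster/ion analyses must therefore recover the planted labels exactly —
these round-trips are identities, not statistical checks.

*Toy aggregation* is overdamped Langevin dynamics on bead chains: harmonic
bonds (r₀ = 3 Å, k = 10), a Gaussian attractive well between hydrophobic
beads (range 8 Å; SDS–SDS depth 6 kT, SDS–CA 1.8 kT, CA–CA 0.54 kT),
screened Coulomb interactions between charged beads (screening length
10 Å) and a soft excluded-volume core. The asymmetric well depths encode
the mechanism of interest: SDS tails nucleate stable cores, cholate binds
weakly and exchanges. The default box is 90 Å for 30 + 30 surfactants
(~137 mM effective). This is deliberately denser than the 12.28 mM of the
reference simulation cell: at 12 mM a desk-scale run cannot diffuse
monomers into contact, and the toy model's purpose is the mechanism, not
the state point — the concentration remains far above the cmc either way.
The run is mapped onto a nominal 10 µs clock so the windowed analyses use
the same conventions as a real trajectory. A deterministic step
displacement exceeding a quarter box aborts the run as unstable.

What the toy model does *not* establish: Martini-level energetics,
aggregation numbers, the measured NOC ≈ 18.7 or x₂ ≈ 0.67, condensed-ion
counts, or any force-field observable. Those require the original 10 µs
trajectory, which is not deposited; the analyses are instead validated by
brute-force oracles, planted-truth round-trips, exact geometric references
and conservation laws, plus the qualitative mechanism (decreasing NOC,
SDS-enriched dominant aggregate, predominantly-cholate monomers) at pinned
seeds.

## Orchestration (`pipeline`, `cli`)

The library is the primary interface (see `examples/`); a thin `micellemix`
command covers the file-based workflows (`thermo`, `fit-cmc`, `simulate`,
`analyze`, `pipeline`). Physical defaults everywhere are the study
conventions: 7 Å cutoff, 100 ns blocks, 0.6–10 µs window. Pipeline
summaries embed the package version and full configuration; identical
configuration and seed give identical outputs.

## Problem sizes used in the test suite

The suite runs entirely on synthetic data at desk scale: oracle comparisons
use ≤ 20 molecules over 100 random configurations; recovery simulations use
100 seeded curves of 30 points; the shared toy trajectory is one default
run (60 surfactants, 201 frames). These sizes were chosen so the whole
suite exercises every code path in a few minutes while keeping the
statistical assertions comfortably powered.

## Known limitations

- The Rubingh solver requires a sign change on (0, 1); genuinely
  antagonistic or inconsistent inputs raise rather than extrapolate.
- The segmented-line F-test is anti-conservative under grid selection; the
  slope-ratio guard is the effective false-positive control, so breaks with
  < 5% slope change are undetectable by design.
- Cluster unwrapping assumes each cluster fits in half a box; a percolating
  aggregate would be mis-unwrapped.
- The toy simulator's time, energy and concentration scales are reduced
  units; only ordering and mechanism are meaningful.
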