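# Methods

## Scope and model

`bzdyn` analyzes the conformational dynamics of alternating-GC DNA
duplexes in B- and Z-form, with optional 5-methylcytosine, at desk scale.
It does not run molecular dynamics: structures are idealized constructs,
trajectories are synthetic, and the solvation/entropy terms of the
MM/PBSA bookkeeping are consumed as inputs, never computed. What the
package owns is everything downstream of a trajectory: torsion and pucker
extraction, discrete-state statistics, Boltzmann-inversion profiles,
base-pair geometry, flexibility metrics and energy aggregation.

## Duplex construction

Pair frames are generated by composing canonical base-pair-step
parameters with the symmetric mid-frame (CEHS-style) scheme. Defaults:

| form | shift | slide | rise | tilt | roll | twist |
|------|-------|-------|------|------|------|-------|
| B (every step)   | 0 | 0    | 3.38 Å | 0 | 0 | +36° |
| Z, GpC step      | 0 | −1.1 Å | 3.7 Å | 0 | 0 | −51° |
| Z, CpG step      | 0 | +1.0 Å | 3.7 Å | 0 | 0 | −9°  |

The Z twists sum to −60° per dinucleotide (left-handed, 12 bp/turn); the
two distinct slides produce the bimodal slide/twist distributions
characteristic of the zigzag backbone. The construction parameters are
stored on the model (`step_parameters`) so any alternative fiber
convention is auditable.

Bases are planar idealized templates (regular-polygon rings,
literature-like bond lengths) positioned in the standard base reference
frame, with the glycosidic nitrogen and C1′ at the positions shared by
purines and pyrimidines; the complementary base is the 180° x-axis flip
of the pair frame. Because the analysis fits the *same* templates back to
the coordinates, builder → frame → step-parameter round trips are exact
(tested at 0.01 Å / 0.1°, observed at ~1e-13).

Sugars and backbone are attached per residue with the natural extension
reference frame (NeRF) so that the following take exact canonical values:

* χ (B: −117° anti; Z-G: +68° syn; Z-C: −159° anti),
* sugar pseudorotation (B: P = 162°, τₘ = 38°, C2′-endo; Z-G: P = 18°,
  C3′-endo; Z-C: P = 152°),
* δ (B 128°, Z-G 95°, Z-C 138°),
* ε and ζ at every phosphodiester junction (B: −169°/−103°, hence
  ε−ζ = −66° < 0, a BI backbone; Z-G: −104°/−69°; Z-C: −94°/+80°),
* γ at 5′-terminal residues (no upstream junction).

α, β and interior γ are then *emergent* from the helical geometry. For
the B-form they come out near canonical (α ≈ −83°, β ≈ 173°, γ in g⁺)
and the backbone is chemically continuous to within ~0.3 Å of standard
bond lengths at the O5′–C5′ link. For the Z-form the imposed ε/ζ
literature values are not perfectly compatible with the idealized frame
helix, which leaves a geometric seam at the O5′–C5′ link; Z-form α/β
values should therefore not be interpreted, while χ, δ, ε, ζ and the
puckers are exact by construction. The sugar ring itself is a
Cremer–Pople-puckered pentagon whose (q, φ) are solved numerically
(deterministic least squares) so the Altona–Sundaralingam phase and
amplitude hit their targets.

Methylation replaces nothing: it adds a single heavy atom C7 in the base
plane on the exterior bisector at C5 (1.50 Å) and renames the residue
5CM. The `all_non_terminal` rule reproduces the hypermethylated design
(8 of 10 cytosines in a 10-bp duplex). Hydrogens are not modeled; every
statistic here uses heavy atoms. Neutralizing-ion count equals the
phosphate count (2(N−1) for N bp), the net backbone charge magnitude.

## Torsions and pucker

Dihedrals use the two-argument arctangent form of the IUPAC convention
(cis = 0°, reported in [−180°, 180°)); collinear triplets are an error
for scalar input and NaN in array input. Terminal residues lacking the
atoms a torsion needs (α/β at 5′ ends, ε/ζ at 3′ ends) carry NaN and a
`terminal` flag — exclusion happens downstream, mirroring end-effect
trimming of duplex analyses.

Pseudorotation follows Altona–Sundaralingam with ν₂ = τₘ cos P (i.e.
νⱼ = τₘ cos(P + 144°(j−2))); the inverse generator uses the same
indexing, which makes the forward/inverse identity exact — note that the
naive νⱼ = τₘ cos(P + 144°j) indexing does not invert the arctangent
formula (it shifts P by 72°). Amplitudes below 1° are reported as planar
(undefined phase). Pucker states are the ten 36°-wide wheel names, each
the union of two half-open 18° sectors; a boundary phase belongs to the
upper sector. "O4′-endo" is the state some authors print as "O1′-endo".

## Discrete states

BI/BII is the sign of the minimal circular difference ε−ζ wrapped to
[−180°, 180°): negative → BI, positive → BII, exact zero → BI (a
deterministic measure-zero tie-break). The circular rule makes the call
independent of each angle's reporting range. Rotamers partition [0°,
360°) exactly: g⁺ [0,120), t [120,240), g⁻ [240,360); χ is syn on
[−90°, 90°). No debouncing is applied to single-frame dwells — passage
counts are raw transition counts. Dwells truncated by either trajectory
end are excluded from dwell means but retained in occupancy. Because it
is unstated whether published passage counts are per-trajectory sums or
per-residue averages, both are reported (`passages_total`,
`passages_per_residue`). Occupancy tables sum to 100% and can be split
by step type: CpG steps read the α/γ of G residues, GpC steps those of C
residues.

## Free-energy profiles

The sampled coordinate is wrapped to [−180°, 180°) before binning so the
18°-bin default yields exactly 20 bins (an unwrapped difference would
span 720°). G_b = −RT ln(n_b/N) with R = 1.987×10⁻³ kcal/(mol K),
T = 300 K by default, shifted so the occupied minimum is zero. Empty bins
are NaN, never pseudo-counted: the profile reports only what was sampled.
Well/barrier analysis takes the occupied minima on each side of a
boundary (default 0°), reports ΔG = G_right − G_left and the barrier from
each well (the ambiguity of which well a published barrier refers to is
resolved by reporting both), and flags profiles whose inter-well region
contains empty bins. KDE summaries use a Gaussian kernel with Silverman
bandwidth via scipy.

## Helix geometry and flexibility

Base frames are Kabsch fits of the idealized ring templates (proper
rotations enforced). Pair parameters apply the same mid-frame
decomposition between the flipped complementary frame and the Watson
frame (translations → shear/stretch/stagger, rotations →
buckle/propeller/opening); step parameters between successive pair
frames (twist positive for right-handed stacking). The decomposition and
its composition inverse round-trip to 1e-8, are rigid-motion invariant,
and obey strand-reversal parity (shift/tilt — and shear/buckle — negate).
This standard reference-frame scheme replaces curvilinear-axis analyses;
on strongly bent helices the two differ, a known limitation irrelevant to
the idealized fixtures here.

RMSD uses optimal superposition. The average structure is computed by
two rounds of superposition onto the running mean. B-factors are
B = (8π²/3)⟨|r−⟨r⟩|²⟩ per atom after superposing every frame onto the
average structure, averaged over each residue's heavy atoms (heavy atoms
chosen since hydrogens are unmodeled), terminals excluded by default.
For isotropic Gaussian noise of σ per axis the closed form is
B = 8π²σ² (7.11 Å² at σ = 0.3 Å); the superposition removes six rigid
degrees of freedom, biasing B low by ~1% at this system size.

## Synthetic dynamics: what it emulates, what it does not

`perturb_trajectory` models only uncorrelated isotropic thermal jitter —
exactly the null model under which B-factor and RMSF estimators have
closed forms. `simulate_two_state` is a two-state first-order Markov
chain (geometric dwells, mean dt/(1−p_stay); stationary occupancy
(1−p₂)/((1−p₁)+(1−p₂))) with von Mises emissions, the minimal circular-
emission model of BI/BII flips; dt defaults to 2 ps so picosecond
residence times read naturally. Defaults place the wells at ∓70° with
κ = 20, far enough from the 0° cut that sign classification recovers
ground truth with error ≪ 10⁻³. A Boltzmann helper sets the
self-transition probabilities equal to the stationary weights, giving
i.i.d. draws with occupancies p₁/p₂ = exp(ΔG/RT) for profile-recovery
checks. All generators are seed-deterministic.

What passing these tests shows: the *estimators* (classifier, dwell
statistics, fraction series, Boltzmann inversion, B-factors) are correct
on data whose ground truth is known. What it does not show: anything
about real MD ensembles — the generators have no kinetic correlations
between residues, no anharmonicity, no coupling between torsions and
helical parameters. Trajectory-derived published values (84%/92% BI,
216/28 ps dwells, ~6000 passages, ΔG_BI–BII of 1.6/2.08 kcal/mol) are
therefore used as generator *settings* whose recovery is verified, not as
quantities this package can re-derive ab initio.

## Energetics

Identities applied per snapshot, then averaged: E_MM = E_ELE + E_VDW +
E_INT; E_PBSOL = E_PBSUR + E_PBCAL; E_PBELE = E_ELE + E_PBCAL; E_PBTOT =
E_MM + E_PBSOL; G = E_PBTOT + TS, where the TS column holds the −T·S
contribution and is always an input (entropy estimation is out of
scope). E_PBSUR = γ·SA + b (γ = 0.00542 kcal mol⁻¹ Å⁻², b = 0.92
kcal/mol) when only a surface area is given; a precomputed E_PBSUR takes
precedence with a logged warning. SE = sample SD/√n. Contrasts are Welch
(unequal-variance) t-tests by default — the robust reading of an
unqualified "two-sample t-test" — with a paired variant for aligned
snapshots; −log₁₀P is computed from the log survival function so extreme
significances do not underflow. Zero-variance (constant-fixture) columns
yield t = ±∞ with ΔG still exact. Published energy tables whose cells
are not internally consistent are detected by recomputation, not
reproduced.

## Numerical choices and degenerate inputs

* Angles live in [−180°, 180°) internally; rotamer sectors rewrap to
  [0°, 360°). All sector conventions are half-open.
* Step decomposition handles the parallel-z (zero bend) case explicitly
  (hinge undefined → tilt = roll = 0).
* The sugar-ring (q, φ) solve is a deterministic least-squares with a
  four-point phase start grid; results are cached per (P, τₘ).
* PDB coordinates carry 10⁻³ Å precision; torsions survive a round trip
  to ~0.1°. Tables are CSV/TSV with mandatory headers; parsers reject
  (with line numbers) rather than drop malformed rows; inconsistent
  multi-model files name the offending model.
* Problem sizes used by the test-suite: 10⁶-step chains for occupancy
  (±0.01) and dwell (±5%) recovery, 1.6×10⁶ Boltzmann samples for ΔG
  recovery (±0.1 kcal/mol), 1.5–2×10³ frames for B-factor closed forms.

## Known limitations

* The Z-form backbone has a geometric seam at the O5′–C5′ link (see
  above); Z α/β are not meaningful. B-form α/β are emergent, near but
  not exactly canonical.
* Helical-axis parameters (x-displacement, inclination, …) and groove
  geometry are not computed; the step/pair parameter set covers the
  analysis surface.
* Base templates are idealized regular-polygon rings, adequate for frame
  fitting and torsion work, not for contact or H-bond geometry.
* ZI/ZII substates, hidden-Markov dwell fitting, WHAM reweighting and 2-D
  free-energy surfaces are out of scope.
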