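# Methods

This note documents the models implemented in `cgres`, their
assumptions, the defaults and why they were chosen, and what the test
suite does and does not demonstrate.

## Chain model and coordinates

A polypeptide of n residues is represented by 2n interaction sites:
the α-carbons Cα_i, which define chain geometry, and united side-chain
sites SC_i attached to them; united peptide groups p_i sit at the
midpoints (Cα_i + Cα_{i+1})/2 and are not independent degrees of
freedom.  Internal coordinates are the virtual-bond lengths d_i
(Å, reference 3.8), virtual-bond angles θ_i ∈ (0, π] with vertex at
Cα_i, right-handed virtual-bond dihedrals γ_i ∈ (−π, π] with axis
Cα_i→Cα_{i+1}, and side-chain polar/azimuth angles (α_i, β_i) defined
in the local bisector frame of θ_i (b̂ along the angle bisector, ê1
in-plane toward the previous Cα, ê2 = b̂ × ê1).  Terminal residues,
which lack one neighbor, use a virtual neighbor extrapolated from the
two nearest virtual bonds; this keeps every local frame a smooth,
rotation-equivariant function of the coordinates.  Collinear triples
are flagged (sin θ < 1e−9) and the affected dihedral is reported as 0
rather than raising.

Atomic models are mapped by taking Cα directly and the SC site as the
centroid of side-chain heavy atoms (Cβ and beyond); glycine's SC
coincides with its Cα.  Cα–Cα distances outside 2.6–4.6 Å are treated
as chain breaks and rejected with the residue indices named.

## Effective energy

The energy is a weighted sum over the standard united-residue term
inventory, with temperature factors

    f_n(T) = ln(e + e⁻¹) / ln(exp(x) + exp(−x)),  x = (T/T°)^(n−1)

(T° = 300 K) multiplying the mean-field electrostatic and torsional
terms (n = 2) and the third-order correlation terms (n = 3).  f₁ ≡ 1,
f_n(T°) = 1, and f_n → 0 as T → ∞; the factors express that these
terms descend from higher orders of a cumulant expansion of a
potential of mean force and therefore weaken with temperature.

The published, calibrated functional forms and parameter tables of the
individual terms are *not* reproduced here.  Each term is implemented
behind a named-term interface with a documented simplified stand-in,
and all tables are user-replaceable:

| term | stand-in form | default scale |
|------|---------------|---------------|
| U_SCSC | isotropic 6-12 with minimum at σ_ij; ε_ij = √(ε_iε_j), σ_ij = (σ_i+σ_j)/2 | ε 0.30 (0.45 hydrophobics) kcal/mol |
| U_SCp | purely repulsive ε(σ/r)⁶, excluding the two peptide groups flanking the side chain's own Cα | ε 0.20 kcal/mol, σ 4.0 Å |
| U_pp^VdW | 6-12 between peptide midpoints, pairs i < j−1 | ε 0.20 kcal/mol, σ 4.2 Å |
| U_pp^el | point-dipole interaction μ²[û_i·û_j − 3(û_i·r̂)(û_j·r̂)]/r³, dipoles along the virtual bonds | μ² 2.0 kcal·Å³/mol |
| U_tor | sin θ_i sin θ_{i+1} Σ_m c_m cos(mγ) — vanishes when a chain fragment becomes linear, which removes the indeterminacy of the dihedral there | c = (0.4, 0.2, 0.1) kcal/mol |
| U_b | harmonic in θ | k 5.0, θ₀ 1.90 rad |
| U_rot | harmonic in (ᾶ, β̃): ᾶ is the three-point angle at Cα between the neighbor-midpoint and the SC site, β̃ the corresponding four-point dihedral — an analytically differentiable variant of the bisector-frame (α, β) | k_α 2.0, k_β 0.5 |
| U_bond | harmonic Cα–Cα (d₀ 3.8 Å) and Cα–SC (per-type b₀); glycine's zero-offset SC uses the smooth ½k|r|² tether | k 50 / 10 kcal/mol/Å² |
| U_ssbond | stub returning 0 (disulfide energetics not implemented) | — |
| U_corr(3) | dipole-alignment coupling a(û_i·û_j)²(σ_c²/r²+δ²)³ over peptide pairs | a 0.10 kcal/mol |
| U_turn(3) | local sinθ-damped alignment −a sin θ cos θ | a 0.20 kcal/mol |

These stand-ins preserve the *structure* of the energy (term inventory,
temperature-factor placement, symmetry, short-range repulsion,
secondary-structure-scale stiffness) but are **not** a calibrated force
field; no quantitative claim about real-protein energetics is made or
tested.  All pair terms are soft-core regularized (r² → r² + r_s²,
r_s = 0.25 Å) so that random starting structures cannot produce
numerical overflow; this modifies the potential only below ~0.5 Å
separations, which are unphysical for these sites.

## Proton estimation

Interproton NMR restraints require proton positions the model does not
carry.  The default estimator places the amide H and Hα of each
residue at fixed offsets in the local bisector frame (offsets chosen to
put Hα ≈ 1.1 Å and HN ≈ 1.75 Å from the Cα, on the appropriate sides
of the backbone), and represents all side-chain protons by a single
pseudo-proton at the SC site pushed radially outward by a per-type pad
(0.8–1.5 Å).  Every position is an analytic function of at most four
site coordinates; exact Jacobians are propagated through the frame
construction, so restraint forces are available to MD.  The estimator
is deliberately pluggable: a published analytical proton-placement
scheme can be substituted without touching the restraint code.
Because the synthetic restraint generator uses the *same* estimator,
restraint-recovery tests validate the machinery, not the geometric
accuracy of the proton rules against real NOE data.

## Restraint penalties

**Angular (θ/γ).**  g(x) = 0 inside the band [x_l, x_u] (interpreted
mod 2π) and (1/4)(|δ| − w/2)⁴ outside, with δ the offset from the band
center wrapped to (−π, π] and w the band width.  The form is
2π-periodic and C¹; the quartic keeps forces gentle near the band and
strong for gross violations.  φ/ψ boxes are converted to θ/γ bands by
building ideal-geometry all-atom backbones on a grid over the box
(θ_i depends on (φ_i, ψ_i); γ_i on the dihedrals of residues i and
i+1, hence a 4-D grid), taking the min/max envelope, and padding by
1.5 grid spacings against discretization; the envelope is conservative
by construction.

**Distance (V_cont).**  Zero on [d_l, d_u]; outside, with Δ the excess,
A·Δ⁴/(σ⁴+Δ⁴)·(1 + κ·ln cosh Δ).  Defaults σ = 0.5 Å, A = 1 kcal/mol,
κ = 0.01.  The bounded well means wrong restraints saturate at ≈A and
cannot tear the structure apart; κ > 0 adds the gentle asymptote
A + κ(d−d_u) that keeps a small guiding force at large violation.
ln cosh is evaluated as |Δ| + ln(1+e^(−2|Δ|)) − ln 2 to avoid overflow.

**Ambiguity.**  An assignment set {d_i} sharing one signal scores
V = −(1/α) ln Σ_i exp(−α V_cont,i), the soft minimum: the set is
satisfied when any one member is.  Evaluated with the max-shift trick;
members with α(V_i − V_min) > ln(n/1e−9) are skipped, which bounds the
induced error below 1e−9/α kcal/mol and is verified against full
summation in the tests.  Group members share (d_l, d_u, A) by default;
per-member values are accepted but flagged as an extension.

**Crosslinks.**  The statistical potential uses the grouping
a + b·(d⁴/σ⁴)·exp(−d²/(2σ²)) + c inside the logarithm — a
Gaussian-damped quartic rise matching the shape of observed
crosslinked-pair distance distributions, with floor c guaranteeing a
finite value at any distance; the grouping is isolated in one function
so an alternative reading is a one-line change.  RT is fixed at the
conventional 0.591 kcal/mol (298 K).  The anchor-geometry family puts
the anchor X on the Cα→SC axis; the default is the full Cα–SC offset
(X = SC site, the natural stand-in for a side-chain tip attachment
atom), configurable per residue type as a fraction or an absolute
offset.  The multi-well distance form is evaluated through the
harmonic smooth-min identity V_d = (Σ_j 1/w_j)⁻¹,
w_j = a_j + ½k_j(d−d°_j)², which reproduces the single-well limit
exactly and is verified against the product/sum transcription as an
invariant.  Shipped coefficient tables are toy defaults; calibrated
tables drop in as data.  Glycine cannot carry an anchor-family
restraint (no Cα–SC axis) and is rejected by validation.

**SAXS.**  P^calc is a normalized sum of log-normal kernels over Cα
pairs with width σ_ij = (r°_i + r°_j)/r_ij, where
r°_i = ρ_i + σ_max + (σ_min − σ_max)(x_i + 1)/2 interpolates the
solvation shell between σ_min (buried, occupancy x = 1) and
(σ_min+σ_max)/2 (exposed, x = 0).  Occupancy is the clamped count of
non-bonded residues within 8 Å (saturating at 10); Stokes radii default
to a heavy-atom-count volume formula ρ = 1.68·N^(1/3) Å.  The penalty
is the cross-entropy −Δr Σ P^exp ln P^calc, minimized exactly at
P^calc = P^exp (Gibbs).  Gradients include the σ_ij(r_ij) dependence;
the occupancy, a piecewise-constant count, is treated as locally
constant.  ln arguments are floored at 1e−12 Å⁻¹.

## Sampling

Dynamics integrates both site families with diagonal effective masses
(backbone 56 amu ≈ CO–NH–CαH; SC the side-chain mass, 12 amu minimum)
— a simplification of the full coarse-grained Lagrangian, whose
constant inertia matrix couples neighboring sites.  Integrators:
velocity Verlet (NVE), Berendsen velocity rescaling (default τ = 1 ps),
and Langevin via BAOAB splitting (default γ = 1 ps⁻¹).  The default
step is 9.78 fs, stable for the default force constants; the NVE
conservation test uses 0.2 fs because Verlet's O((ωΔt)²) energy
oscillation must sit below the 1e−5 bar there.  Seeded runs are
bitwise reproducible.

Replica exchange attempts nearest-neighbor swaps in alternating parity
sweeps every exchange interval, with acceptance
min(1, exp[(β_i − β_j)(E_i − E_j)]); temperatures migrate between
replicas and velocities rescale by √(T_new/T_old).  Multi-temperature
samples are combined by binless WHAM: the dimensionless free energies
f_k of the source temperatures are iterated to self-consistency
(max|Δf| < 1e−8, log-sum-exp throughout), giving per-sample weights at
any target temperature; a single source temperature reduces exactly to
Boltzmann reweighting, and an effective-sample-size diagnostic warns of
poor overlap.  Ensembles are clustered by average-linkage hierarchical
clustering on pairwise Cα RMSD; each cluster's representative
minimizes the weighted RMSD to its cluster mates, and clusters are
ranked by summed weight.

GDT_TS is computed as the mean over the 1/2/4/8 Å cutoffs of the
maximal within-cutoff Cα fraction over superpositions seeded from all
contiguous 4-residue segments with up to four rounds of
within-cutoff refinement — the standard practical approximation of the
exhaustive search.

## Synthetic data and what the tests show

The fixture generator builds ideal-geometry references (helix: θ = 1.58,
γ = 0.90; hairpin: strands θ = 2.20, γ = 3.00 with a reversed-γ turn;
two-domain: two helices joined by an extended linker) and derives
restraints *from the reference*: every estimated interproton distance
below 5 Å becomes a [d−0.5, d+0.5] Å well (NOE-like scale), every θ/γ
gets a ±0.1 rad band, crosslink lists come from linker-compatible
residue pairs within reach, and P(r) is computed from the reference
itself.  By construction the reference incurs exactly zero penalty at
zero noise, which the tests assert.  Ambiguity is emulated by wrapping
each true restraint in a group with decoy members drawn from pairs
whose true separation violates the shared bounds by ≥2 Å.

The headline experiment folds a 20-residue helix from random starts by
4-replica REMD (280/300/325/350 K, 200,000 steps of 9.78 fs Langevin
dynamics per replica, exchanges every 1,000 steps) under noise-free
restraints, requiring the top-weight cluster representative within
2.0 Å Cα RMSD in ≥4 of 5 seeds, and repeats it with 30% decoy
ambiguous groups at a relaxed 3.0 Å.  These problem sizes keep the
whole experiment in the ten-minute range on one CPU while leaving the
task genuinely nontrivial (a random 20-mer start is 10–15 Å from the
target).  Passing demonstrates that the restraint gradients, the
ambiguous soft minimum, REMD bookkeeping, WHAM and clustering work
together correctly — it does **not** demonstrate predictive folding of
real proteins, which would require the calibrated energy tables and
far larger sampling.

## Numerical choices and limitations

* Units: kcal/mol, Å, rad, K, amu, fs; k_B = 1.987204e−3 kcal/mol/K.
  The acceleration conversion is 4.184e−4 Å/fs² per (kcal/mol/Å/amu).
* RT at 298 K is the field's conventional rounded 0.591 kcal/mol (the
  unrounded R×298 is 0.5922; the difference is 0.2%, far below any
  effect studied here).
* Degenerate geometry: collinear dihedrals evaluate to 0 with zero
  gradient (flagged); the sinθ damping of torsional and anchor-dihedral
  terms removes the force singularity there by construction.
* Coordinate singularities: the Cartesian gradients of θ, γ and of the
  bisector frame diverge as a bond angle approaches 0 or π (a
  coordinate, not a physical, singularity).  The gradient
  normalization factors are clamped there (sin θ at 0.01, |n|² of the
  dihedral at 0.01 Å⁴, frame norms at 0.05), which bounds MD forces at
  the cost of gradient accuracy only within ~0.01 rad of geometries
  that the angle terms already strongly disfavor; values are computed
  exactly everywhere.  Without the clamps, a thermal excursion through
  a near-straight angle can inject unbounded force in a single 9.78 fs
  step.
* Minimization is L-BFGS on the stacked site coordinates (scipy),
  converged at ‖∇V‖_∞ ≤ tol.
* The WHAM equilibration cut discards the first fifth of each
  temperature slot's samples.
* Restraints between protons fewer than two residues apart are accepted
  with a warning (they are unusual but not invalid in this model).
* Known limitations: no disulfide energetics; no multi-chain systems;
  plain temperature REMD only (no Hamiltonian or multiplexed variants);
  temperature ladders are user input; the intensity→P(r) transform is
  upstream of this package (supply P(r) in the CRYSOL layout).
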