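# Methods

## Model

`poredge` computes the free energy of a transversal pore edge in a lipid
bilayer within continuum liquid-crystal elasticity.  A monolayer is
described by a director field **n** (average lipid orientation) on its
neutral surface, with three quadratic deformation modes: splay
(B/2)(div **n** + J₀)² − (B/2)J₀², tilt (K_t/2)(**n** − **N**)², and
lateral stretch (K_A/2)α², where **N** is the surface normal and J₀ the
monolayer spontaneous curvature (lysolipid-positive convention).  The
hydrophobic core is locally volumetrically incompressible, which ties the
monolayer thickness to the fields:

    h_c = h − (h²/2) div n − h α.

Deformations at a pore edge are not small relative to any single flat
reference, so the edge is split into two segments, each linearized about
its own reference:

1. **Horizontal bilayer region** (ρ ≥ R₀): fields n(ρ) (radial director
   projection) and α(ρ); the neutral-surface height H(ρ) follows from
   incompressibility.  The Euler–Lagrange equations are solved by
   cylinder harmonics Z₁(pρ), Z₀(pρ) with complex wavenumbers p from the
   characteristic quartic

       (1+σ) h²(Ah²+4l²) p⁴ − 4(A(h²−l²) − σh²) p² + 4A = 0,

   l² = B/K_t, A = K_A/K_t, σ = σ₀/K_t.  For every registered lipid the
   discriminant is negative, the two p² form a conjugate pair, and the
   decaying real solution space is spanned by one outgoing Hankel mode
   H⁽¹⁾(pρ) (Im p > 0) plus its conjugate — exactly two real degrees of
   freedom, fixed by n(R₀) = n₀ and H(R₀) = Z₀.  (A commonly quoted
   closed form for these roots is inconsistent with the corresponding
   Euler–Lagrange equations by a factor of √2 in p²; the quartic above
   is derived from the functional directly and validated against an
   independent discretized minimization.)

2. **Vertical monolayer region** (the pore-lining wall): fields v(z)
   (axial director projection), m(z) (tail-end radius deviation), β(z)
   (stretch), expanded about a reference cylinder of neutral radius
   R_v = r (the waist radius), with the neutral-radius deviation u slaved
   by incompressibility, u = R_v²/(2R_v²+h²)(2m + 2hβ + h²v′).  Because
   the energy depends on m and β only through m + hβ, the β equation
   reduces to K_A β = 0: the wall carries no stretch energy.  The
   second-order Lagrangian (measure 2πR√(1+R′²) and 1/R both expanded to
   second order) is assembled numerically as a quadratic form; the
   exponential-mode symbol then yields a biquadratic characteristic
   equation — exactly four modes, although the nominal differential order
   is six, because v″ and m′ enter only through u′ (the same degeneracy
   makes the natural boundary conditions identically satisfied).  The
   four amplitudes are fixed by v and u at the two ends of the wall:
   mirror symmetry (v = 0) or the belt rim, and the junction circle.

3. **Hydrophobic belt** (pre-pore intermediate): a water-filled cylinder
   of radius r and height 2L whose side wall exposes lipid tails.  Its
   cost follows mean-field water-ordering theory,
   W_h = 4πrL σ_h I₁(r/ξ_h)/I₀(r/ξ_h), with tail/water tension σ_h and
   decay length ξ_h; the belt rim also prescribes the wall director,
   v(L) = −L/√(L² + (h−L)²), by incompressibility.  Evaluated with
   scaled Bessel functions (overflow-safe).

The segments are conjugated along the circles {R₀, ±Z₀} by continuity of
the neutral surfaces and of the director, H(R₀) = Z₀, R(Z₀) = R₀ and
n(R₀) − v(Z₀) = 1; the junction circle itself is optimized by gradient
descent (backtracking line search plus Newton polishing) until the
central-difference gradient norm is below 10⁻⁷ k_BT/nm.

## Junction-director closure

The condition n₀ − v₀ = 1 is the chord linearization of the exact
quarter-turn continuity n₀² + v₀² = 1.  Treating the leftover director
value as a free variational parameter is *not* well posed for this
linearization: the truncated functional admits a branch in which the wall
performs the entire turn (v → −1) while everting (u′ ≈ −v), whose energy
the quadratic expansion prices near zero although the exact functional
does not (both |v| and the geometric rotation rate leave the linear
regime).  We verified with the independent discretized-functional
minimizer that this branch is a true minimum *of the truncated model* —
i.e. it is a defect of the linearization, not of the solver.

The closure adopted here confines each segment to its trust region:
the bilayer deviation may carry at most half the linearized turn
(|n₀| ≤ ½), and the wall may not rotate the junction director beyond the
larger of half the turn and the rim value already imposed by the belt,

    θ = clip(θ*, 1 − max(½, |v_rim|), ½),

with θ* the unconstrained quadratic vertex.  The rule is parameter-free,
continuous in L (it reduces to the symmetric split θ = ½ for hydrophilic
pores), and leaves the hydrophobic-defect branch essentially variational
(the clip is inactive or marginal there).  Its consequences are examined
quantitatively in the Limitations section.

## Trajectory construction

The pore state is parametrized by (r, L).  For each radius the energy is
minimized over the belt half-height (grid scan, default step 0.1 nm along
trajectories and 0.05 nm in dedicated belt scans, with parabolic
refinement of interior minima); belt scanning is restricted to small
radii where the defect branch can compete (default r ≲ 0.55 h).
Junction optimizations are warm-started along scans.  Landscape features
are extracted from the trajectory with three-point parabolic refinement:
the transition radius (local maximum of W), the metastable hydrophilic
pore (local minimum, reported only when deeper than 0.25 k_BT — the
noise floor of the quadrature/optimization tolerances), the forward and
reverse barriers (relative to the intact bilayer, W(0) ≡ 0), and the
line-tension curve γ(r) = W/(2πr).

The asymptotic line tension γ₀ is taken from the slope of W(r) fitted
over the top radius range (20–50 nm by default), which converges faster
than γ evaluated at the largest radius (the two still differ by ~5% at
r = 50 nm because the metastable dip relaxes slowly; both are reported).

The degeneracy radius — where the hydrophilic pore and the hydrophobic
defect minima of W(L) have equal energies — is found by bisection on the
branch difference and characterizes the "flicker" regime: two states of
equal energy but very different lumen hydrophobicity separated by a
barrier of order 1–2 k_BT.

## Parameters

Internal units: energy k_BT (4.14·10⁻²¹ J exactly, the constant against
which all registry values are stated), length nm.  Registered monolayer
parameter sets (tilt modulus 40 mN/m for all): a reference model lipid
(B = 8 k_BT, K_A = 100 mN/m, h = 2 nm, J₀ = 0) with single-parameter
variants (J₀ = ±0.1 nm⁻¹; B = 5.3, 12 k_BT; K_A = 67, 150 mN/m;
h = 1.3, 3 nm; and the constant-B/h pairs), and DOPC
(10.3 k_BT, 133 mN/m, 1.45 nm, −0.091 nm⁻¹ — the alternative published
value −0.11 nm⁻¹ can be set via override), POPC (11, 117, 1.46, −0.022)
and DMPC (6.8, 117, 1.37, +0.075).  Environment: lateral tension σ₀
(kept as a parameter; all shipped results use σ₀ = 0), tail/water
tension σ_h from 36 mN/m, hydrophobic decay length ξ_h = 1 nm (1.5 nm
supported).  DOPC confidence intervals are exposed as a 2⁴ corner sweep
(`dopc_uncertainty_sets`) rather than a guessed subset.

## Numerics

* Bilayer energies: composite Gauss–Legendre quadrature to
  ρ_max = R₀ + max(30 nm, 12/Im p); the neglected tail is below
  10⁻⁸ k_BT.  Wall energies: panel count scales with |q|·(Z₀ − z_lo).
* Boundary systems are solved densely with column equilibration;
  condition numbers above 10¹² trigger a warning, not failure.
* Junction gradients: central differences with step 10⁻⁵ nm.  (A much
  smaller published increment would sit below double-precision noise;
  the stopping criterion, not the step, defines the answer.)
* Characteristic roots: `numpy.roots` on the determinant polynomial with
  leading coefficients below 10⁻⁹ of the maximum trimmed (the degree-6
  terms cancel structurally).
* The discretized route (`poredge.discretized`) works in first-order
  variables — (n, H) for the bilayer, (v, u, β) for the wall — because
  discretizing in the native variables, where higher derivatives enter
  only through the surface shape, admits parasitic grid-scale modes.
  Its second-order wall density is generated symbolically from the exact
  integrand, independently of the hand-assembled quadratic form.

## Scope of the shipped computations

Full trajectories use radius grids dense (0.05 nm) through the
transition region, 0.1 nm through the metastable region, and sparse up
to 50 nm; one lipid takes on the order of a minute on one CPU.  The
acceptance script runs three real-lipid curves plus the reference
landscape at these sizes.

## Limitations

* The two-segment decomposition overestimates edge energies relative to
  finer decompositions (by up to roughly 30%); no
  three-segment refinement is implemented.
* The trust-region closure is a regularization of an ill-posed
  linearized matching, not a variational principle.  With it, asymptotic
  line tensions and the transition-region landscape (barrier, transition
  radius, belt-height degeneracy) reproduce the reference values of this
  model family closely,
  but the metastable well at r ≈ (1–2)h remains too deep: the partial
  meridional/equatorial splay compensation that creates the well is
  over-effective in the quadratic expansion.  Consequently the minima of
  γ(r) at r ≈ 2–4 nm come out 20–30% below the reference values (closer,
  in fact, to the experimental 10–12 pN range for small DOPC pores), and
  the reverse barrier of the reference lipid is ~16 k_BT rather than
  ~10 k_BT.  These deviations are intrinsic to our reading of the
  printed functional; no further parameter exists to tune them without
  departing from it.
* β ≡ 0 in the wall means the model assigns the wall no stretch energy;
  all stretch resides in the bilayer region.
* σ₀ > 0 is plumbed through (characteristic roots, energy terms, area
  terms) but untested against published results; the printed functional
  is ambiguous about a factor in the σ-term, which is irrelevant at
  σ₀ = 0.
* Single-component membranes only; no Gaussian (saddle-splay) term; no
  stochastic dynamics (the closure-rate helper is deterministic
  overdamped dynamics).
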