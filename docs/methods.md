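# Methods

## Community model construction

A strain model is a constraint-based model (CBM): metabolites × reactions
stoichiometric matrix **S** (reactants negative, products positive),
steady-state mass balance **Sv** = 0, flux bounds *l* ≤ *v* ≤ *u* in
mmol·gDW⁻¹·h⁻¹, and a linear growth objective with exactly one biomass
reaction per strain.  Exchange fluxes are signed so that positive flux
exports the metabolite out of its compartment.

`assemble_community` builds the community matrix **S**^σ block-diagonally
from the strain matrices and adds one *pool* row per shared metabolite.
The pool row mirrors every strain exchange column of that metabolite with
sign −1 (a strain export deposits into the pool) and carries a −1 for the
pool→environment exchange column.  Pool metabolites obey strict steady
state — there is no accumulation term — so every unit of cross-fed
metabolite is accounted for.  Environment-exchange bounds live in the
`PoolSpec`; the default for an unlisted shared metabolite is export-only
(0, 1000), because finite, explicitly chosen nutrient supplies are what
make community fronts non-trivial.  Linear flux couplings (for example a
fixed oxygenase/carboxylase ratio v_a − ρ·v_b = 0) are stored symbolically
and appended as extra LP rows rather than folded into **S**^σ, which keeps
the stoichiometric matrix purely chemical.

## LP layer

All analyses compile to one standard form (maximize c'v over equality
rows, inequality rows and box bounds) solved with scipy's HiGHS backend.
Feasibility is trusted to ~1e-7 (the solver's default class) and ranges
and vertices are compared at 1e-6.  Single-objective FBA reports
infeasible/unbounded in its status rather than raising; FVA additionally
requires a non-negative optimum before imposing c'v ≥ α·z*, because
α-scaling a negative optimum silently inverts the constraint's meaning
(growth objectives are non-negative, so this is an error, not a choice).

## Exact Pareto fronts (MO-FBA)

With one growth objective per member, the solution set of the
multi-objective LP is the Pareto front — the non-dominated part of the
boundary of the attainable image Y = {C'v : v feasible} in objective
space.  `solve_mofba` computes the exact vertex/facet description by a
primal Benson-type outer approximation:

1. per-objective maxima give the ideal box (unbounded objectives raise an
   error naming the strain); per-objective minima, pushed down by a
   margin, give artificial lower bounds that no genuine vertex can touch;
2. the outer polytope's vertices are enumerated (halfspace intersection
   around the Chebyshev center);
3. for each unverified vertex y, the LP ``min t s.t. C'v ≥ y − t·1``
   measures attainability along the all-ones direction; its dual weights
   w ≥ 0 (normalized to Σw = 1) define the supporting hyperplane
   ``w·y ≤ max_v w·C'v``, and the deepest-violating vertex's cut is added;
4. the loop ends when every outer vertex is attainable within tolerance
   (default 1e-6; gap checks run at a tenth of that).  Each final vertex
   is "polished" to the image of the attaining flux vector, so every
   reported vertex is certified by a feasible community state.

Vertices are deduplicated componentwise at 1e-6 with lexicographic
tie-breaking.  Reported facets are the supporting halfspaces tight at
enough vertices to carry a (k−1)-dimensional face of the efficient image;
faces that contain only dominated points (e.g. the vertical face below an
axis vertex) are intentionally omitted, since the front describes
efficient points only.  Because growth objectives are required bounded,
the `rays` field is an empty list in normal use.

Scalarizations serve as independent routes to the same object.
`weighted_sum` returns a Pareto-optimal image point for every valid weight
vector: for strictly positive weights this is the classical convexity
result; for weights with zeros a second LP maximizes the plain sum of
objectives over the first-stage optimal face, discarding weakly efficient
alternatives.  The second stage tolerates only the solver's objective
round-off (1e-12 relative): a looser slack would let the solution drift
off the optimal face along shallow edges by an amplified amount.
`epsilon_constraint` maximizes one objective under floors on the others
and returns a weakly efficient point.  `verify_front` samples strictly
positive weight vectors (seeded Dirichlet), solves each weighted-sum LP
and checks that every solution lies on the front boundary and dominates no
vertex — the property that must hold by convexity if the front is correct.
In the test suite a dense weight-grid scalarization plus the closed-form
fronts of the synthetic generators act as the independent oracle for the
Benson solver; the two routes are never collapsed.

## MO-FVA

At a Pareto point **f**\*, flux ranges are the per-reaction min/max
subject to the componentwise (vector) constraint **C**ᵀ**v** ≥ α·**f**\*:
each strain keeps at least the fraction α of its growth at **f**\*.  A
zero component makes that strain's floor vacuous; a point strictly above
the front makes the base problem infeasible, which is reported as such.
The default α = 0.9.

Three-member fronts are swept with a barycentric lattice over the triangle
spanned by the three per-strain-maximum vertices: points at
(i/n, j/n, (n−i−j)/n), i.e. (n+1)(n+2)/2 points.  Two lift modes exist:
`flat` (default) takes the plain convex combination of the anchors — on or
below the front, hence always feasible for α ≤ 1 floors and comparable
across models — and `epsilon` pushes each point onto the Pareto surface by
an ε-constraint LP along its largest-weight objective.  Regional
aggregation scales the barycentric weights by r and takes floors: floor
sums of r−1 select an upward sub-triangle, r−2 a downward one, giving
exactly r² congruent regions; lattice points on region boundaries are
assigned deterministically by an infinitesimal pull toward the centroid.
Region values are the means of member-point MO-FVA maxima (and minima).
Every per-point problem is an independent LP, so results are
order-independent.  An r that leaves a region empty is rejected rather
than silently merged.

## Thermodynamics

Chemical potentials follow μᵢ = μᵢ⁰ + RT ln(xᵢ/xᵢ⁰); allowing the
concentration to range over x⁰·10⁻ᵐ … x⁰·10ᵐ yields the symmetric
interval μᵢ⁰ ± dg with dg = RT ln(10ᵐ) (`compute_dg`; R = 8.314 J/mol/K).
At 75 °C and a three-decade window, dg ≈ 20 kJ/mol.  The photon potential
is anchored by requiring the photon-driven glucose-synthesis reaction
(6 CO₂ + 6 H₂O + 48 hν → C₆H₁₂O₆) to sit at equilibrium: Δμ = 0 gives
μ_hv = Σ Sᵢ μᵢ⁰ / 48 (`photon_potential`), and the calculation is
homogeneous under rescaling of the stoichiometry.

The chemical motive force cmf = Σᵢ μᵢ vᵢ over boundary fluxes measures the
external chemical potential consumed to sustain the non-equilibrium steady
state.  Uptake from the environment counts positive, so intake of
high-potential nutrients (photons) raises the cmf; `cmf_over_mesh`
accordingly negates the pool→environment export axis before maximizing.
Over the MO-FVA boxes [aᵢ, bᵢ] × [μᵢ⁰ − dg, μᵢ⁰ + dg] the objective is
separable and bilinear, so each pair's maximum lies at a rectangle corner:
`corner_exact` enumerates the four products per metabolite and is exact.
The `numeric` mode retains a truncated-Newton (TNC) gradient ascent as an
independent numerical cross-check; it is run per metabolite pair from the
four box corners, which guarantees convergence to the pair's global corner
(a single joint start can stall in the sign-symmetric local optimum) while
still exercising a genuinely gradient-based route.  `numeric` can never
exceed `corner_exact`, and agreement to 1e-6 relative is enforced in the
tests.  Reported cmf units are kJ·gDW⁻¹·h⁻¹, taken directly from the
mmol-based exchange fluxes; no biomass-concentration normalization is
applied.

## Synthetic generators

`make_competition` builds k strains drawing one pooled nutrient with
per-strain yields y_j; the front is known in closed form (the simplex
Σ f_j/(y_j·cap) ≤ 1 with axis vertices y_j·cap), which makes it the
primary oracle for the MOLP solver.  `make_crossfeed` adds a producer that
fixes an environmental substrate into an organic acid that is the
consumers' only carbon source, so consumer growth is provably zero when
the producer is off.  `random_community` draws seeded random communities
that are feasible and bounded by construction: every strain carries a
guaranteed substrate→biomass chain on a supply-capped pooled nutrient, and
random conversion coefficients never exceed 1 so no reaction cycle can
create mass.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; there is no global random state.

## The hot-spring fixture (synthetic stand-in)

The packaged three-guild community (SYN/FAP/SRB) emulates a phototrophic
hot-spring mat: SYN fixes CO₂ photosynthetically with an obligate 0.03
flux ratio between `RXN-961` (oxygenase, glycolate-producing) and
`RIBULOSE-BISPHOSPHATE-CARBOXYLASE-RXN`, assimilates nitrate, and exports
surplus ammonia and acetate, which are the consumers' only nitrogen and
reduced-carbon sources; SRB additionally respires sulfate to H₂S.  The
guild stoichiometries are *not* curated genome-scale networks: they are a
stand-in whose biomass quotas and community supply caps (photons, nitrate,
phosphate, sulfate) were calibrated analytically — the three binding
community resource constraints are planes chosen to pass exactly through
the benchmark front geometry — so that each guild's solo FBA optimum is
1 h⁻¹ and the community front has exactly five vertices, (1,0,0),
(0,1,0), (0,0,1), (0.27, 0, 0.89) and (0, 0.46, 0.65), with growth sums
1.16 and 1.11 h⁻¹ at the two mixed optima.  Passing fixture tests
therefore validates the *algorithms* against a community with known exact
structure, not the biochemistry of any real mat.

The fixture's thermodynamic table is synthetic in the same sense:
potentials are internally consistent but expressed on an arbitrary
per-element reference (only stoichiometrically balanced combinations are
physically meaningful).  The CO₂/H₂O/glucose entries are chosen so the
glucose-synthesis equilibrium yields μ_hv = 68.6 kJ/mol; water and photons
have dg = 0 (fixed 1 M / fixed activity) and all other species dg =
20 kJ/mol at 348.15 K.  The remaining potentials were set once, from the
model's forced-flux economy, so that the maximal-cmf surface is positive
over the whole front and peaks at the SYN corner with SRB growth the
strongest depressant — the qualitative pattern expected when primary
production consumes the largest external potential.  Absolute cmf values
have no literature meaning.

## Numerical choices and edge cases

* LP feasibility 1e-7; vertex/range comparisons 1e-6; Benson attainability
  gap 1e-7; vertex dedup lexicographic at 1e-6.
* Degenerate (flat) outer polytopes fall back from halfspace intersection
  to exhaustive plane-triple enumeration.
* k = 1 communities short-circuit to plain FBA (the front is one point).
* FVA min/max crossing by solver jitter on a pinned flux is collapsed to
  the midpoint.
* Mesh lift is `flat` by default; `epsilon` lift is available where points
  on the curved front are wanted.
* Problem sizes in the shipped analyses: the fixture community has 32
  reactions; acceptance and tests sweep an n = 10 mesh (66 points) for
  MO-FVA/cmf and verify the n = 100 / r = 15 lattice geometry (5151
  points, 225 regions) combinatorially, which keeps the full suite at
  interactive runtimes on one CPU.

## Known limitations

* Front meshing and regional aggregation support exactly three objectives;
  k > 3 fronts are computed but must be sampled by other means.
* Facets of the efficient image are reported; faces consisting solely of
  weakly efficient points are omitted by design.
* The cmf maximization treats the per-reaction MO-FVA ranges as an
  independent box (the standard relaxation); joint flux feasibility of the
  reported (μ, v) corner is not enforced.
* SBML support covers level-3 FBC bounds/objectives as exposed by cobrapy;
  exotic SBML constructs (groups, kinetic laws) are ignored.
* Thermodynamic screening is a post-processing step; concentrations are
  not variables inside the LP.
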