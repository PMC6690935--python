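# Methods

`nichesim` couples an off-lattice, cell-based model of a growing tumour to
a lattice-based model of a perfused, remodeling microvascular network
through quasi-static continuum fields on a cubic grid. This note records
the model equations, the parameter choices that matter, the numerical
methods, and what the desk-scale study conditions do and do not represent.

## Vascular network and hemodynamics

The initial vasculature is a regular cubic capillary mesh (default 9×9×9
nodes, 80 μm spacing) with every −x-face node held at the arterial
pressure (10 kPa) and every +x-face node at the venous pressure (2 kPa);
segments touching those faces are classed arteries/veins and are exempt
from regression. A cubic lattice is used rather than a face-centred one:
at desk scale the difference is a constant factor in vessel density,
and the cubic geometry keeps the inter-capillary spacing — which sets the
early-stage distance ceiling — explicit and exact. Segment radii carry a
±10% seeded jitter so that bifurcation flow splits are generically
asymmetric.

Blood is a Poiseuille fluid: segment conductance G = πr⁴/(8ηL), mass
conservation at every node, Dirichlet pressures at boundary nodes. The
apparent viscosity η(d, H) = η_plasma · η_rel(d, H) follows the Pries
empirical diameter–hematocrit law for tube flow, which is exactly 1 for
pure plasma and has the Fåhræus–Lindqvist minimum near d ≈ 7 μm at
H = 0.45. (The variant with an endothelial-surface-layer factor was
considered and rejected: its H → 0 limit is not plasma viscosity, which
breaks the definitional limit the rheology should satisfy; the difference
between the two laws is well below the other uncertainties at capillary
scale.) Wall shear stress is τ = 4η|Q|/(πr³).

Discharge hematocrit propagates downstream in topological order of the
flow. At diverging bifurcations the red-cell flux splits according to the
Pries logit phase-separation relation (parameters A, B, X₀ as functions
of daughter diameters, parent diameter and hematocrit); junctions with
more than two outflows split proportionally to blood flow; zero-flow
segments inherit the mixed hematocrit of their upstream node with a
lowest-segment-id tie-break. Cyclic flow orientations (possible after
remodeling) fall back to damped sweeps with a convergence check.
Red-cell flux is conserved at every junction to round-off.

## Oxygen

Blood O₂ content is carried per unit volume as C(p) = p + H·κ·S(p) in
dissolved-pO₂ units, with S the Hill saturation curve (p50 = 27 mmHg,
n = 2.7) and κ = 1.6·10⁴ mmHg the bound-capacity equivalent, so that at
physiological hematocrit nearly all content is hemoglobin-bound. Along a
perfused segment, Q·dC/ds = −2πr·γ·(p − p_tissue), integrated with
backward-Euler substeps (Newton per substep; the map C(p) + k·p is
strictly monotone). At junctions, content fluxes mix flow-weighted and
the mixed pO₂ is recovered by inverting C. Inlet nodes take the arterial
pO₂ (80 mmHg).

Tissue-side fields obey steady reaction–diffusion equations
∇·(D∇c) − λc + S − M(c) = 0 discretized with the 7-point finite-difference
stencil (the parent codes used finite elements; at the smooth, desk-scale
geometries used here finite differences are equivalent and much simpler).
Michaelis–Menten sinks M(c) = m₀c/(c + c_half) are handled by a damped
lagged-coefficient iteration (relative tolerance 10⁻⁶), which preserves
the discrete maximum principle at every iterate. The linear systems are
solved with Jacobi-preconditioned conjugate gradients warm-started from
the previous field (the operators are symmetric positive definite).

Vessels exchange with the grid through their rasterized centrelines: each
piece Δs of a segment crossing a voxel contributes a linear exchange term
γ·2πr·Δs·(p_blood − p_voxel)/V_voxel. The blood and tissue problems are
alternated until the largest tissue pO₂ change falls below 0.1 mmHg; at
convergence the vessel release balances tissue consumption to 1%.

Defaults (all config-exposed): D_O₂ = 2000 μm²/s, tissue Michaelis
constant 4 mmHg, transmural transfer coefficient γ = 30 μm/s. γ was set
so that a capillary mesh at 80 μm spacing keeps resting tissue at
40–70 mmHg but drops it into the hypoxic range when the local consumption
density multiplies severalfold inside a packed tumour — the regime the
angiogenic switch needs.

## Cell agents

Each agent is a two-compartment structure: an intracellular pool (pO₂ p,
glucose c, lactate l) exchanging with the extracellular environment
sampled from the grid at the cell centre. The per-cell ODEs are

- dp/dt = [P_m·A·(p_env − p) − q(p)]/V with q(p) = q_max·f(p)·g(pH)·
  (n_mito/n_ref)·(V/V_ref), f a Hill factor (p50 = 1.5 mmHg, n = 2) and
  g a Gaussian bell in extracellular pH (optimum 7.35, width 0.8);
- dc/dt = [V_max·A·(sat(c_env) − sat(c)) − s_og·q(p) − u_an]/V, a
  facilitated carrier minus oxidative use (stoichiometrically tied to
  oxygen, s_og = 2.2·10⁻⁴ mM/mmHg ≈ α/6) minus anaerobic glycolysis
  u_an ∝ (1 − f(p))·sat(c);
- dl/dt = [2·u_an − P_lac·A·(l − l_env)]/V — two lactate per glucose.

The system is stiff (membrane exchange equilibrates in ~0.3 s against
10 s steps), so each step is one backward-Euler solve with damped Newton
(batched over the population, numeric Jacobians, 3×3 solves); steps
producing negative pools are halved and retried. Extracellular pH is
algebraic: pH = 7.4 − 0.15·[lactate] (clamped to [6.0, 7.6]), with the
lactate field fed by cellular export and cleared by diffusion plus a
3·10⁻³ s⁻¹ decay.

Cycle progression G1m → G1p → S → G2 → M uses nominal durations
6/5/8/3/1 h scaled per-cell by a phenotype factor; the clock advances at
a nutrient-dependent rate ν = f_O₂ · f_glc ∈ [0, 1] ("stretching" under
scarcity). Growth adds volume at rate ν·(V_div/2)/T_growth, so a daughter
doubles its volume over one nominal cycle; the G1p→S gate requires radius
≥ 9 μm (chosen so the gate is reached exactly on schedule under full
nutrition). Mitochondria partition Binomial(n, ½) at mitosis and regrow
deterministically at ν·n_ref per cycle, making the endowment stationary
across generations. Death occurs after 8 h of continuous intracellular
anoxia (p < 1 mmHg) or instantly below pH 6.1; dead cells are inert and
shrink exponentially toward 6 μm. Division places daughters at ±ε along a
uniformly random axis (cells are not polarized), each with radius
2^(−1/3) of the parent.

Neighbour relations are the Delaunay edges of the cell centres capped at
30 μm; degenerate configurations are retried with a deterministic jitter
of 10⁻⁶ μm. Mechanics is overdamped: repulsion k_r·(d_eq − d) inside the
equilibrium distance (sum of radii), adhesion in a 2 μm shell outside it,
displacement capped at 0.1·radius per step. The spheroid surface is the
boundary of the alpha complex (tetrahedra with circumradius² ≤ α,
α = (3·mean radius)²).

## Coupling and scheduling

Cells deposit their instantaneous consumption/production rates onto the
grid with the cloud-in-cell (trilinear) kernel, whose adjoint serves as
the environment sampler; the deposited total equals the summed rates to
round-off. Nearest-vessel distances are exact point-to-segment distances
with k-d-tree pruning over segment midpoints (lower bound: midpoint
distance minus half-length), giving brute-force-identical results at
near-linear cost — the trimming that reduces the cell–vessel coupling
from O(N_C·N_BV) to O(N_C).

Three cadences drive the main loop: dt_cell = 10 s (metabolism, cycle,
mechanics), dt_fields = 600 s default (field refresh; fields are
quasi-static relative to both neighbours, so any value between the two
extreme scales works), dt_vessel = 1 h default (flow, hematocrit, coupled
oxygen, remodeling). Remodeling stays off until the VEGF field first
exceeds its threshold. Single-threaded determinism for a fixed seed is a
contract; every stochastic choice draws from one PCG64 stream.

VEGF is emitted only by living cells with intracellular pO₂ below 5 mmHg,
deposited as point sources and diffused with a 10⁻² s⁻¹ decay
(penetration ≈ 100 μm), which ties the angiogenic signal directly to the
hypoxic niche structure.

## Vascular remodeling

Per vessel tick, inside-tumour segments (midpoint inside the alpha-shape
volume of all cells) dilate by 0.4 μm up to 10 μm; inside-tumour segments
with wall shear below 1 Pa collapse with probability 0.25 per tick;
immature vessels (capillaries and sprouts past a grace age) in the tumour
neighbourhood whose midpoint VEGF falls below 2·10⁻⁴ regress. Regression
is restricted to the tumour neighbourhood (alpha shape plus one lattice
spacing): an unrestricted low-VEGF rule would delete the entire healthy
far-field mesh within the grace period, which contradicts the requirement
that the network remain perfusable — co-option-driven regression is a
tumour-local process. Arteries and veins never regress. Sprouts launch
from segment midpoints where VEGF exceeds the remodeling threshold
(probability 0.1 per site-hour), walk one lattice step per tick up the
VEGF gradient with random tie-breaks, anastomose when they pass within
45 μm of a foreign vessel (stepping exactly onto an existing node is an
anastomosis, never a duplicate), and are abandoned past 320 μm. After
every tick the network is pruned: collapsed segments, dead-end branches
(active sprout chains exempt) and components cut off from every boundary
are removed, and flow/hematocrit/shear are re-solved, so the network is
always perfusable and flow-conservative.

The remodeling thresholds (τ_crit, collapse probability, VEGF levels)
have no published values; they were fixed once against the scaled-down
growth scenario below — chosen so that the angiogenic switch fires after
the hypoxic core forms and interior clearance completes within a few
vessel ticks — and are not tuned per run.

## The desk-scale study conditions

The reference experiment seeds one tumour cell at the centre of the
default mesh and follows growth through the angiogenic switch. Two
compressions make this a desk-scale computation rather than a multi-week
run over ~10⁶ entities:

1. **Agent granularity** — one agent (division radius 10 μm) stands for a
   small cluster of tumour cells; its maximal O₂ consumption
   (2·10⁵ mmHg·μm³/s ≈ 25 mmHg/s at packing density) is set to the
   consumption density of packed tumour tissue, so the oxygen landscape
   is that of real tissue even though agent counts stay in the thousands.
2. **Time compression** — all biological clocks (cycle phases, starvation
   time, regression grace, maturation) are divided by 20, so the cell
   cycle is 1.15 h and the full avascular → vascular development fits in
   ~15 simulated hours. Stage equivalences: the angiogenic switch at
   ~13 h corresponds to the early stage of a ~280 h tumour, and the
   hollowed-out late stage at ~14–16 h to ~580 h. Transport and
   hemodynamics are quasi-static, so compressing biology against them
   changes only the ratio of remodeling ticks per cell cycle, which the
   per-tick probabilities absorb.

Under these conditions the simulation reproduces the defining
microenvironmental signature: while the mesh is intact, no cell is
farther than ~57 μm from a vessel (the cubic-lattice bound
√2/2 × 80 μm ≈ 57 μm, within the 0–80 μm early range); after dilation,
collapse and regression hollow out the interior, central cells sit beyond
160 μm from the nearest surviving vessel, and sprouting later re-enters
the gap — the same reversal seen in the inter-vessel pO₂ line samples.

`scripts/acceptance.py` runs exactly this study: it advances in hourly
checkpoints, records the maximum nearest-vessel distance at the last
checkpoint before any collapse/regression event (early stage) and at the
first checkpoint where no vessel remains within two lattice spacings of
the tumour centroid (late stage, the vessel-free-interior regime), and
writes both in μm.

### What the generator does not emulate

The synthetic scenario has no stromal or immune cells, no interstitial
fluid pressure, no lymphatics, a regular (not hierarchically grown)
initial vasculature, and a minimal three-metabolite biochemistry. Passing
tests therefore demonstrate the coupled mechanism — perfusion-limited
oxygenation, hypoxia-driven remodeling, niche formation — at reduced
scale, not quantitative agreement with any particular tumour. Absolute
times and cell counts are meaningful only through the compressions above.

## Numerical choices and degenerate inputs

- Backward Euler everywhere a stiff step is taken (cell ODEs,
  intravascular substeps); Newton tolerances 10⁻⁸–10⁻¹⁰.
- Flow solves: sparse Cholesky-like direct solve via SuperLU for the
  (small) vessel systems; CG for the (large) grid systems.
- Zero-flow segments: hematocrit from the upstream node, lowest-id
  tie-break; they still exchange oxygen (stagnant blood).
- Degenerate Delaunay inputs: deterministic jitter, logged retry.
- Collapsed segments keep their row in the segment table (flagged, zero
  flow) until the next pruning; radius is left untouched so the event log
  remains interpretable.
- Snapshot HDF5 files are written with timestamp tracking disabled so a
  given state always produces identical bytes.

## Known limitations

- Sprout tips move on the vessel lattice, one spacing per tick; sub-step
  anastomoses are resolved to the nearest node within 45 μm.
- The alpha-shape tumour mask is recomputed per vessel tick from all
  cells; for very anisotropic tumours a phase-field mask would be
  smoother.
- The pH model is algebraic in lactate; bicarbonate buffering and CO₂
  transport are out of scope.
- Hematocrit relaxation for cyclic flow patterns is damped fixed-point,
  not exact; residuals are checked and surfaced.
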