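# Methods

## Model

Two coupled fields on the unit square Ω = (0,1)²: the endothelial-cell
(EC) density u and the tumor-angiogenic-factor (TAF) concentration v,

    ∂u/∂t = ∇·( Du ∇u − χ(v) u ∇v ),   χ(v) = χ / (1 + α v),
    ∂v/∂t = Dv Δv − γ u v.

ECs undergo random motility (Du) and drift up the TAF gradient with a
receptor-saturating sensitivity χ(v); TAF diffuses (Dv) and is consumed
where ECs are present (γ u v). There is no interior TAF source: the
tumor releases TAF *through the boundary*. With n the outward normal,

    ∂u/∂n = 0                on all of ∂Ω,
    ∂v/∂n − μ v = 0          on the tumor edge,
    ∂v/∂n = 0                on the vessel and lateral edges.

The Robin coefficient μ measures the permeability of the tumor
interface: μ = 0 recovers a sealed (Neumann) boundary, larger μ means a
leakier tumor releasing more TAF. Haptotaxis, EC proliferation and
logistic kinetics are deliberately omitted; the model isolates the
interaction between chemotaxis and boundary-driven TAF supply.

### Geometry

The tumor occupies the top edge y = 1 and the parent vessel the bottom
edge y = 0; this is the orientation fixed by the initial data (the TAF
ramp is maximal at y = 1, the EC sprouts sit on y = 0). The assignment
is configurable (`geometry.tumor_edge`); rotating it rotates the initial
data congruently.

### Initial data

Evaluated pointwise at cell centers (no cell averaging — the difference
is O(h²)):

    u₀ = max(0, e^(−y²/0.001) · sin 6πx)    three sprout tips, strip width ≈ 0.03
    v₀ = e^(−(1−y)/0.45)                     exponential TAF ramp, v₀(·,1) = 1

v₀ satisfies the Robin relation at y = 1 only approximately for μ ≠
1/0.45; the mild incompatibility is part of the model statement and is
not corrected. Roundoff negatives are clipped at initialization only;
positivity during time stepping is the scheme's job, never a clip.

## Parameters

| name | meaning                              | default | notes |
|------|--------------------------------------|---------|-------|
| Du   | EC random motility                   | 0.0035  | length² per unit time, domain scaled to 1 |
| Dv   | TAF diffusivity                      | 0.01    | sets the gradient's smoothness |
| χ    | maximum chemotactic response         | 1       | halving it stalls the front before T = 2 |
| α    | receptor desensitization severity    | 0.6     | χ(v) = χ/(1+αv) |
| γ    | EC–TAF consumption coefficient       | 0.1     | weak coupling at these densities |
| μ    | Robin influx coefficient             | 0.5     | tumor interface permeability |
| n    | grid resolution                      | 100     | h = 0.01 resolves the sprout strip with ≥3 cells |
| T    | final time                           | 2       | the study window; steady state is not reached |

## Discretization

Cell-centered conservative finite volume on a uniform n×n grid,
unknowns at centers (i+½, j+½)h, boundary conditions through one ghost
layer.

**Diffusion** is the standard 5-point flux divergence
D Σ_faces (f_nb − f_c)/h². Neumann edges mirror the boundary cell
(f_g = f_b); the Robin edge uses the second-order face-centered ghost

    v_g = v_b (2 + hμ)/(2 − hμ),

which makes the centered face derivative (v_g − v_b)/h equal μ times the
face-interpolated value (v_g + v_b)/2 and keeps diffusion second-order
up to the boundary (requires hμ < 2, enforced with an error directing a
finer grid). Against the Neumann eigenmode cos(πy) the stencil is exact
up to the discrete-eigenvalue defect π²h²/12, and the integrated heat
problem converges at second order (verified in the suite).

**Chemotaxis** is donor-cell upwinding in flux form: on each face the
drift velocity is a = χ(v̄)·(v_R − v_L)/h with v̄ the arithmetic mean of
the adjacent cells, and the flux is a·u_donor with the donor the cell
the drift leaves; zero drift carries zero flux (no donor needed). This
first-order scheme is the standard positivity-preserving treatment of
Keller–Segel transport and makes conservation exactly testable: the
divergence telescopes to the net boundary flux at machine precision.

**EC boundary closure.** The no-flux condition on u is exact for the
diffusive flux, but at the tumor edge ∂v/∂n = μv leaves a chemotactic
drift pointing out of the domain, and the literal reading lets ECs exit
through the tumor interface. Both closures are implemented:

* `bc.u_leak = false` (library default): the chemotactic flux through
  every boundary face is closed to zero, so EC mass is conserved to
  machine precision — the natural choice when the solver is used as a
  conservative transport code, and the one whose conservation property
  the suite asserts.
* `bc.u_leak = true` (used by the replication experiment presets): the
  tumor-edge face keeps the Robin ghost drift, ECs that reach the tumor
  are absorbed into it. Only this closure reproduces the reported
  terminal EC readouts at the tumor interface — under the conservative
  closure ECs pile up against the tumor wall (tumor-row density ≈ 0.93
  at μ = 5 instead of ≈ 2×10⁻³) and the strong-influx suppression of
  angiogenesis disappears, which contradicts the phenomenon the
  parameter study documents. Biologically the literal closure is the
  sensible one: tip cells that reach the tumor anastomose into it rather
  than accumulating on its surface.

**Time integration** is forward Euler with the step recomputed every
step from a combined positivity bound. The update of a cell is a
nonnegative combination of old values whenever dt times the largest
per-cell outflow rate is below 1, giving

    dt = 0.9 / max( 4Du/h² + 4a_max/h ,  4Dv(1 + hμ)/h² + γ·max u ),

with a_max the largest chemotactic face speed on the current fields
(including the Robin face, regularized by 10⁻¹² so a gradient-free field
yields a finite bound). A single min of separate diffusive and advective
bounds would not guarantee positivity — the two outflow rates add — so
the combined form is used; with zero drift and μ = 0 it reduces to the
familiar 0.9·h²/(4Dv). Steps are clipped to land exactly on snapshot
times. Explicitly configured steps are validated against the same bound
and rejected above it; a field maximum beyond 10⁶ (fields start ≤ 1)
aborts the run as diverged.

At the benchmark scales this is cheap: the n = 100 baseline takes ~1100
steps (about a second), the μ = 5 run ~4000 steps, so the full μ-sweep
is interactive. The test suite runs the sweep at n = 50, where the
qualitative monotonicity is already resolved; convergence checks in the
suite use n = 25–100.

## Diagnostics and readouts

Per record: total masses Σf·h², global maxima, and maxima over the
tumor-adjacent cell row. Front arrival is declared when the tumor-row EC
maximum first reaches a threshold, default 0.01 — the reported arrival
density is ≈ 0.03 and the stalled (χ = 0.5) run stays below 10⁻³, so
0.01 separates the regimes robustly.

The terminal TAF maximum is reported as the reconstructed value on the
tumor boundary face, v_face = v_b·2/(2 − hμ) (the average of the
boundary cell and its Robin ghost): the continuum maximum sits on the
boundary itself, and the cell-center value half a cell inside
understates it by O(hμ) — 2.5% at μ = 5, h = 0.01. The reconstruction
agrees with an independent 1D method-of-lines solution of the TAF
equation to 0.1%.

The μ-sweep (μ = 0, 0.5, …, 5, all else at benchmark) tabulates terminal
maxima and arrival times. Terminal EC concentration is monotonically
nonincreasing in μ. Arrival time is *not* monotone at small μ: a sealed
tumor (μ = 0) lets the TAF ramp decay and the front arrives slightly
later than at μ = 0.5–1.5, where the influx sustains the near-edge
gradient before, at larger μ, flattening the field and stalling the
front entirely.

## What the tests do and do not show

The suite verifies the scheme's structural guarantees exactly
(conservation, per-step mass balance, positivity, agreement with
loop-assembled flux oracles on tiny grids), its accuracy against an
analytic heat-equation solution, and the study's qualitative and
quantitative outcomes at n = 100. The model itself remains a 2D
continuum caricature of angiogenesis: no haptotaxis, no EC
proliferation or branching morphology, a flat tumor interface, and
parameters scaled to a unit tissue square — agreement with the
replication targets says the solver integrates this model correctly,
not that the model captures vascular biology in detail.

## Known limitations

* First-order upwinding smears the sprout tips; tip amplitudes at the
  far wall are therefore scheme-sensitive (the replication tolerance on
  the terminal EC density is a factor of two for this reason).
* Explicit stepping makes cost scale as n⁴ per unit time; n ≳ 400 calls
  for an IMEX treatment that is out of scope.
* The printed study values carry the original experiments' unknown
  discretization error; the μ = 5 TAF maximum in particular converges
  to ≈ 2.15 under grid refinement here (and in the independent 1D
  cross-check), below the printed 2.5.
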