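# Methods

## Model and scope

The package treats the bursting limit of stochastic gene expression: mRNA
is short-lived relative to protein, so translation arrives in bursts of
exponentially distributed size b, at dimensionless frequency a = k_m/γ_x,
and the protein density p(t, x) obeys a linear PIDE combining drift
towards the origin (degradation, velocity γ x) with a lower-triangular
jump (burst) operator weighted by a Hill input function c(x) ∈ [ε, 1].
Time is measured in protein lifetimes (t = γ_x τ), protein in molecule
numbers. The n-gene generalisation applies one such drift/jump pair per
coordinate with input functions c_i(**x**); only the printed regulatory
motifs (independent self-regulation, mutual repression, one self/cross
motif with four promoter states) have closed-form c_i and only those are
implemented — there is no universal expression for an arbitrary promoter
graph.

Assumptions inherited from the model: constant (unit, unless configured)
degradation rates in the solver's splitting path; bursts are instantaneous
and additive; the feedback acts through transcription only.

## Stationary analysis (1D)

The stationary density P∞ ∝ (x^H + K^H)^{a(ε−1)/H} x^{a−1} e^{−x/b} is
evaluated in log space throughout; the Hill term goes through
`logaddexp(H log x, H log K)`, which is exact in the limits x → 0, ∞ and
immune to overflow for any integer H. The local exponent at the origin is
r = a−1 (negative feedback/open loop) or r = aε−1 (positive feedback); the
law diverges at 0 iff r < 0 (always integrably, since r > −1).

Normalisation integrates on (0, x_max] after the substitution
x = u^{1/(1+r)} when r < 0, which removes the singularity exactly;
composite Gauss–Legendre (256 geometrically graded panels × order 16,
doubled for verification; the two must agree to 1e−10 relative or the
call fails). x_max comes from the gamma-tail envelope
x^{max(a, aε)−1}e^{−x/b} at tail mass 1e−15, padded 5%. Against a 40-digit
arbitrary-precision quadrature of the same integrand the normalising
constant agrees to ~15 significant digits.

Shape classification uses the analytic log-derivative: interior critical
points are roots of φ(x) = a − 1 + a(ε−1)ρ(x) − x/b, bracketed on a
20 000-point log grid and refined by Brent's method; a boundary peak at 0
is counted iff r < 0. Cases: 1 (boundary peak only), 2 (boundary +
interior), 4 (two interior peaks), and the single-interior-peak class,
which the taxonomy splits into 3 ("peak near the origin") and 5 without
defining a boundary; the classifier reports 3 when the peak lies at or
below the binding constant K and 5 above it, and treats {3, 5} as one
equivalence class. Grid values of φ within 1e−10 (relative to the scale of
a) of zero that do not belong to a strict sign change raise an
"ambiguous" error instead of being resolved silently.

## Discretisation

Cell-centred finite volume on a uniform grid over (0, x_max] per
dimension; cell values are cell averages, the quadrature weight is the
cell volume. In 1D x_max comes from the stationary tail envelope; in nD,
where no closed form exists, x_max_i = κ a_i b_i with κ = 4 — exactly
four cells per burst size on a 128² grid for the toggle-switch example —
validated post hoc by the outermost-cell mass (reported by the solver;
~1e−16 at t = 1 there). Grids resolving a burst with fewer than 4 cells
are rejected.

**Burst operator.** The gain from source cell j into target cell i is the
kernel's exact double cell integral, which for the exponential kernel has
the closed form (b/dx)(2 sinh(dx/2b))² e^{−(x_i−x_j)/b} off the diagonal
and 1 − (b/dx)(1 − e^{−dx/b}) on it. Each column is renormalised by its
raw sum — a correction that only compensates the truncated tail — so
every column sums to exactly one and gain − loss is exactly mass-neutral:
probability conservation holds to machine precision per step by
construction, not as an approximation. Application costs O(N) through the
kernel's one-step recurrence (an IIR filter); the dense triangular matrix
is retained as a cross-check and the two agree to 1e−12.

**Transport.** Two discretisations:

- a conservative first-order upwind divergence of γ x p with zero flux at
  both boundaries (the inner flux vanishes with the velocity), used by the
  method-of-lines RK4 integrator;
- the exact dilation semigroup p ↦ p(x e^{γΔt}) e^{γΔt}, realised as a
  conservative remap: the new cell average is the integral of a
  reconstruction of the old density over the pulled-back cell. The
  reconstruction is slope-limited (minmod) piecewise linear in 1D, with a
  two-term singular basis {x^r, x^{r+1}} in the near-origin cells when the
  stationary exponent r ∈ (−1, 1)\{0} is available — fitted to the cell's
  own average (mass consistency) and its right neighbour's (captures the
  smooth factor's slope), falling back to the limited line wherever the
  fit dips negative. This removes the first-order error a limited line
  commits against the x^r layer. In several dimensions the remap drops
  the data-dependent pieces and is piecewise constant, making each axis
  remap a fixed linear operator; the per-axis dilations then commute
  exactly and symmetric two-gene problems remain transpose-symmetric to
  round-off. Either way the remap is exactly mass-preserving and
  positivity-preserving.

**Time stepping.** Default is Strang splitting: half dilation, a Heun
(two-stage) update of the jump operator, half dilation. The Heun update is
a convex combination of nonnegativity-preserving Euler steps whenever
Δt k_m max c ≤ 1; the default Δt is half that bound. RK4 on the full
right-hand side is the independent cross-check integrator, with
Δt ≤ min(CFL·dx/(γ x_max), 1/(2 a max c)), CFL = 0.5; the two agree
increasingly under grid refinement (observed order ~1, limited by the
upwind transport). RK4 undershoots below −1e−12 abort; smaller ones are
clipped to zero with the clipped mass logged in the report.

The splitting operator's stationarity defect on the discretised analytic
law vanishes at observed order ≥ 1 under refinement even in the singular
case; for smooth stationary laws the RK4 right-hand-side residual shows
clean first order in L². For the singular laws the L² residual of the
upwind right-hand side is dominated by the x^r boundary layer and
converges slower (~order 0.4) — an intrinsic feature of measuring a
singular layer in L², not a scheme defect; the L¹ residual keeps order 1.

**Maximum-principle monitoring** compares u = p/P_ref only on cells where
P_ref exceeds 1e−10 of its maximum: cells deeper in the tail carry
relative round-off, not dynamics, and their ratios are meaningless.

## Entropy diagnostics

G₂ is the quadrature of (u−1)² P∞ with u = p/P∞; it is cross-checked
against the algebraically identical expanded form ∫p²/P∞ − 2m_p + m_P
(the familiar ∫p²/P∞ − 1 for mass-one inputs) at 1e−10 relative. Cells
where the reference underflows (< 1e−280) are excluded and their p-mass
reported; more than 1e−6 of excluded mass is a support-mismatch error.

D₂ is evaluated through the solver's own column-renormalised kernel
matrix — not a separate quadrature of ω — so that the discrete H-theorem
balances: per axis the inner integral collapses to
Wᵀu² − 2u Wᵀu + u² (two O(N) kernel applications), summed against
k_m c P∞. Along a resolved trajectory the centred finite difference of G₂
matches −D₂ within 2% at N = 512 and the residual halves per refinement.
This diagnostic requires the state to be resolved: differentiating an
initial profile narrower than one cell (the printed N(2, 0.1) start on
coarse grids) produces O(1) residuals for any scheme, so the balance
experiment starts from a wide Gaussian.

**Decay fits.** Against the analytic reference the computed G₂ cannot
fall below the discretisation floor — the entropy of the scheme's own
fixed point relative to the analytic law — so a trace decays, bottoms
out, and may creep back up while settling. `fit_decay_rate` therefore
discards everything after the trace's global minimum, and by default fits
log G₂ on [t_min/4, 0.8 t_min] (the last stretch before the minimum
already curves under the floor); an increase *before* the minimum is a
genuine H-theorem violation and rejects the trace. The fitted slope is
the entropy rate; the implied norm rate is half of it. Preset runs use a
fixed relative window (25–62.5% of the horizon) so rates are comparable
across resolutions; the fitted rate is resolution-converged to a few
percent only from ~2048 cells, coarser grids bias it upward.

**nD references.** For independent genes the product of 1D analytic laws
is the exact joint stationary law and G₂ of a product state factorises as
1 + G₂ = ∏(1 + G₂^{(i)}); this identity is used as a test oracle. For
coupled networks the reference is operational: long-time integration to
relative L¹ change below 1e−10 per unit time. Whether nD convergence is
truly exponential is left as an empirical observation — fits are reported,
exponentiality is not asserted.

## Study conditions and what the tests show

The synthetic experiments are the printed ones: five 1D positive-feedback
parameter sets (H = −4, ε = 0.15, K = 45; (a, b) = (5,10), (5,30),
(10,5), (8,16), (15,20)) started from N(2, 0.1), and three two-gene
networks started from N([10,10], [1,1]) — two independent copies of the
first gene, a self/cross activator–repressor pair, and a mutual-repression
toggle switch (H₁₂ = H₂₁ = 4, K = 45, ε = 0.15, k_m = 8, b = 16,
γ_x = 1). Problem sizes used by the test-suite: N = 2048 cells for the
1D long-time convergence runs (horizon T = 60, which is past the slow
basin-exchange transient of the bimodal sets, Δt = 0.005), N = 1024 for
decay fits (horizon 10), N = 512/1024 for the H-theorem balance, and 128²
for the toggle switch.

These are mathematical-consistency experiments: they validate the solver
and the entropy machinery against the model's own closed forms and
structural laws (conservation, contraction, maximum principle,
factorisation). Passing them says nothing about how well the PIDE itself
describes any real circuit — no biological data enters anywhere — and the
nD results are self-consistent (solver against its own fixed point)
rather than checked against an external discretisation.

## Known limitations

- Uniform grids only; the O(N) kernel recurrence and the exact-dilation
  remap both rely on uniform spacing. Strongly multiscale problems pay
  for this in cell count.
- The singular-basis reconstruction is not monotone: it can overshoot by
  a small amount near the origin, so strict discrete maximum principles
  hold for the minmod/nD paths but only up to that overshoot in 1D
  singular cases (monitored with relative slack 1e−9 against the solver's
  own fixed point, where it passes).
- Splitting supports constant per-gene degradation rates; variable
  γ_x^i(x) is available only through the RK4/upwind path.
- n ≥ 3 genes are supported by the tensor-grid code but memory-bound
  (N^n storage); tests exercise n ≤ 2.
- The fitted decay rates are empirical slopes, not spectral gaps; no
  attempt is made to compute the theoretical rate from functional
  inequalities, whose constants are known to be far from optimal.
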