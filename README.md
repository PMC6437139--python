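# burstpide

Simulation and analysis of the burst-production partial integro-differential
equation (PIDE) that describes protein levels in self- and cross-regulated
gene circuits, together with relative-entropy diagnostics of how fast those
circuits equilibrate.

## The model

When messenger RNA degrades much faster than protein (γ<sub>m</sub>/γ<sub>x</sub> ≫ 1),
protein is produced in random bursts of exponentially distributed size
(mean *b*), at a dimensionless frequency *a* = k<sub>m</sub>/γ<sub>x</sub>,
modulated by Hill-type feedback. The probability density p(t, x) of the
protein level x evolves by

    ∂p/∂t − ∂(x p)/∂x = a ∫₀ˣ ω(x−y) c(y) p(t,y) dy − a c(x) p(t,x),

with burst kernel ω(s) = e^(−s/b)/b and input function
c(x) = (K^H + ε x^H)/(K^H + x^H) ∈ [ε, 1], where H is the Hill
coefficient (H < 0: positive feedback), K the binding constant and ε the
transcriptional leakage. The 1D stationary law is explicit,

    P∞(x) = Z (x^H + K^H)^(a(ε−1)/H) x^(a−1) e^(−x/b),

reducing to the gamma density x^(a−1)e^(−x/b)/(b^a Γ(a)) in the open loop
(c ≡ 1). Depending on (a, b) a positive-feedback gene realises five
qualitative shapes, from a single boundary peak at x = 0 to bimodal laws
with two interior peaks. A multi-gene generalisation couples n genes
through input functions c_i(**x**) (e.g. a mutual-repression toggle
switch); its stationary law has no known closed form.

Convergence to P∞ is tracked with the L² relative entropy
G₂(p) = ∫ (p − P∞)²/P∞ dx, whose dissipation along solutions,

    dG₂/dt = −D₂ = −a ∬_{x>y} ω(x−y) (u(x) − u(y))² c(y) P∞(y) dx dy,

(u = p/P∞) is the H-theorem underlying exponential equilibration. The
package computes G₂, D₂ and their n-dimensional analogues along simulated
trajectories and fits the decay rate from the semilog trace.

## What is in the box

- `burstpide.kernels` — Hill input functions (1D, and the printed two-gene
  variants: independent genes, mutual repression, general self/cross
  regulation) and the exponential burst kernel, all evaluated in log space.
- `burstpide.stationary` — the closed-form 1D stationary density:
  log-space evaluation, singularity-aware normalisation, asymptotic
  exponents, five-way shape classification, phase diagrams over (a, b).
- `burstpide.solver` — conservative finite-volume discretisation on
  truncated tensor grids with two independent integrators: method-of-lines
  RK4 with upwind transport, and Strang splitting around the *exact*
  dilation semigroup of the transport part. Mass is conserved to machine
  precision by construction; positivity and maximum-principle bounds are
  monitored en route.
- `burstpide.entropy` — general relative entropies, the G₂/D₂ pair
  (computed through the solver's own kernel matrix, so the discrete
  H-theorem balances), decay-rate fits, and operational stationary states
  for multi-gene networks by long-time integration.
- `burstpide.presets` / `burstpide.config` / CLI — the printed experiment
  presets (`fig4` … `fig11`), TOML experiment configs, CSV/JSON/HDF5
  artefacts, and a `burstpide` command with verbs `stationary`,
  `classify`, `phase-diagram`, `simulate`, `entropy`, `preset run`.

## Worked example

A bistable positive-feedback gene (H = −4, ε = 0.15, K = 45, a = 8,
b = 16): classify its stationary law, then measure how fast a narrow
initial condition N(2, 0.1) equilibrates.

```python
import burstpide as bp

fb = bp.HillFeedback1D(H=-4, K=45.0, epsilon=0.15)
model = bp.Model1D(a=8.0, b=16.0, feedback=fb)
dens = bp.classify_shape(model)
print(f"shape case: {dens.shape_case}")
print(f"modes at:   {[round(m, 2) for m in dens.mode_locations]}")

axis = bp.Axis(x_max=dens.x_max, n=1024)
pinf = dens.cell_averages(axis.faces)
p0 = bp.gaussian_initial_condition([2.0], [0.1], (axis,))
trace = bp.entropy_experiment(model, p0, 10.0, pinf, n_save=100, dt=0.005)
print(f"G2(0) = {trace.G2[0]:.3g}, G2(10) = {trace.G2[-1]:.3g}")
print(f"entropy rate = {trace.entropy_rate:.3f}, norm rate = {trace.fitted_rate:.3f}")
print(f"semilog fit R^2 = {trace.fit_r_squared:.4f}")
```

prints

```
shape case: 4
modes at:   [3.2, 108.92]
G2(0) = 174, G2(10) = 0.147
entropy rate = 0.411, norm rate = 0.205
semilog fit R^2 = 0.9980
```

Case 4 is the bimodal regime: two interior peaks, at x ≈ 3.2 (repressed
basin) and x ≈ 108.9 (expressed basin). The entropy trace is a straight
line on a semilog plot (R² ≈ 0.998), i.e. equilibration is exponential;
its slope says G₂ decays as e^(−0.41 t), so the weighted-norm distance to
the stationary law halves roughly every 3.4 protein lifetimes — slow,
because probability must cross the valley between the two basins.

The same experiment from the command line:

```
burstpide preset run fig7 --out fig7_run
```

writes the classification record, stationary table, final density, entropy
trace and fit into `fig7_run/`.

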