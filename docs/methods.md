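# Methods

## The model

A well-mixed system starts at `t = 0` with `N` free monomers in a volume
`V` and evolves by binary events only:

* aggregation `C_i + C_j -> C_{i+j}` (allowed when `i + j <= N`), with
  probability per unit time `K(i, j)/V` for each distinct reactant pair;
* fragmentation `C_{i+j} -> C_i + C_j`, with probability per unit time
  `F(i, j)` for each (i+j)-mer.

The state is the count vector `n = (n_1, ..., n_N)`; total mass
`sum_i i n_i = N` is conserved exactly. Both kernels are symmetric in
`(i, j)`, and a channel is an *unordered* pair `(i, j)` with `i <= j`: the
number of reactant pairs is `n_i n_j` off the diagonal and
`n_i (n_i - 1)/2` on it, compactly `n_i (n_j - d_ij)/(1 + d_ij)`.

Four layers of description share this single channel enumeration
(`kernels.iter_channels`), so conventions cannot drift between them:

1. **Master equation** (`master_oracle`): exact linear evolution of the
   probability over all integer-partition states. Solved by building the
   sparse column-stochastic generator and stiff (BDF) propagation with the
   generator as exact Jacobian. Feasible to `N = 30` (5604 states); the
   module refuses larger `N` and reports the partition count.
2. **Stochastic simulation** (`gillespie`): the direct method — waiting
   time `tau = ln(1/u1)/a_tot`, channel chosen as the smallest cumulative
   index reaching `u2 a_tot`. States with zero total propensity are
   absorbing and freeze the trajectory. Ensembles are averaged onto a
   fixed grid by piecewise-constant sampling; one master seed spawns
   independent per-trajectory `SeedSequence` streams.
3. **Modified (finite-N) rate equations** (`smoluchowski_ode`): the mean
   hierarchy of the master equation closed with
   `<n_i (n_j - d_ij)> ~= <n_i><n_j>`. In concentrations
   `c_bar_i = <n_i>/V` the equations are the classical Smoluchowski form
   truncated so that no channel creates sizes above `N`, with rate
   coefficients `k_ij = K_ij` and fragmentation coefficients
   `f'_ij = (1 + d_ij) F_ij` (the stoichiometric factor covers splits
   into equal fragments). Mass conservation is identical-by-construction
   in the right-hand side and asserted per run to `1e-8 c`.
4. **Closed forms** (`analytic`): exact infinite-system solutions for the
   constant, additive and size-independent reversible kernels under a
   monodisperse start (see below).

The thermodynamic limit (`N, V -> infinity` at fixed `c = N/V`) is
represented numerically by the same right-hand side truncated at a large
`N_max`, auto-doubled until the monomer/dimer/trimer curves change by
less than `1e-8` relative.

## Kernel families and conventions

Kernel algebra admits several normalization conventions; the package
fixes the following ones (the standard literature forms, chosen so that
the stochastic, mean-field and closed-form layers are mutually
consistent) and uses them everywhere:

| family | K(i, j) | F(i, j) | params |
|---|---|---|---|
| constant | `k_f` | 0 | `k_f` |
| additive | `k_f (i + j)/2` | 0 | `k_f` |
| diffusion | `(k_f/4)(i^{1/3} + j^{1/3})(i^{-1/3} + j^{-1/3})` | 0 | `k_f` |
| blatz_tobolsky | `k_f` | `k_b/(1 + d_ij)` | `k_f, k_b` |
| three_param | BT x `q` on monomer channels | BT x `q` on monomer channels | `k_f, k_b, q` |

Normalizations: the additive and diffusion kernels are scaled so
`K(1, 1) = k_f` (the diffusion diagonal is size-independent,
`K(i, i) = k_f`). The reversible model is defined by *flat rate
coefficients* `k_ij = k_f`, `f_ij = k_b`, i.e. `F(i, i) = k_b/2` on the
diagonal; the total breakup rate of an i-mer is then `(i - 1) k_b/2`,
proportional to the bond count of a linear chain. This is the counting
under which the cluster-size distribution stays geometric and the model
is solvable in closed form; a flat `F` on unordered channels (breakup
rate `k_b floor(i/2)`) admits no such solution. In the three-parameter
family `q` multiplies every channel whose smaller index is 1 — monomer
pick-up and monomer shedding — on both kernels; `q = 1` reduces exactly
to the reversible base and `k_b = 0` to the constant kernel.

Units: `K` in nm^3/ps and `F` in 1/ps match typical coarse-grained MD
reports. All tests and examples run in the dimensionless mode `k_f = c =
1` with scaled time `T = k_f c t`, where the kernel families differ only
in shape.

## Closed forms

With `c_i(0) = c d_{1i}`:

* constant kernel: `c_i = c B^{i-1}(1 - B)^2`, `B = (T/2)/(1 + T/2)`;
  number-average size `L = 1 + T/2` — unbounded, which is the unphysical
  excursion the finite-`N` equations remove (`L <= N` always).
* additive kernel: `c_i = c (1 - tau)(i tau)^{i-1} e^{-i tau}/i!` with
  `tau = 1 - e^{-T/2}` (Borel/tree-function distribution).
* reversible flat model: `c_i = c (1 - p)^2 p^{i-1}` with
  `dp/dt = [k_f c (1 - p)^2 - k_b p]/2`, `p(0) = 0`, integrated in closed
  form through the two roots of the stationary condition (their product
  is 1, which makes the expression numerically stable). At equilibrium
  every channel satisfies detailed balance
  `k_f c_i c_j/(1 + d) = F(i, j) c_{i+j}`.

Evaluation is in log space (`xlogy`, `gammaln`) so large sizes underflow
gracefully; series sums (mass, cluster totals) are truncated adaptively
where `i c_i < 1e-15 c`.

## Numerical choices

* Modified equations: LSODA, `rtol = 1e-8`, `atol = 1e-12 c`.
  Concentrations below `-1e3 atol` abort the run instead of being
  clipped. Truncated classical reference: DOP853 at `rtol = 1e-10`.
* Master equation: BDF at `rtol = 1e-10`, `atol = 1e-14`; probabilities
  are clipped at zero and normalization is monitored (`<= 1e-10` drift).
* The SSA recomputes the full propensity vector after every event as a
  handful of vector operations over the precomputed channel table. At the
  sizes this package targets (`N <= ~100`, at most a few thousand
  channels) this is faster in practice than fine-grained incremental
  updates and keeps one code path.
* Fitting: parameters are log-transformed (positivity built in) and
  bounded (`k_f in [1e-4, 1e4]`, `k_b in [1e-8, 1e4]`,
  `q in [1e-2, 1e3]`); five deterministic starts log-uniform across the
  box, each refined by Nelder-Mead and polished with trust-region least
  squares; the best final chi-square wins. Parameter uncertainties come
  from the Gauss-Newton covariance at the optimum scaled by the reduced
  chi-square.

## Weighting of the fit

The objective is the reduced chi-square over the four observables
(monomer, dimer, trimer and total-cluster counts), each point weighted by
its SEM. Two details the data model forces:

* the `t = 0` point is identical in every repeat (SEM 0, residual 0 by
  construction) and is excluded;
* an *interior* point with SEM 0 means the observable was identically
  zero (or constant) in every repeat — a resolution limit, not infinite
  precision. Such points are floored at the observable's smallest
  positive SEM; weighting them by a purely numerical epsilon floor makes
  them dominate the fit and demonstrably drags rate constants to zero.
  A `1e-6 x max` backstop remains for fully noiseless (synthetic ODE)
  series.

A `scale="per_observable"` switch divides each observable's squared
residuals by its point count, equalizing observables when their grids
differ; with a common grid it changes nothing.

## The synthetic-data generator

`synthetic_data` emulates the *structure* of averaged coarse-grained MD
campaigns: `N = 72` monomers, a handful of repeats (default 3), 101-point
grids on `T in [0, 5]`, observation noise arising solely from
finite-repeat averaging of exact stochastic trajectories — no additive
Gaussian noise, so the error bars have exactly the SEM-of-repeats
structure real averaged simulations have. The fitting experiments use a
three-parameter truth `k_f = 1, k_b = 0.5, q = 4` (moderate reversibility
and a strong monomer-channel boost, the regime where a size-dependent
kernel is actually needed) and 1000-repeat ensembles where tight error
bars are required. The optional `kf_of_c` hook makes `k_f` depend on
concentration, deliberately violating the model's core assumption to
reproduce the cross-concentration failure mode: single-concentration fits
stay good while the joint fit degrades.

What the generator does **not** emulate: spatial correlations, cluster
morphology and internal restructuring, diffusion-limited encounter
dynamics, and any concentration dependence beyond the explicit hook.
Passing tests therefore certify the inference machinery on data whose
generating process *is* the fitted model class; they say nothing about
whether a particular force field's kinetics belong to that class.

## Known limitations

* The mean-field closure leaves an `O(1/N)` systematic offset between the
  modified equations and the exact ensemble means (about 2% of `c` on the
  monomer curve at `N = 20`, shrinking with `N`). Consequences worth
  knowing before fitting very tightly averaged data: with error bars at
  the 1000-repeat scale the offset is statistically resolvable, and a fit
  will absorb it into parameter shifts along sloppy directions — in the
  recovery experiment the stiff combination `k_f q` is recovered to a
  fraction of a percent while `k_f` alone shifts by ~15-20%; on purely
  irreversible 1000-repeat averages the offset even masquerades as a
  statistically significant pseudo-fragmentation rate
  (`k_b ~ 0.005 k_f c`) in a reversible fit. At the 3-6 repeats of
  realistic campaigns the offset is far below the noise and the
  reversible fit collapses cleanly onto the irreversible one.
* Exact master solutions stop at `N = 30` (partition-count growth); SSA
  covers larger systems.
* No gelation-regime (multiplicative) kernels, no ternary events, no
  spatial resolution, no Bayesian/bootstrap uncertainty quantification.
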