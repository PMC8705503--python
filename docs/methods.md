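# Models and methods

## State space and geometry

Sequences of length `n` over `{A, U, G, C}` are encoded as base-4
integers (A=0, U=1, G=2, C=3, two bits per position; position 0 in the
least-significant digit).  Element-wise Watson–Crick complementation
(A↔U, G↔C, *not* reverse-complement) is `code XOR 0b01…01`; it is an
involution with no fixed point, so `h(x, xc) = n` for all `x`.  Hamming
distance is computed by collapsing the 2-bit XOR groups to indicator
bits and popcounting.  The population state is a pair of dense integer
vectors over all `4^n` codes: `Ns[x]` single strands of sequence `x`
and `Nd[c]` duplexes under the canonical key `c = min(x, xc)`.  Dense
storage caps at `n ≤ 8` by default (the experiments use `n ∈ {3, 4}`,
i.e. 64–256 species).

The high-fidelity set `R` is a non-empty subset of sequence space,
either explicit or a per-position product `A_1 × … × A_n`; the
experiments use random singletons.  Distances to `R` are
`H(x, R) = min_y h(x, y)`; the manifold partition classes a strand by
`min(H(x, R), H(xc, R))` so a sequence and its complement share a
class.  The pair distance `S(x, y)` is the minimum of the four Hamming
distances among `{x, xc} × {y, yc}`; it is symmetric, invariant to
complementing either argument, and zero for complementary pairs.

## Landscapes

Three surfaces over distance `d`:

* fitness `f(x) = exp(-k · H(x, R))`,
* similarity `s(x, y) = exp(-l · S(x, y))`,
* per-site copying fidelity `p(x) = exp(-m · H(x, R))`.

Curvatures are parameterized by the surface value `i` at maximal
distance: `k = -log(i)/n` ("terminus" parameterization).  Defaults:
`l = k` and fidelity terminus 0.25, so the most distant sequences copy
each site at chance level while members of `R` copy perfectly.  The
"linear" variant replaces the exponential with the affine surface
`1 + (i - 1)/n · d`; a constant similarity `s ≡ b` is also available.

## Reaction network and propensities

| channel | propensity | effect |
|---------|-----------|--------|
| duplex formation | `½ kds Σ_x N(x) N(xc)` | two complementary singles → one duplex |
| duplex dissociation | `kss · #duplexes` | one duplex → two singles |
| RNA polymerization | `a Σ_{x,y} f(x) s(x,y) N(x)(N(y) − 1{x=y})` | adds one offspring strand |
| decay | `k∅ · #singles` | removes one single (duplexes are protected) |
| clay oligomerization | `kclay-o` (zero order) | adds one uniformly random strand |
| clay polymerization | `kclay-p · #singles` | copies one single at fixed fidelity `pclay` |
| vesiculation | `kmic · #singles` | creates a membrane (spatial engine only) |

The ordered-pair factor `N(x)(N(y) − 1{x=y})` excludes self-pairing: a
lone molecule cannot copy itself.  Polymerization is catalytic — the
polymerase and template are not consumed.

**Mutation kernel.**  A polymerase with fidelity `p` copying template
`y` emits each position of `y`'s complement correctly with probability
`p`, else one of the three other bases uniformly.  The offspring's
distance to `yc` is `Binomial(n, 1 − p)` and the law is uniform within
each level set, giving per-sequence mass `p^(n−i) ((1−p)/3)^i` at
distance `i`.  The instantaneous polymerization-output law is the
domain measure over weighted (polymerase, template) pairs pushed
through this kernel (`rnahit.kernel`); it is undefined (raises) when
the total replication rate is zero.

**Simulation** uses Gillespie's direct method: waiting times are
exponential in the grand total propensity; channels, reactants, and
offspring are drawn proportionally.  Channel totals are recomputed each
step by dense linear algebra (one `4^n × 4^n` matrix–vector product);
an unvectorized full-space loop (`channel_rates_naive`) serves as a
test oracle.  All randomness flows through one `numpy` Generator, so a
run is a deterministic function of (config, seed).

## Hitting times and censoring

Detectors observe `(t, K, V)` after every event, where `K` is the
molecule count and `V` the high-fidelity volume fraction (singles in
`R` plus duplexes containing a member of `R`, over `K`).  `tau_rep` is
the first `K > I`; `tau_R` the first `V > 0`; `tau_v` the first
`V ≥ v`; `tau_min` the time of the running minimum of `V` after
`tau_R` (last attainment by default).  A run that exhausts its reaction
budget (5000 in the experiments) contributes a right-censored record
carrying the trajectory end time.  Online monitors (used to stop runs
early) and pure replay functions over the logged series are both
provided and tested against each other.

## Experiment protocols

**Core sweep** — `n ∈ {3, 4}` crossed with curvature termini
`i ∈ {0.1, 0.05, 0.01, 0.005, 0.001}` (`k = l = −log(i)/n`, fidelity
terminus 0.25), `kds = kss = 1`, 10 replicates per cell, `v = 0.1`.
Per `n`-cell, a random singleton `R` and `I = 10` initial strands
disjoint from `R` are drawn once and reused across curvature levels;
the replication scale `a` is calibrated so the initial total
replication propensity is exactly 10.  Per-run generators are keyed by
`(base_seed, n, curvature index, replicate)`, making results
independent of execution order.

**Expanded sweep** — the same grid crossed with 24 iid `U(0,1)^3` draws
of `(k∅, fclay, pclay)` per cell, 10 replicates each (2400 runs).  The
initial propensity budget of 20 is split `(1 − fclay)·20` to RNA
polymerization (via calibration of `a`) and `fclay·20` to clay
polymerization (`kclay-p = fclay·20/I`), with `kclay-o = 1`.

**Compartments** — molecules carry positions on `[−T, T]`; vesicles
are intervals that may nest but never cross (crossing proposals are
rejected).  Only replication is restricted — pairs must share an
innermost region — so restricted replicative mass is provably ≤ the
well-mixed value.

## Statistical analyses

**Survival model.**  Weibull proportional hazards
`h(t, θ) = (α/t)(t/β)^α e^{γ·θ}`, fitted by maximizing the censored
log likelihood over `(log α, log β, γ)` (BFGS with a derivative-free
polish; censored runs enter through their censor times).  Standard
errors come from the numerical observed information with a delta-method
transform back to `(α, β)`; p-values are Wald tests (α, β against 1, γ
against 0).  Closed-form moments
`E τ = β e^{−γθ/α} Γ(1 + 1/α)` are verified against numerical
quadrature, and the whole fit is cross-checked against lifelines'
Weibull AFT fit via `γ_PH = −α · γ_AFT`.

**Sensitivity analysis.**  The sweep outcomes are decomposed by HDMR:
`y = f0 + Σ fi(θi) + Σ fij(θi, θj)` with mean-zero, mutually orthogonal
components and variance shares `S_u = σ_u²/Var(y)`.  Gridded inputs get
centered indicator contrasts, continuous inputs shifted-Legendre
polynomials (degree ≤ 3); each input block is empirically centered and
QR-orthonormalized and all blocks are fitted jointly by least squares.
Two front-ends mirror the analyses: the 0/1 finite-hit indicator
(hitting probability) and the hitting time on the finite-hit
subsample.  The curvature input is the crossed design factor `i` (the
terminus), not `k = −log(i)/n`: `k`'s levels are nested within `n`,
which would break the product-design orthogonality the decomposition
relies on.

**Mean-field reduction.**  Mass-action ODEs for `[x]` and `[{x, xc}]`
assembled from the same propensities, *retaining* the self-pair
exclusion `[x]([y] − 1{x=y})` at count scale — this is what makes the
single-molecule state an equilibrium.  The offspring tensor
`Q[x, y, z]` is dense (`n ≤ 3`).  Fixed points are located by Newton
iteration with an analytic Jacobian (itself verified against finite
differences); stability is read off the Jacobian spectrum.  For a
singleton `R = {x*}`, the state `[x*] = 1` has vector-field residual at
machine precision, no zero eigenvalue, and positive eigenvalues: the
lone replicator is an unstable equilibrium, and the instability is
dynamical (finite-time blow-up of the quadratic autocatalysis under
integration).

## Numerical choices and limitations

* Dense `4^n` state vectors make each SSA step `O(4^n)`–`O(4^{2n})`;
  ample for the study regime (`n ≤ 4`, 5000-reaction budgets) but not
  for long sequences — the enumeration cap makes this failure mode
  loud.
* The spatial engine uses molecule lists (`O(K)` per step) and is meant
  for modest populations; vesicle contents are not resampled on
  membrane creation, and duplex chemistry, decay, and clay channels
  remain well-mixed.
* Calibration of `a` is exact at `t = 0` only; the replication rate
  drifts with the population afterwards.
* Finite-hit counts and sensitivity indices at the 100-run scale carry
  visible sampling noise; in particular the hitting-time regression
  rests on only the successful runs (~60 observations) and its indices
  move noticeably across sweep seeds.  The explained-variance share of
  the hitting-probability expansion is bounded above by `1 −` the
  Bernoulli replicate noise within cells.
* The Weibull-PH model treats runs as independent and the hazard as
  log-linear in the covariates; it is a summary device, not a claim of
  mechanism.
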