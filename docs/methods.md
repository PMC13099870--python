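# Methods

## Models and landscape construction

**Ising model.** A configuration `x` of `n` binary nodes has probability
`P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_{ij} xᵢ xⱼ )`, with each unordered pair
counted once. The threshold τᵢ is the node's autonomous activation tendency
(negative → tends off); the symmetric, zero-diagonal ω holds pairwise
weights. The alphabet matters: with {0,1} nodes a positive weight rewards
joint presence only, with {-1,1} nodes it rewards alignment in either
direction — which is why the two encodings are treated as distinct model
families. For n ≤ 20 the distribution is computed by exact enumeration
(binary counting order, node 0 least significant) with a max-shifted
log-sum-exp for the partition function, since thresholds near −7 combined
with doubled weights overflow naive exponentials. The landscape axis is the
active-symptom count K (number of nodes in state +1) for both encodings;
the bijection s = 2K − n onto the {-1,1} sum score is exposed
(`active_count_to_sum_score`) for relabeling. A reparameterisation between
encodings (ω′ = ω/4, τ′ᵢ = τᵢ/2 + Σⱼ ω_{ij}/4, and its inverse) preserves
the distribution exactly and is used as an invariant test.

**GVAR model.** `y_t = μ + B (y_{t-1} − μ) + ε_t` with `ε_t ~ N(0, Σ)` is
stationary when the spectral radius of B is below one; the stationary
covariance solves the discrete Lyapunov equation `S = B S Bᵀ + Σ` (solved
with `scipy.linalg.solve_discrete_lyapunov`, residual required < 1e-8). The
landscape axis is the sum score, whose stationary law is Gaussian
(mean Σμᵢ, variance 1ᵀS1) — the analytic density is the canonical route
because it is exact and fast; a simulation + Gaussian-KDE route (Silverman
bandwidth, default 2×10⁴ steps after 10³ burn-in) is kept as an independent
cross-check and is required to agree in the central ±3 s.d. (KDE boundary
bias makes the outer grid unreliable).

**Potential.** `U = −ln P` in natural log, with no additive shift: lower
potential = higher probability. Discrete probabilities must sum to 1
(1e-12); continuous densities are renormalised on their grid by the
trapezoid rule (a ±4 s.d. grid holds 0.99994 of Gaussian mass; rescaling
changes only the additive constant of U, never its shape). Zero-probability
points get infinite potential and are excluded from the minima search.

## Stable states, tipping points, classification

A local minimum is a grid point strictly below both neighbours; a boundary
point needs only its single neighbour higher. A flat run of equal values
bounded by higher values counts as one minimum at its midpoint (rounded
down) — on a 10-point active-count grid, counting a plateau twice would
fabricate bistability. The tipping point between two adjacent minima is the
maximal-potential point on the path between them (first index on ties), and
a minimum's barrier is the smallest potential rise to an adjacent tipping
point; with a single minimum the barrier is undefined (reported as NaN).
Detection is verified against an exhaustive neighbour-scan oracle on 1,000
random landscapes.

The theory's predictions are evaluated on a multiplier sweep of one
threshold/mean condition:

- *Severity (prediction 1).* The paper-level claim is visual ("deeper and
  steeper"); it is operationalised here as monotone mass transfer: the
  unhealthy half-depth (−min U over grid points above the axis midpoint)
  must strictly increase across multipliers while the healthy half-depth
  strictly decreases. Half-depths rather than per-minimum potentials are
  used so the criterion is defined even before a second minimum exists
  (mass can shift toward high activation before a valley forms there).
  Minima at or below the axis midpoint are "healthy", above it "unhealthy".
- *Discontinuity (prediction 2).* `yes` when the stable-state count rises
  from 1 to 2 and stays there, `partial` when two states appear and one
  vanishes again (1→2→1), `no` when no tipping point ever appears.

Model-level verdicts aggregate the per-condition verdicts over the
theory-consistent conditions — the negative mean-threshold conditions for
the Ising models (the positive-threshold condition contradicts the theory's
premise that symptoms tend to be off) and all mean conditions for the GVAR
model: all-yes → yes, all-no → no, mixed → partial. Under the default
calibration the {0,1} model is `yes`/`partial` (the mixed verdict arises
because the strongly negative τ = −7 condition never bifurcates within the
multiplier range — more connectivity would be needed the more negative the
thresholds), the {-1,1} model `no`/`yes` (both poles deepen), and the GVAR
model `no`/`no` (one minimum, fixed location).

## Synthetic baselines and calibration

The nine-symptom empirical Ising network that fixes the design's scale is
not available, so the generator emulates its printed summary properties:
nine nodes, all-positive pairwise weights, negative thresholds at the stated
condition means. Defaults:

| parameter | {0,1} | {-1,1} | rationale |
|---|---|---|---|
| mean weight | 0.5 | 0.14 | mean-field coupling (n−1)·c crosses 1 inside the multiplier sweep |
| weight s.d. | 0.1 | 0.03 | mild heterogeneity, truncated-normal positive |
| baseline mean τ | −3.5 | −0.2 | stated condition means |
| τ s.d. | 0.5 | 0.1 | heterogeneous thresholds without sign flips |

Calibration used the mean-field self-consistency `m = tanh((n−1)c·m + h)`
(`mean_field_fixed_points`, bisection to 1e-10) as an oracle only: for the
{0,1} baseline converted to {-1,1} form, the effective coupling is 1.0 at
multiplier 1 (critical) and 2.0 at multiplier 2 with residual field +0.25 —
inside the bistable wedge — while multiplier 0.9 is subcritical; the
{-1,1} baseline has coupling 1.12 / 2.24 at multipliers 1 / 2 around field
−0.2. Landscapes themselves always come from exact enumeration, never from
the mean-field approximation.

{0,1} threshold conditions derive from the baseline (×1, ×2, ×−1); the
{-1,1} condition means {−0.5, −0.2, 0.8} are not multiples of one another,
so those conditions recentre the baseline thresholds to the target mean,
preserving their spread. The GVAR temporal matrix is sparse — autoregression
U(0.2, 0.4) plus two outgoing cross-lagged edges U(0.1, 0.2) per node — 
because a dense nine-node matrix in those ranges has Perron root above one;
if the spectral radius at the largest multiplier (1.2) still exceeds 0.95
the matrix is rescaled uniformly and the factor recorded in `meta`. The
contemporaneous network is a small-world positive partial-correlation graph
(ring of two neighbours, rewiring probability 0.1, partial correlations
0.25), precision-inverted to a unit-variance covariance.

**What the generator does and does not emulate.** It reproduces the
qualitative landscape regimes (which condition × multiplier cells are mono-
vs. bistable, where minima sit, how barriers order) under heterogeneous
parameters. It does not reproduce the empirical network's exact weights,
so exact potential values, exact barrier heights and the precise minima of
intermediate conditions (e.g. the empirical healthy state at K = 1) are not
comparable — passing tests show the model families' dynamics, not estimates
for any real person.

## Grid, seeds, outputs

The default grid is 3 models × 3 conditions × 3 multipliers = 27 cells,
evaluated for 20 seeds (0–19). A single fixed empirical network needs no
replication, but synthetic surrogates do: stable-state counts are summarised
by their mode across seeds, minima locations by their median over the modal
seeds, and the per-seed theory classifications by their modal
(prediction 1, prediction 2) pair — under the defaults all 20 seeds agree
unanimously on every verdict. Each cell writes a landscape CSV
(representative seed with the modal state count), a JSON report with all
per-seed results, and a manifest listing seed, condition, multiplier and
connectivity per file; reruns with the same configuration are bit-identical.
Cell failures are recorded per cell and the run continues (nonzero CLI exit
at the end). Problem sizes (nine nodes → 512 states per Ising cell;
closed-form GVAR) keep the full default grid under two seconds and the whole
test suite, including a 2×10⁵-sample Glauber cross-check and a 2×10⁵-step
GVAR simulation check, near ten seconds.

## Known limitations

- Exact enumeration caps at 20 nodes (2ⁿ memory); larger networks would
  need the sampler plus a density estimate on K.
- The severity criterion is one defensible operationalisation of "deeper
  and steeper"; basin curvature or committor-based measures could order
  sweeps differently in edge cases.
- The GVAR route assumes Gaussian innovations; skewed or bounded variables
  (typical of affect data) are out of scope.
- Landscapes are one-dimensional projections (active count / sum score);
  states with equal K are aggregated regardless of which symptoms are
  active.
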