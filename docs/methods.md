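# Methods

## Model and state

The package simulates `N` urn-with-triggering processes that share a single
unbounded item (color) space. The state after `t` steps is the adoption-count
table `K_t(j, c)`, the originator map `j*(c)` (the unique agent that produced
item `c` first — simultaneous shared novelties have probability zero by
construction), and the derived counters `D*_{t,h}` (novelties produced by `h`)
and `D_{t,h}` (distinct items adopted by `h`). One ball is drawn from every
urn per time-step; draws within a step are conditionally independent given
the past and all use the time-`t` state. The per-step conditional law is the
closed form given in the README; the denominator `θ_h + t` is deterministic
because the balance condition fixes the per-step ball increment.

Conditional independence of the simultaneous draws is the natural reading of
"one ball drawn at random from each urn" and is the modelling choice adopted
here; nothing else in the package depends on it except the exhaustive
outcome-tree oracle, which makes the same assumption.

## Parametrizations

* **Raw**: integer ball counts `N0`, `ρ̂`, `ν`, `ρ` with the balance condition
  `ρ̂ + ν = ρ` and positive diagonals. This is the literal urn scheme.
* **Normalized**: `θ = N0/ρ_h`, `Γ = ν/ρ_h`, `Λ = ρ̂/ρ_h`, `W = Γ + Λ`
  (columns of `W` sum to 1, columns of `Γ` to < 1, `Λ ≥ 0`).

`normalize` carries an exact `fractions.Fraction` mirror of the parameters so
that oracle comparisons (below) can be made in exact rational arithmetic;
parameters built from floats are validated with a column-sum tolerance of
1e-12. `denormalize` inverts the map for a caller-chosen common denominator
and errors on non-integral products. Only the per-entry bounds and column
constraints stated above are enforced; off-diagonal `γ_{jh} = 1` is legal as
long as the column sum stays below 1.

## Simulation engine and its oracles

The simulator works at the probability level, never materializing balls: it
maintains per color the numerator array
`A[h, c] = Σ_j w_{jh} K_t(j,c) − γ_{j*(c),h}` incrementally (creation sets it
to `Λ[j*, ·]`, each adoption by `j` adds `W[j, ·]`), so a draw is one uniform
plus a cumulative-sum inversion over the current colors — O(#colors) per
agent-step, comfortable up to the 10⁵–10⁶-step horizons used here. Agents are
drawn in index order from a single seeded `numpy` generator and fresh ids are
assigned consecutively (ties within a step broken by agent index), making
trajectories bit-reproducible from the seed. `Λ ≥ 0` guarantees every
numerator stays non-negative; this is asserted at runtime.

Three independent routes check the engine:

1. **Literal urn oracle** (`LiteralUrnSystem`): integer ball bookkeeping that
   applies the replacement rules verbatim and reports probabilities as exact
   fractions; compared against the closed form in exact arithmetic on
   randomized reachable states.
2. **Outcome-tree enumeration** (`enumerate_paths`): exact rational
   enumeration of every trajectory of a small system; path probabilities sum
   to one, match products of literal-urn probabilities, and match empirical
   frequencies of 10⁵ seeded runs within four binomial standard errors.
3. **Mean recursion** (`expected_dstar_recursion`): because the denominator
   is deterministic, `E D*` satisfies the exact recursion
   `E D*_{t+1,h} = E D*_{t,h} + (θ_h + Σ_j γ_{jh} E D*_{t,j})/(θ_h + t)`;
   Monte-Carlo means are checked against it at three standard errors.

## Spectral predictions

Irreducibility is decided exactly on the support digraph (strict positivity
defines an edge) via strongly connected components. The Perron–Frobenius
eigenvalue and positive left/right eigenvectors come from a dense
eigendecomposition (the spectral radius of a non-negative matrix is itself an
eigenvalue, so selecting the largest real part suffices); residuals of both
eigen-equations must be below 1e-10, and the eigenvalue is asserted to lie
between the extreme column sums. Reducible matrices raise an explicit error —
decomposition into irreducible blocks is out of scope.

## Stream statistics

Event streams are tab-separated `(t, category, item, is_new)` with 1-based
time and categories; validation requires exactly one record per category per
time-step. Simultaneous first occurrences of an item in two categories are
impossible under the model; ingestion either rejects them (`error`) or
attributes the item to the lower category (`tiebreak`). Two unequal observed
sequences can be paired after seeded uniform subsampling of the longer one
(order preserved).

Composition quantiles drop items with fewer than 10 total adoptions, bin the
rest by `log10(total)` in half-open intervals of width 0.5 **anchored at
`log10(10)`** (anchoring at the filter threshold keeps the first bin
non-degenerate; the anchoring is otherwise a free choice), and compute
linear-interpolation empirical quantiles of the category-1 proportion per
bin. The reported probabilities default to deciles; both the reference
category and the probability set are configurable.

## Heaps fitting

`common_slope_fit` regresses `log10` of the selected counting curves on
`log10 t` with one shared slope and per-series intercepts — a closed-form
joint least-squares solve — and reports a single R² on the pooled log
residuals. The default grid is 200 log-equispaced integer times from `t = 10`
to `T`; log-equispacing prevents late times from dominating. Two analysis
windows matter in practice, both visible in the exact mean recursion rather
than in any stochastic output:

* the *slope* transient decays like `t^{γ*−1}`, so recovery harnesses fit
  from `t_min = 100`;
* the *ratio* `D*_{t,1}/D*_{t,2}` converges much more slowly (for the
  ratio-2 reference system the mean log10-ratio is still 0.279 at `t = 10⁵`
  against a limit of 0.301), so `û` — the intercept difference of the two
  novelty curves — is estimated on the last decade (`t_min = T/10`) of the
  two `D*` series only.

Whether all four curves (`D*` and `D` per category) or only the novelty
curves share the fitted slope is configurable; the default fits all selected
series jointly.

## Likelihood and the constrained MLE

The likelihood of a stream factorizes over the one-step conditionals: a
novelty contributes `log Z*_{t,h}` (which fresh label appears carries no
information), a repeat of item `c` contributes `log P_t(h,c)`. Events with
zero probability (e.g. adopting an item whose originator has no adoption
weight on the observer) raise an explicit error. For optimization the
likelihood is rewritten over parameter-independent sufficient statistics
(the `D*` vector at each novelty and the `K_t(·,c)` vector plus originator at
each repeat), making one evaluation a handful of matrix-vector products.

The two-agent MLE searches the **symmetric family**: `Γ` symmetric with its
Perron eigenvalue pinned to the externally fitted slope `γ̂*`
(`γ* = γ_d + γ_o` for a symmetric 2×2), `W` symmetric column-stochastic.
Free parameters are `θ_1, θ_2`, the diagonal/off-diagonal split of `γ̂*`, and
the off-diagonal adoption weight, reparametrized so that the box constraints
imply `W ≥ Γ` and positive diagonal `Λ` automatically. A symmetric `Γ` forces
centrality ratio 1, so the externally estimated ratio `r̂` enters only as a
compatibility diagnostic. Optimization is deterministic bounded L-BFGS-B
from a 3×3 grid of starts with tolerance 1e-8 on the log-likelihood; this
family construction is this package's own design.

## Synthetic-data conditions and problem sizes

The test and acceptance harnesses run entirely on data generated by the
package's own simulator — there is no external corpus in the loop. The
reference systems are two-agent configurations with `θ = (1, 1)` and
`γ* = 0.5`: `Γ = [[0.3, 0.1], [0.2, 0.4]]` (centrality ratio 1, `Λ ≡ 0.25`)
and `Γ = [[0.4, 0.1], [0.2, 0.3]]` (ratio 2), plus a fully symmetric system
(`γ = 0.2`, `w_offdiag = 0.4`) for likelihood recovery. Horizons are 10⁵
steps for the limit-theorem checks (10 seeds in the test suite, 5 in the
acceptance script) and 5·10⁴ for the MLE recovery; the exact-arithmetic
checks run at `t ≤ 50` and the exhaustive outcome tree at `t ≤ 3` with 10⁵
replicates. These sizes put the limit-theorem estimates within the
tolerances of the stochastic checks while keeping a full run at minutes on
one CPU.

What the generator does *not* emulate about real corpora: bursty and
non-stationary arrival rates, finite vocabularies, item-level heterogeneity
beyond reinforcement, and any upstream preprocessing (sentiment scoring,
stemming, topic selection). Passing tests therefore certify the
implementation and the internal consistency of the estimators under the
model's own law — not that any particular real data set follows that law.

## Known limitations

* Reducible interaction matrices simulate fine but have no spectral
  predictions here.
* The balance condition is assumed throughout; unbalanced dynamics (Heaps
  exponent 1) and asynchronous single-urn updates are not implemented.
* The MLE is restricted to the symmetric two-agent family; no confidence
  intervals or convergence-rate theory are provided.
* `u_hat` inherits the slow almost-sure convergence of the novelty ratio:
  at desk-scale horizons it is accurate to roughly ±0.1 even with the
  late-window estimator.
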