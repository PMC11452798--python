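# Methods

## Model

Adoption propensities evolve by linear consensus dynamics on an undirected,
connected, simple graph `G` of `n` participants. For each distance
`d = 1..D` (`D` the diameter), the d-path Laplacian `L_d` is the Laplacian
of the auxiliary graph joining node pairs at shortest-path distance exactly
`d`: off-diagonal entries `(L_d)_ij = −1` iff `d(i,j) = d`, diagonal entries
the size of node `i`'s d-th circle. Each `L_d` is symmetric positive
semidefinite with zero row sums, and `Σ_d L_d = n·I − J` because every pair
sits at exactly one distance. The generator is `M = L₁ + Σ_{d≥2} c_d L_d`
with dimensionless strengths `c_d ≥ 0` and `c₁ ≡ 1`; `u(t) = exp(−tM)u₀` is
computed through the symmetric eigendecomposition of `M`, which is exact for
this class of operators and lets one factorization serve every requested
time. Dense linear algebra throughout: the study scale is `n = 31`, and the
implementation is comfortable to a few hundred nodes.

Assumptions inherited from the model class: influence is symmetric,
time-homogeneous and linear in state differences; every participant is
predisposed to reach consensus (stubborn behaviour is outside the model and
shows up as lack of fit); the mean of `u₀` is conserved, so the consensus
value equals the initial adopter fraction `ū₀`.

### Discretization and thresholding

Round `i` of an `r`-round setting maps to `t_i = (i−1)·T/(r−1)`, so round 1
is exactly the initial condition. A node is an adopter at round `k` if
`u_i(t_j) > Δ·ū₀` for any `j ≤ k` (cumulative: once an adopter, always an
adopter — matching the cumulative definition used for the observed curves).
The threshold is expressed as a fraction `Δ ∈ (0,1]` *of the consensus
value* `ū₀`. With binary `u₀` (ū₀ = 4/31 ≈ 0.129 in the study protocol), a
raw threshold in [0.4, 0.99] could never be crossed by an initial
non-adopter, so the normalized form is the default; the raw form is
available via `normalized=False` for sensitivity analysis.

### Decay laws

Three named laws for `c_d` are built in, plus direct-only:
`linear_3: (4−d)/3` (the law the fitted coefficients follow; 2/3 and 1/3 at
the second and third circles), `linear_4: (5−d)/4`, `harmonic: 2/(1+d)`.
Linear laws are clamped at 0 (an influence strength is nonnegative, and
negative coefficients can break positive semidefiniteness); `clamp=False`
yields the signed value. The decay-law comparison experiment averages
adopter curves over seeded random 4-adopter initial conditions; its default
horizon `T = 5` is about one relaxation time `1/λ₂(L₁)` of the direct-only
dynamics on a 31-node study-like network, the regime in which the
direct-only curve is still mid-adoption across 15 rounds while the indirect
laws converge within a few — which is exactly the acceleration the
comparison is meant to display.

## Fitting

Per session-setting, one free coefficient (`c₂` for setting II, `c₃` for
III, `c₄` for IV; none for I) is estimated by exhaustive search over
`c ∈ [0,1]` step 0.01, `T ∈ [10,1000]` step 10,
`Δ ∈ {0.4,0.5,0.6,0.7,0.8,0.9,0.99}`, minimizing the mean squared error
between predicted and observed adopter curves; the Pearson correlation at
the optimum is reported alongside (undefined for constant curves). Ties on
MSE — common, since thresholded curves are quantized to multiples of 1/n —
break toward the lexicographically smallest `(c, T, Δ)`, i.e. the most
parsimonious model; ties are logged. Observed curves that ended early at
consensus are padded at the consensus value to the setting's round count
(truncation is available). Round 1 is included in the MSE; it matches by
construction. All seats, bots included, enter the observed curve.

## Synthetic sessions

The generator emulates the experimental protocol: 31 seats on a fixed
network, 4 uniformly random innovation seeds, four settings (two direct
peers displayed; plus two distance-k peers for k = 2, 3, 4), at most 13–15
synchronous rounds, display peers sampled once per setting with colours
refreshed every round (resampling per round is available), consensus ending
the setting early. Payoffs: 1 point per active round plus, on consensus,
5 points per round left to round 15 for participants active in one of the
last two rounds. Bots: 50% uniform random colour, 50% displayed majority
(ties uniform). Stubborn agents keep their initial colour throughout.
Inactive humans are replaced by a bot for the round with probability
`dropout_prob` (default 0).

What the protocol does not pin down is the individual choice rule, so it is
this package's construction: a human adopts with probability
`σ(α·f_direct + β_k·f_distant + γ·adopted − θ)`, `σ` the logistic link,
`f_*` the innovation fractions among the displayed direct/distant peers, and
`β_k = β·0.6^(k−2)` decaying with the displayed circle's distance — encoding
that information from farther circles moves choices less. Adopters never
revert while `cumulative` is on (the study's adopter definition). Defaults
`α = 3.4, β = 3.0, γ = 2.0, θ = 3.0` were calibrated once against the
protocol-level conditions: S-shaped curves from 4/31, indirect-setting
sessions reaching consensus within 15 rounds essentially always (setting I,
with direct information only, reaches consensus in roughly half the runs —
the same qualitative gap the experiment showed), fitted `c₂ > c₃` on
generated data, and mean fitted `c₂` increasing in `β`.

What passing tests on generated data do and do not show: the generator
shares the protocol and its constraints with the real experiment but not
human psychology — no visual-salience effects, no learning across settings,
no strategic timing of switches, no demographic heterogeneity. Recovery
results (e.g. that fitted `c₂` tracks distance-2 responsiveness) validate
the estimation machinery, not the behavioural claims themselves.

### Fixture networks

The constrained generator rewires a ring-lattice small-world substrate
(bounded, seeded retries) until every node has at least two nodes at each of
distances 1–4 and the diameter is ≥ 4 — the properties the display protocol
requires. The study's own network is instead read from a Pajek file, with
its documented modification (remove edge {10,30}, add {2,17}) applied as an
explicit, precondition-checked step.

## Statistics

Per-setting coefficient summaries use the sample standard deviation (n−1).
Mean differences are tested with Welch's two-sided unequal-variance t-test
(a seeded permutation test is available; the two agree on equal-variance
samples to Monte-Carlo error). Outlier detectors on per-session statistics:
Z-score (population sd, flag at `|z| ≥ 2`; a cutoff of 3 flags almost
nothing at 21 sessions, and for n ≤ 5 even 2 is unattainable since
`max|z| = √(n−1)`), Tukey fences (1.5·IQR), and leave-one-out mean change
(flag above 3× the median score). All cutoffs are configurable. Stubborn
participants: if the final-round modal colour covers ≥ 80% of seats, every
participant differing from it in both of the last two rounds is flagged
(bots excluded by default). The decay summary is the least-squares line
through `(d, c̄_d)` anchored at `(1, 1)`.

## Decision-level analysis

Each human choice from round 2 on is one observation with features:
initial-colour indicator, innovation-majority-among-displayed indicator
(ties → not majority), and the displayed direct and distant innovation
fractions (each in {0, 0.5, 1}). Accuracy is estimated by nested
cross-validation (outer 5-fold for test error, inner 5-fold grid search over
forest size {100, 300} and depth {none, 5, 10}), so hyperparameter selection
never sees test folds. Feature relevance is per-tree out-of-bag permutation
importance on a bagged forest of `max_features='sqrt'` decision trees (a
random forest exposing public per-tree bootstrap indices): permute one
feature within a tree's OOB sample, record the OOB-error increase, average
over trees. Importances are computed per setting; nonpositive values are
reported as-is. Bot decisions are excluded by default (their policy is
known).

## Problem sizes and numerics

Default runs use 21 sessions of 31 seats — the study's scale. One full grid
search (101 × 100 × 7 combinations) takes well under a second via the shared
eigendecomposition per coefficient value. The nested-CV accuracy in the
reproduction script subsamples the decision table to 8,000 rows (seeded)
when larger; the decay-law comparison uses 1,000 initial conditions.
Tolerances: Laplacian identities to 1e−12, PSD-ness to −1e−10, matrix
exponential vs an adaptive ODE integrator to 1e−8, mean conservation to
1e−10. Degenerate inputs (all-adopter or no-adopter initializations,
constant observed curves, constant features) raise or warn explicitly rather
than producing silent output.

## Known limitations

- The consensus model has no stubborn mechanism; stubborn seats surface as
  tail misfit and as outlier sessions, which is how the analysis treats
  them.
- One coefficient per setting is identified; the multi-term model with
  several simultaneous `c_d` is exposed but not the default, and the data
  a single setting provides cannot separate several coefficients well.
- Grid-search estimates are grid members by construction; no uncertainty
  beyond across-session dispersion is attached.
- The logistic choice rule and its β-decay are plausible but unvalidated
  constructions; conclusions about real participants require real session
  data.
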