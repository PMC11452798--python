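# innodiff

Direct **plus indirect** social influence in the diffusion of innovations on
social networks: consensus dynamics driven by *d-path Laplacians*, a seeded
generator of round-based colour-consensus experiment sessions, and grid-search
estimation of how peer pressure decays with social distance.

## The problem

When people adopt an innovation they are influenced by their direct social
ties — but also, through observation and imitation, by people socially close
to them who are *not* direct contacts. `innodiff` quantifies both. On an
undirected, connected friendship network, the nodes at shortest-path distance
`d` from a person form their `d`-th *circle of influence*. Each circle gets a
dimensionless influence strength `c_d` (with `c_1 ≡ 1` setting the scale), and
each adopter carries a continuous adoption propensity `u_i(t)` that relaxes
toward consensus under

```
du/dt = −(L₁ + Σ_{d≥2} c_d · L_d) u,      u(0) = u₀,
```

where `L_d` is the Laplacian of the graph connecting node pairs at distance
exactly `d`. The solution `u(t) = exp(−tM) u₀` conserves the mean `ū₀` of the
initial condition and converges to it everywhere. To compare with round-based
experiments, the trajectory is read off at `r` equispaced times in `[0, T]`
and thresholded: a node counts as an adopter once `u_i(t) > Δ·ū₀`, cumulative
across rounds.

The experimental protocol the package emulates: 31 participants, 4 of whom
start with the minority ("innovation") colour; four informational settings
(I: each participant sees two direct neighbours' colours; II–IV: additionally
two colours from the circle at distance 2, 3 or 4); up to 15 synchronous
rounds per setting, with payoffs rewarding fast consensus; inactive seats
played by bots (50% random, 50% follow-the-majority); occasional *stubborn*
participants who never join the consensus. Fitting the model to each
session-setting's adopter curve by exhaustive grid search over
`c ∈ {0, 0.01, …, 1}`, `T ∈ {10, 20, …, 1000}`,
`Δ ∈ {0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99}` (minimum mean squared error)
yields per-circle strengths whose decay with distance is summarized by a
linear law — the second and third circles exerting roughly two-thirds and
one-third of direct-neighbour pressure.

## Worked example

```python
import numpy as np
from innodiff import (
    generate_constrained_network, distance_matrix, path_laplacian_set,
    generate_session,
)
from innodiff.fitting import grid_search

net = generate_constrained_network(31, seed=1)   # study-like fixture network
dist = distance_matrix(net)
laps = path_laplacian_set(net)

sess = generate_session(net, seed=11, dist=dist) # one full 4-setting session
res = sess.settings[1]                           # setting II (distance-2 info)
print("consensus round:", res.consensus_round)
print("adopter curve:", np.round(res.curve.padded(15).proportion, 3))

fit = grid_search(res.curve.padded(15), laps, 2, res.initial.astype(float))
print(f"c2={fit.c:.2f}  delta={fit.delta}  T={fit.T:.0f}  "
      f"mse={fit.mse:.5f}  pearson={fit.pearson:.3f}")
```

prints

```
consensus round: 8
adopter curve: [0.129 0.258 0.419 0.581 0.645 0.871 0.968 1.    1.    1.    1.    1.
 1.    1.    1.   ]
c2=0.30  delta=0.99  T=20  mse=0.00416  pearson=0.979
```

The session starts with 4/31 ≈ 12.9% adopters, follows an S-shaped cumulative
adoption and reaches consensus in round 8. The grid search identifies a
distance-2 influence strength of 0.30 relative to direct neighbours, with the
fitted curve correlating 0.98 with the observed one.

The same analysis end-to-end, from the shell:

```
innodiff run --seed 1 --sessions 21 --out results/
innodiff decay-experiment --seed 1 --n-init 1000 --out results/decay.csv
```

`run` writes the session records, per-session fits, coefficient summary
(means ± sd per setting, pairwise Welch p-values, the fitted linear decay
law), outlier reports (Z-score, Tukey fences, leave-one-out mean change) with
stubborn-participant counts, and the decision-level random-forest feature
importances with nested-cross-validated accuracy. `decay-experiment` compares
mean adoption curves under the decay laws `c_d = (4−d)/3`, `(5−d)/4`,
`2/(1+d)` and direct-only influence.

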