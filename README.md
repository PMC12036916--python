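# pestgame

Government–enterprise differential game for forest pest-and-disease
management under carbon offsets.

Two players (a government and an enterprise) choose effort levels to manage
forest pests under one of three cooperation modes — individual action (`A`),
scarce-resource sharing (`S`) and information sharing (`I`). Each player's
payoff is an infinite-horizon discounted integral of gains, quadratic costs,
fixed transfer flows (carbon offset, information-sharing cost) and a
reputation stock that accumulates with effort and decays over time. The
package provides:

- **`pestgame.model`** — validated parameter sets and the canonical
  reduction of every (mode, player) pair to a linear-state, concave-effort
  control problem.
- **`pestgame.solver`** — closed-form feedback equilibria via the linear
  value-function ansatz: optimal constant effort `F*`, value coefficients
  `(m, n)`, the quadratic-in-gain decomposition `V = K + Q·(w·b + u)²`, and
  HJB residual diagnostics.
- **`pestgame.oracle`** — an independent brute-force verifier: closed-form
  reputation trajectories, trapezoid quadrature of discounted payoffs, and
  grid search over constant efforts.
- **`pestgame.comparison`** — mode rankings, analytic crossover gains,
  dominance-region maps over (gain, cost) grids, and comparative statics of
  `F*` (symbolic derivative cross-checked by finite differences).
- **`pestgame.scenarios` / `pestgame.report`** — the baseline numerical
  scenario, seeded random scenario generation, and end-to-end report bundles
  with embedded verification checks.
- **`pestgame.cli`** — the `pestgame` command.

## CLI

```sh
pestgame validate scenario.yaml           # strict schema check
pestgame solve --mode A --player government --b 1 --x 1
pestgame compare --player government --b 0 --c 4
pestgame regions --player enterprise --out region.csv
pestgame simulate --mode S --player government --out traj.csv
pestgame batch --seed 7 --n 10 --outdir reports/
pestgame reproduce                        # diff the 12 baseline decompositions
```

Parameter/scenario files are JSON or YAML with strict schemas (unknown keys
rejected); CLI flags override the baseline defaults. Exit codes: 0 success,
1 validation failure, 2 verification-check failure.

## Notes

- The discount rate must be strictly positive; values above 1 are accepted
  with a warning.
- The two players' problems are decoupled within each mode, so each
  (mode, player) pair is solved as an independent optimal-control problem.
- One value expression in the source derivations leaves the value-function
  slope symbolic; it is evaluated as `l/(ρ+δ)`, consistent with the linear
  ansatz used everywhere else.
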