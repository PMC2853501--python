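# statelump

Lumping-based model-order reduction for linear mono-molecular reaction
networks, with **analytical back-translation**: after simulating the
reduced model, every original state is recovered algebraically as its
quasi-steady-state fraction of the pool it belongs to — no re-simulation.
The reduced and original models act as two degrees of zooming of the same
system.

The pipeline:

1. **Fast/slow split** — rate constants above a threshold `epsilon`
   (the inverse of the time-scale of interest) form the fast reaction
   graph.
2. **Graph analysis** — weakly connected fast groups are found by
   ε-decomposition/total-connectivity; strong components are computed on
   the directed fast edges and classified as *sink clusters* (no
   outgoing fast edge) or non-sink components.  Non-sink components join
   a sink cluster's pool when their fast paths lead to exactly one sink
   cluster, or when a slow path returns from exactly one of several.
   States with all rates far below `epsilon` are frozen as constants
   (Gershgorin argument), and — opt-in — states reachable only through
   negligibly occupied states are eliminated.
3. **Fraction parameters** — for each pool, the quasi-steady-state
   system is solved with the conserved-moiety row replacing a
   sink-state balance; the solution gives time-invariant fractions
   `eta` (numerically, and in closed form via sympy on request).
4. **Reduced model** — pool totals become states; outgoing rate
   constants translate as `khat = sum_i k_i * eta_i`, initial
   conditions and output rows sum accordingly.
5. **Back-translation & comparison** — `x_i(t) = eta_i * xhat(t)`,
   plus error reports against full simulations.

Also included: a stiff/exact simulator, a balanced-truncation baseline
(Hankel singular values, square-root balancing on the stable part), a
synthetic generator of fast/slow networks with planted pools and known
fractions, and the nonlinear carrier-transport demonstration in which
the same moiety-QSS construction yields state-dependent fractions and
the classic carrier-mediated influx/efflux rate laws.

## Packaged models

- `statelump.fixtures.photosynthesis_6state()` — the 6-state
  fluorescence model with its reference rate constants; `epsilon = 100`
  reduces it to 2 states.
- `statelump.fixtures.photosynthesis_26state()` — the 26-state
  fluorescence model; `epsilon = 1000` with elimination threshold
  `1e-5` reduces it to 6 states with a cyclic pool structure.  The
  wiring reproduces the known structural facts of the reference network
  (see the module docstring); a checksum test guards the fixture.
- `statelump.fixtures.glucose_transport()` — the nonlinear
  carrier-transport model (rate constants are repository-chosen).
- `statelump.fixtures.planted_network(spec)` — synthetic ground truth.

## CLI

```sh
statelump fixtures --out fixtures            # export models as JSON
statelump reduce fixtures/photo6.json --epsilon 100 --out out6
statelump reduce fixtures/photo26.json --epsilon 1000 \
    --eliminate-threshold 1e-5 --out out26
statelump simulate fixtures/photo26.json --out sim
statelump compare fixtures/photo6.json out6/reduced_model.json \
    out6/backtranslation_map.json --t-end 5 --t-min 0.1 --out cmp
statelump backtranslate out6/reduced_model.json out6/backtranslation_map.json
statelump baseline-bt fixtures/photo26.json --order 6 --out bt
```

`reduce` writes the reduced model (same JSON dialect, so it can be
simulated or reduced again), the back-translation map, the scheme report
with a per-decision log, fraction parameters as CSV, and a provenance
file linking every reduced rate constant to its defining sum.

## Model file format

The native JSON dialect lists states, first-order reactions
(`{"source": "x2", "target": "x1", "name": "k12", "value": 6.72}`,
target `"EXTERNAL"` for outflows; units 1/s), matrices `B`, `C`, `D`
row-major, and `x0`.  `write_model`/`load_model` round-trip exactly.
SBML Level 2/3 files are readable when every kinetic law is
`k * species`.

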