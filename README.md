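# rnascale

A techno-economic model of RNA vaccine drug-substance (DS) manufacturing for
pandemic-scale demand. Given a vaccine definition (RNA mass per dose, UTP
chemistry), process parameters (bioreactor working volume, titre, recovery,
failure rate, batch scheduling anchors) and calibrated cost parameters, the
package computes:

- annual production mass and doses, required batches, total bioreactor
  volume, facility counts and single-line time-to-demand (`throughput`);
- CapEx, annual OpEx (including annualised capital) and cost per dose with a
  per-component breakdown, plus a calibration routine that refits cost
  coefficients to aggregate targets (`economics`);
- one-at-a-time tornado sensitivity, ±20% titre scenarios, scale sweeps and
  effective-recovery recalibration (`sensitivity`);
- pouch-filling throughput and the DS-vs-fill-finish bottleneck comparison
  (`fillfinish`);
- the five study vaccine presets (100, 30, 12, 1 and 0.1 µg RNA/dose),
  YAML/JSON configuration I/O and a randomized scenario generator for
  property tests (`scenarios`);
- a CLI tying it all together (`cli`).

## CLI

```sh
rnascale capacity  [--config cfg.yaml] [--scenario all|NAME|config] [--demand N] [--out DIR] [--format csv|json]
rnascale timeline  [--config cfg.yaml] [--demand N] [--out DIR]
rnascale tornado   [--config cfg.yaml] [--out DIR] [--plot tornado.png]
rnascale fillfinish [--out DIR]
rnascale calibrate examples/batch_table.csv [--out DIR]
```

`capacity` emits the resource table (CapEx, OpEx, cost/dose, total scale,
batches, facilities) per scenario for low/medium/high titre (4/5/6 g/L);
`timeline` the single-line production times at the feasible and 30 L scales;
`tornado` the sensitivity table sorted by effect size. Reports are
deterministic for fixed inputs and include a full parameter echo with
provenance (default vs config). Example configs for all five vaccine
presets live in `examples/`.

## Configuration

A single YAML or JSON file with optional sections `vaccine`, `process`,
`cost` and `demand`; omitted fields take the documented baseline defaults
(30 L, 5 g/L titre, 56% nominal downstream recovery, 5% failure rate,
8 billion doses/year demand). See `examples/mRNA-100ug.yaml` for the full
schema.

Two recovery conventions are deliberately explicit: resource sizing (batch
counts, volumes, facilities, costs) uses the effective recovery
`nominal x (1 - failure_rate) x residual_loss_factor` (~0.4922 at defaults),
while production timelines use the nominal recovery (0.56) alone. The
residual loss factor and all cost coefficients are calibration constants;
`sensitivity.recalibrate_recovery` and `economics.calibrate_costs` refit
them from aggregate tables.

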