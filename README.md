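# groundflow

Closed-loop simulation and analysis of altitude control from ground
optic-flow invariants.

A flying agent traversing a narrow tunnel can read its altitude changes
from two optical invariants: the rate of change of the ground's optical
speed (`ω̇`, with `ω = ẋ/z`) and the rate of change of the splay angle of
a ground-parallel line (`Ṡ`, with `S = arctan(y/z)`). For constant
forward speed and no lateral drift both relative rates reduce to
`−ż/z`, so either can serve as the error signal of an altitude
controller. This package implements:

- **`invariants`** — the two invariants and their relative-rate forms,
  plus finite-difference extraction from sampled series;
- **`tunnel`** — the 220 × 71 × 25 cm flight tunnel, striped/white floor
  textures (modelled as an optical-speed accessibility coefficient) and
  motorized rods that manipulate the splay angle statically (between
  flights) or dynamically (during flight);
- **`controller`** — a priority-based control law: the optical-speed
  rate is used exclusively when its accessibility is high; otherwise
  the two invariants are blended, and a safety veto blocks descent
  commands driven by the splay rate alone. `simulate_flight` integrates
  the closed loop and records 100 Hz trajectories;
- **`pipeline`** — pixel-to-cm calibration of the cropped video frame
  (620 × 210 px ↔ 160 × 71 cm), 150 ms median binning, a
  ground-following flight filter, and flights-by-bins epoch matrices
  around the manipulation onset;
- **`stats`** — Friedman omnibus test, exact all-pairs rank-sum post hoc
  comparisons and Mann–Whitney, each with full-enumeration nulls when
  the permutation space allows (≤ 10⁶) and seeded Monte-Carlo or
  asymptotic fallbacks otherwise, plus a type-I-error harness;
- **`synthio` / `experiment` / `cli`** — reproducible synthetic cohorts
  (per-flight truncated-normal speed, entry-altitude jitter, process and
  tracking noise, optional 3.381 mm pixel quantization), per-flight CSV +
  JSON-sidecar I/O, and end-to-end experiment runners.

With default settings the 16-cell study (4 rod modes × 2 textures for
each of the dynamic and static experiments) reproduces the expected
qualitative pattern: a significant altitude increase only under
dynamically converging rods over a white floor, and no effect in any
static or striped-floor condition. With the safety veto disabled,
diverging rods produce the mirror-image descent.

## Command line

```sh
groundflow simulate --config cohort.yaml --seed 7 --out flights/
groundflow analyze  --flights flights/ --out analysis/
groundflow validate --seed 2 --reps 300
groundflow report   --seed 3 --n-flights 10 --out grid.csv
```

`simulate` writes one `t_s,x_cm,z_cm` CSV (10 ms rows) plus a JSON
sidecar per flight. `analyze` produces the condition-outcome grid, epoch
matrices and all-pairs p-value tables (including the lower-triangular
bin-by-bin form). `validate` runs the invariant identity suite, the
exact-test self-checks and a type-I simulation, exiting non-zero on any
failure. `report` simulates both experiments and prints the significance
grid.

A cohort config is a YAML/JSON mapping of `CohortSpec` fields with an
optional `controller` section for `ControllerParams`, e.g.

```yaml
n_flights: 10
conditions:
  - [parallel, white]
  - [dynamic_converging, white]
controller:
  safety_mode: true
```

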