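# protonsim

A simplified Monte Carlo dose engine for double-scattering proton therapy.
The treatment nozzle is reduced to a single lead foil inside a cylindrical
shell; all of the machine's complexity is pushed into a layered source
model — discrete energy layers with per-layer weights and energy spreads —
which feeds thin-plane beamline devices (aperture, Lucite compensator) and
a condensed-history proton transport engine in voxelized phantoms.

## What's inside

| module | role |
| --- | --- |
| `protonsim.materials` | material table; power-law range–energy model; stopping power; water-equivalent thickness (WET) |
| `protonsim.source_model` | energy-layer ladder construction, layer sigma (entrance spread ⊕ range straggling in quadrature), weight fitting (NNLS + minimax fallback), disk-source sampling |
| `protonsim.beamline` | lead foil (WET degrade + Highland scatter), nozzle wall, aperture masks, compensator thickness maps |
| `protonsim.transport` | numba condensed-history loop: boundary-clamped steps, Bohr-like straggling, Highland MCS, exponential nuclear attenuation, midpoint dose scoring with per-history variance |
| `protonsim.metrics` | depth-dose / lateral-profile extraction, SOBP range–modulation–flatness, distal 80–20 falloff, penumbra, gamma index (2%/2 mm, global) |
| `protonsim.oracle` | independent analytic Bragg-curve model (CSDA + straggling convolution) used for weight optimization and engine cross-checks |
| `protonsim.fixtures` | built-in geometries: 40 cm water tank, three-step stair compensator, bone/lung slab phantom |
| `protonsim.pipeline` | source → beamline → phantom runs; MC-in-the-loop commissioning |
| `protonsim.cli` | `protonsim` command-line interface |

## CLI

```bash
# commission a source (range/modulation in cm of water)
protonsim build-source --range 8 --mod 5 --out source.json

# simulate a run described by a YAML config
protonsim simulate --config run.yaml

# extract metrics / curves from a dose grid
protonsim analyze --dose out/dose.h5 --profile-depths 3,5,7 --out report.json

# gamma comparison of two exported curves
protonsim compare --reference a.csv --evaluated b.csv

# export built-in geometries
protonsim fixtures --name stair-compensator --out stair.csv
```

A minimal `run.yaml`:

```yaml
range_cm: 8.0
modulation_cm: 5.0
histories: 200000
seed: 7
phantom: water-tank
phantom_voxel: 1.0
scoring_voxel: [0.4, 0.4, 0.1]
aperture: {shape: circle, radius: 12.5}
out_dir: out
```

## Physics notes

- Range–energy uses the Bragg–Kleeman power law (`R = 0.0022·E^1.77` cm,
  MeV) for water; other materials are tracked purely via relative
  stopping power.
- Per-layer energy sigma = entrance spread (default `0.007·E`) ⊕ range
  straggling (default `0.012·R^0.935` cm via the stopping power), both
  injectable.
- Nuclear interactions are a stand-in: primaries removed at
  `1 − exp(−0.012/cm WET)`, depositing 60% of their remaining energy
  locally.
- Same seed ⇒ bit-identical dose grids (single-threaded kernel with a
  seeded generator).
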