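# odorcap

Simulation and analysis tools for asking how many stimuli a perceptual system
can discriminate — and for demonstrating how sphere-packing extrapolations
from overlap-controlled mixture-discrimination experiments can overestimate
that number by many orders of magnitude.

The package implements:

- **Three encoding models** (`odorcap.models`)
  - *microbe*: mixtures of ±1 components are summed and collapsed to three
    categories (`yum` / `meh` / `yuck`); responses are deterministic.
  - *color*: mixtures add linearly in a 3-D RGB unit cube; iid Gaussian noise
    per coordinate, calibrated so a Euclidean separation of 0.01 (the JND) is
    just discriminable in the odd-man-out test.
  - *ring*: components are unit vectors on a circle; a mixture maps to the
    angle of the normalized vector sum, corrupted by Gaussian angular noise
    (SD 0.4 rad by default).
- **Synthetic mixture designs** (`odorcap.mixtures`): pools of 128 random
  primaries, pairs of N-component mixtures sharing exactly O components,
  overlap classes of 20 pairs, plus an "unbounded-dimensional" color variant
  with fresh random component vectors per pair. JSON export/import for audits.
- **The odd-man-out protocol** (`odorcap.protocol`): three noisy samples per
  trial (two from one mixture, one from the other), nearest-pair decision,
  26 trials per pair, discriminable at ≥ 14/26 correct; class fractions,
  mean ± SD discriminability-vs-overlap curves over 1000 replicate designs,
  and critical-distance extraction (50% crossing, linear interpolation).
- **Capacity estimates** (`odorcap.capacity`): the Hamming-bound sphere-
  packing count in exact big-integer arithmetic (with geometric-mean
  interpolation at odd diameters), the sphere-coloring lower bound
  k(q) = ⌈1/(1−q)⌉, grid percept counts, the Monte-Carlo ring capacity, and
  the critical color-mixture size at which one unshared component stops
  being discriminable.
- **Orchestration** (`odorcap.reports`, `odorcap.cli`): seeded figure runs
  with CSV/JSON/PNG artifacts and checksummed manifests, and a ten-row
  headline-claim table with pass/fail flags.

## CLI

```sh
# discriminability-vs-overlap curve as CSV
odorcap simulate --model microbe --n 30 --n-replicates 1000 --seed 1 --out curve.csv

# exact packing count, coloring bound, grid count, subset count, ring capacity
odorcap capacity sphere-count --c 128 --n 30 --d 15
odorcap capacity coloring --q 0.9999
odorcap capacity grid --jnd 0.01 --dims 3
odorcap capacity subsets --c 128 --n 60
odorcap capacity ring --sigma 0.4
odorcap capacity critical-size --jnd 0.01

# full figure runs (fig1 microbe, fig2/fig2c color, fig3 ring) and the
# headline-claim table; config may come from a flat YAML file
odorcap figures fig1 --seed 0 --outdir results
odorcap acceptance --seed 0 --outdir results
```

## Reproducibility

All randomness flows from a single seed through spawned substreams: the same
seed gives byte-identical CSV/JSON outputs, and every figure run writes a
manifest listing each artifact with its SHA-256 checksum.
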