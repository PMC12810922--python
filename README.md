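# mitofast

Quantitative machinery for studying **mitochondrial DNA quality control in
budding yeast**: how populations founded by heteroplasmic zygotes — cells
carrying both an intact, fluorescently tagged mtDNA (mtDNA^ATP6-NG^) and an
unlabeled mutant variant — segregate into fluorescent and dark
subpopulations, and whether the observed depletion of mutant mtDNA can be
explained by growth-rate differences and founding copy-number asymmetries
alone.

The package provides:

- **`mitofast.flow_gating`** — the FAST classifier (Flow cytometry Analysis
  for Segregation Tracking): debris gating on the FSC-H/FSC-A ratio, a
  Gaussian KDE of log10 fluorescence, detection of the two major peaks and
  the interpeak valley, and classification of events into *dark*,
  *heteroplasmic* (valley ± 10 % of the interpeak distance) and
  *fluorescent* fractions.
- **`mitofast.segregation_sim`** — an agent-based simulation of nucleoid
  segregation. Each cell carries an ordered string of N = 32 nucleoids
  (0 = reference, 1 = mutant); heteroplasmy *h* is the fraction of 1s. Per
  generation (one reference doubling time) a cell divides with probability
  p = 2^g − 1 where g = 1 + (g_other − 1)·h interpolates the relative
  growth rate linearly in *h*. Division cuts the string at `nspl` random
  boundaries, assigns segments to mother and daughter by fair coins, and
  replenishes both to N by duplication. Defaults: ngen = 14, ndau = 11,
  nspl = 5, 30 founders.
- **`mitofast.quant_stats`** — growth-rate/doubling-time fits
  (T_d = ln 2 / r), plate doubling times from cell counts, exponential
  fluorescence half-life fits, qPCR relative copy number (COX1/ACT1,
  ΔCq with perfect efficiency), growth-factor inference from mixing-assay
  fractions, Monte-Carlo one-sided p-values against simulation
  distributions, and Fisher combination (−2 Σ ln p ~ χ²(2k)).
- **`mitofast.mito_metrics`** — mitochondrial network skeleton metrics on
  vertex tables: total network length, ratiometric channel summaries
  (e.g. QUEEN 400/480, TMRM/mtNG), and P2/P1 zygote compartment ratios.
- **`mitofast.synthetic_data`** — seeded generators with planted ground
  truth for every input the pipeline consumes: log-normal flow-cytometry
  mixtures with debris, decay series, growth curves, Cq tables, and 3-D
  skeleton tables.
- **`mitofast.pipeline`** — the headline comparison: gate FAST replicates,
  run matched simulations, and test whether the simulation significantly
  exceeds the measurement (Monte Carlo per replicate + Fisher combination).

## Worked example

```python
import random
from mitofast import (SimConfig, init_founder, run_replicates,
                      compare_fast_to_sim)

# A zygote from a 1:0.71 cross starts with 13 of 32 mutant nucleoids:
founder = init_founder(32, 0.71, random.Random(0))
print(sum(founder.alleles))            # -> 13

# Simulate 100 replicate 20 h expansions (14 generations) with the 2 %
# growth penalty measured for the mutant strain:
cfg = SimConfig(ratio=0.71, g_other=0.98, n_runs=100, seed=1)
sim = run_replicates(cfg)
print(f"{100 * sim.grand_mean:.1f}%")  # -> 40.0%  (predicted mutant cells)

# The flow measurement found only 27.7% dark cells; is that compatible?
report = compare_fast_to_sim([0.277, 0.28, 0.27], cfg, B=10_000, seed=2,
                             sim_result=sim)
print(report.verdict, report.stars)    # -> simulation exceeds FAST ***
```

The simulation predicts ~40 % mutant cells from growth and copy number
alone, well above the measured 27.7 % — the discrepancy that points to an
additional intracellular mode of selection against the mutant genome.

A console script mirrors the library:

```bash
mitofast simulate --config sim.toml --runs 100 --seed 7 -o result.json
mitofast gate --events events.tsv -o report.json
mitofast fast-compare --observed 0.277,0.28,0.27 --sim-config sim.toml -o cmp.json
```

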