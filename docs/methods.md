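# Methods

This note documents the models, estimators and numerical choices behind
`mitofast`, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate about real instrument data.

## The segregation model

Cells are agents carrying an **ordered string of N nucleoids**, each coded 0
(reference mtDNA, fluorescently tagged) or 1 (the competing variant).
Heteroplasmy *h* of a cell is the fraction of 1s. The string is ordered to
represent limited spatial mixing of nucleoids in the mitochondrial network:
segregation acts on contiguous segments, not on a well-stirred pool.

**Founder initialization.** A founder at copy-number ratio *r*
(variant : reference) starts from the alternating string `[1,0,1,0,…]` and
flips randomly chosen positions until the count of 1s equals
`round(N · r/(1+r))` — i.e. *r* is converted to a variant *fraction*
`r/(1+r)` before rounding (half away from zero). At N = 32 and r = 0.1 this
gives 3 ones and 29 zeros; at r = 0.71, 13 ones (h₀ = 0.406). The fraction
rule is the only reading under which a 1:0.71 cross can produce ≈40 % final
variant cells, which anchors the headline comparison.

**Growth coupling.** One simulation step is one doubling time of the
reference strain. A cell divides in a step with probability

    p = clamp(2^g − 1, 0, 1),   g = 1 + (g_other − 1) · h .

At h = 0 this gives p = 1 (a reference cell divides every reference
doubling time, by construction); at h = 1 the cell divides at the rate
implied by the homoplasmic variant strain's relative growth rate `g_other`
(0.98 for the Δcox2 variant, 0.93 for Δatp6, 1.0 for a neutral variant).
The linear interpolation in *h* is an assumption — the mildest model linking
genotype dosage to growth. For g_other > 1 the probability is clamped at 1.

**Division mechanics.** The string is cut at `nspl` distinct internal
boundaries chosen uniformly (default 5, giving 6 segments); each segment
goes to mother or daughter by an independent fair coin, redrawn if either
cell would receive nothing. Both cells then replenish to N by duplication:
each missing copy is **templated from a uniformly chosen nucleoid of the
parental string** and inserted at a uniform position in the child.

The parental-template choice is deliberate. Duplicating from the child's own
residents looks natural but is *not* neutral for the unweighted population
mean of h: the coin assignment randomizes child sizes, and the expectation
of the ratio ones/size is biased toward 1/2 (measured at about +0.004 per
division for the 13/32 founder and +0.016 for clustered minorities — a
mean-reverting pseudo-selection that would corrupt the neutral baseline the
significance test rests on). With parental templating the expected number of
inherited 1s is K/2 per child and each duplicate is a 1 with probability
K/N, so E[h_child] = h exactly, and with g_other = 1 the population mean of
h is a martingale at any ngen/ndau/nspl. Biologically, the mitochondrial
network of mother and bud remains continuous until cytokinesis, so
replication restoring copy number can template from the shared pool.

**Lifespan and protocol.** A cell stops dividing after `ndau = 11`
divisions (replicative lifespan); daughters start at zero. A run grows
30 independent founders for `ngen = 14` synchronous generations (14 × the
1.48 h plate doubling time ≈ 20.7 h, covering the 20 h experiment) and
reports the unweighted mean of h over all final cells. Replicate protocols:
100 runs for measured ratios, 10 runs per grid point for the 0.10–1.00
ratio sweep. At these defaults one run ends with ~4.6 × 10⁵ cells; the
generation loop is a compiled (numba) kernel with an inlined xorshift64*
generator, seeded per run, because the interpreted reference engine
(retained in `_simulate_once_python` and cross-checked statistically in the
tests) is ~400× slower. Per-run variance of mean_h is a property of these
specific mechanics and is not treated as a calibrated quantity; only mean
behavior is.

## The FAST classifier

Events are first gated on the FSC-H/FSC-A ratio (default band 0.7–1.3;
debris such as dirt or agar falls off the diagonal). The classifier then:

1. computes a Gaussian KDE of log10 fluorescence on a 512-point grid
   spanning the data range ± 3 bandwidths, with Silverman's rule-of-thumb
   bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` on the log10 values;
2. takes the two most prominent density maxima (prominence ≥ 5 % of the
   density maximum, so minor ripples and a small heteroplasmic bump do not
   masquerade as major peaks) as the dark and fluorescent modes;
3. finds the valley as the global density minimum strictly between them;
4. classifies events against the window valley ± 10 % of the interpeak
   distance: below = dark, inside (bounds inclusive — ties count as
   heteroplasmic, the conservative direction) = heteroplasmic, above =
   fluorescent. Fractions are reported over post-debris events.

The log10 transform, bandwidth rule, grid size and prominence threshold are
package choices; they are stable across the synthetic populations tested
but were not tuned against any instrument's characteristics. A window
extending past either peak raises an error (peaks too close). Unimodal
samples raise a dedicated error; for those, `dark_fraction_control`
thresholds at the 99.9th percentile of a non-fluorescent control sample,
so a fully fluorescent sample reads ≈0 with a ≤0.1 % false-positive floor.

## Synthetic populations

`make_flow_mixture` draws per-component log-normal fluorescence
(multinomial component membership), log-normal FSC-A, cell fsc_h/fsc_a
ratios near 1 (sd 0.03), and debris with ratios uniform in 0.1–0.6 and dim
autofluorescence. The canonical segregated-population geometry
(`fig1e_like_spec`) places the dark and fluorescent components at log10
means 2.0 and 4.0 (sd 0.32) — about two decades of separation, typical for
a bright reporter over autofluorescence — and the heteroplasmic stand-in at
the midpoint with sd = 0.08 × the interpeak distance.

That intermediate width balances two failure modes, chosen by analysis of
the mixture density before any end-to-end run: a much narrower spike makes
the smoothed density locally convex at the midpoint, carving flanking dips
that capture the detected valley and displace the ±10 % window off the
planted component; a much wider component leaves most of its mass outside
the window. At 0.08·d about 79 % of the component falls inside the window
and main-component tail leakage compensates the remainder, so the recovered
heteroplasmic fraction tracks the planted one and is insensitive to the
residual sampling wander of the valley position. Because the intermediate
component is a stand-in — the fluorescence distribution of genuinely
heteroplasmic cells is not characterized — recovery tests validate the
classifier's window logic, not a biological model of heteroplasmic
fluorescence. Likewise the generators emulate neither spectral spillover,
instrument noise floors, nor acquisition-time drift; passing recovery tests
demonstrates correctness of the estimators on clean mixtures, not
robustness to every instrument artifact.

## Estimators

- **Growth rate**: OLS of ln OD₆₀₀ on time; T_d = ln 2 / r. The automatic
  window takes the contiguous stretch with OD between 2× the initial value
  and half the maximum (exponential phase) maximizing r², ties broken
  toward the longest then earliest stretch; an explicit window overrides.
  Fits require ≥4 points and a positive slope.
- **Plate doubling time**: T_d = t · ln 2 / ln(n_f/n₀) from initial and
  final cell counts.
- **Fluorescence half-life**: OLS of ln(median) on time;
  t½ = ln 2 / (−slope); non-decaying series are an error.
- **qPCR relative copy number**: per replicate 2^(Cq_ACT1 − Cq_COX1)
  (perfect doubling per cycle; efficiency is an explicit model assumption),
  replicate means per strain, normalized so the reference strain is
  exactly 1.
- **Growth factor from mixing assays**: with equal founder numbers growing
  exponentially for G reference generations, a final dark fraction f gives
  g_other = 1 + log₂(f/(1−f))/G. This inversion is the package's
  reconstruction of the calculation; G defaults to total time divided by
  the reference doubling time (20 h / 1.48 h ≈ 13.5).

## Significance testing

Each measured replicate fraction is compared against the simulated
distribution of final variant fractions by resampling: B draws with
replacement from the per-run values, one-sided p =
(1 + #{draw ≤ observed}) / (B + 1). The add-one estimator keeps p > 0 so
Fisher's method (−2 Σ ln p ~ χ²(2k)) is always defined; "≤" resolves the
tie direction conservatively. Small combined p means the simulation
systematically exceeds the measurement — evidence for selection beyond
growth and copy number. The alternative direction is configurable for
crosses where simulations may underestimate the dark fraction. Under the
null the p-values are uniform (verified by KS test in the suite).
Significance tiers follow the 0.05 / 0.005 / 0.001 star convention.

## Network metrics

Vertex tables are one row per skeleton node with line and point indices,
coordinates in µm and per-node channel intensities. Network length sums
Euclidean segment lengths along consecutive points per line (single-point
lines warn and contribute zero). Ratiometric summaries offer the per-node
mean of ratios (zero-denominator nodes excluded and counted) and the ratio
of sums; both are provided because compartment-level readouts can use
either statistic. Compartment ratios evaluate the chosen summary separately
on P1- and P2-labelled nodes and divide; compartment masks are consumed as
a label column — image segmentation is out of scope.

## Known limitations

- The division mechanics (meaning of ndau and nspl, the partition and
  replenishment scheme) are this package's concrete instantiation of a
  segment-based segregation model; alternative martingale-preserving
  mechanics would change per-run variance but not neutral means.
- The simulation has no cell death, no population cap, no explicit zygote
  geometry, and no spatial network model (fusion/fission).
- qPCR efficiency is fixed at 2 unless overridden; no standard-curve
  calibration is modelled.
- The FCS binary format is not parsed; event tables are consumed as TSV
  (readers subsample to the 10,000-event acquisition cap, seeded).
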