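"""Agent-based simulation of mtDNA nucleoid segregation in a growing yeast population.

The model tracks cells descending from heteroplasmic founders.  Each cell
carries an ordered string of N nucleoids coded 0 (reference, fluorescently
tagged mtDNA) or 1 (the competing "other" variant); the heteroplasmy level h
of a cell is the fraction of 1s.  One simulation step corresponds to one
doubling time of the reference strain.  Within a step a cell divides with
probability

    p = 2**g - 1,   g = 1 + (g_other - 1) * h

so a pure-reference cell (h=0, g=1) divides every step, while a cell
homoplasmic for the other variant divides at the rate implied by that
strain's relative growth rate ``g_other`` (clamped to [0, 1] when
g_other > 1).  At division the nucleoid string is cut at ``nspl`` random
internal boundaries, the resulting segments are distributed to mother and
daughter by independent fair coins (re-drawn if either cell would be empty),
and both cells replenish back to N nucleoids by duplication: each missing
copy is templated from a uniformly chosen nucleoid of the *parental* string
and inserted at a random position in the child.  (In budding yeast the
mitochondrial network of mother and bud remains continuous until cytokinesis,
so replication that restores copy number can template from the shared pool.)
Cells stop dividing after ``ndau`` divisions (replicative lifespan);
daughters start fresh.

Parent-templated replenishment makes E[h] of every child exactly the parent's
h when g_other = 1 (E[inherited 1s] = K/2 and each duplicate is a 1 with
probability K/N, so the expectation is linear in the parent composition and
no intracellular selection is built in).  Duplicating from the child's own
residents instead would bias E[ones/size] toward 1/2 because the segment
assignment randomizes child sizes; that variant is measurably mean-reverting
and is deliberately not used.  Population-level depletion of the variant
arises only through the growth coupling and the founder copy-number
asymmetry.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NucleoidCell",
    "SimConfig",
    "SimResult",
    "SweepResult",
    "init_founder",
    "growth_rate_ratio",
    "division_probability",
    "divide_cell",
    "simulate_population",
    "run_replicates",
    "sweep_ratios",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class NucleoidCell:
    """One simulated cell: an ordered binary nucleoid string plus its division count."""

    alleles: list[int]
    divisions_done: int = 0

    @property
    def h(self) -> float:
        """Heteroplasmy level: fraction of non-reference (1) nucleoids."""
        return sum(self.alleles) / len(self.alleles)

    @property
    def n_nucleoids(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a segregation simulation.

    ratio is other:reference mtDNA copy number in the founding zygote, so the
    founder starts with a variant fraction of ratio / (1 + ratio).
    """

    ratio: float
    g_other: float = 1.0
    n_nucleoids: int = 32
    ngen: int = 14
    ndau: int = 11
    nspl: int = 5
    n_founders: int = 30
    n_runs: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError(f"ratio must be >= 0, got {self.ratio}")
        if not (0 < self.g_other <= 2):
            raise ValueError(f"g_other must be in (0, 2], got {self.g_other}")
        if self.n_nucleoids < 2 or self.n_nucleoids % 2:
            raise ValueError("n_nucleoids must be even and >= 2")
        if self.ngen < 1:
            raise ValueError("ngen must be >= 1")
        if self.ndau < 1:
            raise ValueError("ndau must be >= 1")
        if not (1 <= self.nspl <= self.n_nucleoids - 1):
            raise ValueError("nspl must be in [1, n_nucleoids - 1]")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class SimResult:
    """Per-run population mean heteroplasmy and summary statistics."""

    mean_h: np.ndarray           # one entry per run
    final_cells: np.ndarray      # total cells at the end of each run
    config: SimConfig

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.mean_h))

    @property
    def sd(self) -> float:
        return float(np.std(self.mean_h, ddof=1)) if len(self.mean_h) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "mean_h": [float(x) for x in self.mean_h],
            "final_cells": [int(x) for x in self.final_cells],
            "grand_mean": self.grand_mean,
            "sd": self.sd,
            "config": {
                "ratio": self.config.ratio,
                "g_other": self.config.g_other,
                "n_nucleoids": self.config.n_nucleoids,
                "ngen": self.config.ngen,
                "ndau": self.config.ndau,
                "nspl": self.config.nspl,
                "n_founders": self.config.n_founders,
                "n_runs": self.config.n_runs,
                "seed": self.config.seed,
            },
        }


# ---------------------------------------------------------------------------
# elementary operations


def _target_ones(n: int, ratio: float) -> int:
    # variant fraction ratio/(1+ratio), rounded half away from zero
    return int(n * ratio / (1.0 + ratio) + 0.5)


def init_founder(n: int, ratio: float, rng: random.Random) -> NucleoidCell:
    """Build a founder cell at the requested other:reference copy-number ratio.

    Starts from the alternating string [1, 0, 1, 0, ...] and flips randomly
    chosen positions until the count of 1s equals round(n * ratio/(1+ratio)).
    """
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if n < 2 or n % 2:
        raise ValueError("n must be even and >= 2")
    alleles = [1, 0] * (n // 2)
    k = _target_ones(n, ratio)
    ones = n // 2
    if k < ones:
        idx = [i for i, a in enumerate(alleles) if a == 1]
        for i in rng.sample(idx, ones - k):
            alleles[i] = 0
    elif k > ones:
        idx = [i for i, a in enumerate(alleles) if a == 0]
        for i in rng.sample(idx, k - ones):
            alleles[i] = 1
    return NucleoidCell(alleles=alleles, divisions_done=0)


def growth_rate_ratio(h: float, g_other: float) -> float:
    """Linear interpolation of relative growth rate between 1 (h=0) and g_other (h=1)."""
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"h must be in [0, 1], got {h}")
    return 1.0 + (g_other - 1.0) * h


def division_probability(g: float) -> float:
    """Probability of dividing within one reference doubling time: clamp(2^g - 1, 0, 1)."""
    if g <= 0:
        raise ValueError(f"g must be > 0, got {g}")
    return min(max(2.0 ** g - 1.0, 0.0), 1.0)


# ---------------------------------------------------------------------------
# division mechanics


def _split_alleles(
    alleles: list[int], nspl: int, rng: random.Random
) -> tuple[list[int], list[int]]:
    """Cut the string at nspl distinct internal boundaries and coin-assign segments.

    Re-draws the coin pattern if either side would receive zero nucleoids.
    Returns (mother, daughter) segment concatenations, un-replenished.
    """
    n = len(alleles)
    cuts = sorted(rng.sample(range(1, n), nspl))
    bounds = [0, *cuts, n]
    nseg = nspl + 1
    full = (1 << nseg) - 1
    while True:
        coins = rng.getrandbits(nseg)
        if coins != 0 and coins != full:
            break
    mother: list[int] = []
    daughter: list[int] = []
    for i in range(nseg):
        seg = alleles[bounds[i]:bounds[i + 1]]
        if (coins >> i) & 1:
            mother.extend(seg)
        else:
            daughter.extend(seg)
    return mother, daughter


def _replenish(child: list[int], parent: list[int], rng: random.Random) -> None:
    """Top the child up to the parental copy number by duplication.

    Each new copy is templated from a uniformly chosen parental nucleoid and
    inserted at a uniformly chosen position in the child string.  Templating
    from the parent keeps E[h_child] exactly equal to the parent's h.
    """
    n = len(parent)
    randrange = rng.randrange
    insert = child.insert
    size = len(child)
    while size < n:
        insert(randrange(size + 1), parent[randrange(n)])
        size += 1


def _divide_alleles(
    alleles: list[int], nspl: int, rng: random.Random
) -> tuple[list[int], list[int]]:
    mother, daughter = _split_alleles(alleles, nspl, rng)
    _replenish(mother, alleles, rng)
    _replenish(daughter, alleles, rng)
    return mother, daughter


def divide_cell(
    cell: NucleoidCell, nspl: int, rng: random.Random, ndau: int | None = None
) -> tuple[NucleoidCell, NucleoidCell]:
    """Divide one cell into (mother, daughter).

    The mother's division counter increments; the daughter starts at zero.
    Raises if the cell has exhausted its replicative lifespan (``ndau``).
    """
    if ndau is not None and cell.divisions_done >= ndau:
        raise ValueError(
            f"cell is post-replicative ({cell.divisions_done} >= ndau={ndau})"
        )
    m, d = _divide_alleles(cell.alleles, nspl, rng)
    return (
        NucleoidCell(alleles=m, divisions_done=cell.divisions_done + 1),
        NucleoidCell(alleles=d, divisions_done=0),
    )


# ---------------------------------------------------------------------------
# population engine

# The generation loop is compiled with numba: at the default problem size one
# run grows 30 founders to ~half a million cells, each division running the
# cut/assign/replenish kernel, which is far too slow in interpreted Python.
# The compiled kernel implements exactly the mechanics of divide_cell above
# (tests cross-check the two paths statistically).

from numba import njit  # noqa: E402

# The kernel uses an inlined xorshift64* generator instead of numba's numpy
# RNG: a division consumes ~50 bounded draws and the call overhead of the
# library generator dominated the runtime.  Bounded draws use the multiply-
# shift trick on the top 32 output bits (bias < 2^-22 for the ranges here).
_XORSHIFT_MULT = np.uint64(0x2545F4914F6CDD1D)
_U32 = np.uint64(32)


@njit(inline="always")
def _prng_next(state):  # pragma: no cover
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * _XORSHIFT_MULT


@njit(inline="always")
def _rand_below(state, k):  # pragma: no cover
    """Uniform integer in [0, k) from the top 32 bits of the stream."""
    return int(((_prng_next(state) >> _U32) * np.uint64(k)) >> _U32)


@njit(inline="always")
def _rand_unit(state):  # pragma: no cover
    return float(_prng_next(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _run_kernel(seed, n, ratio, g_other, ngen, ndau, nspl, n_founders):  # pragma: no cover
    # seed the stream through a splitmix64 scramble so nearby seeds decorrelate
    state = np.empty(1, np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    state[0] = z

    cap = n_founders * (1 << ngen)
    pop = np.empty((cap, n), np.uint8)
    dd = np.zeros(cap, np.int64)
    ones_of = np.empty(cap, np.int64)

    # founders: alternating string, then random flips to the target ones count
    k_target = int(n * ratio / (1.0 + ratio) + 0.5)
    for f in range(n_founders):
        for j in range(n):
            pop[f, j] = 1 - (j & 1)
        ones = n // 2
        while ones > k_target:
            j = _rand_below(state, n)
            if pop[f, j] == 1:
                pop[f, j] = 0
                ones -= 1
        while ones < k_target:
            j = _rand_below(state, n)
            if pop[f, j] == 0:
                pop[f, j] = 1
                ones += 1
        ones_of[f] = k_target
    count = n_founders

    nseg = nspl + 1
    coin_cap = (1 << nseg) - 2  # valid patterns: 1 .. 2^nseg - 2 (both sides non-empty)
    cuts = np.empty(nspl, np.int64)
    positions = np.empty(n - 1, np.int64)
    parent = np.empty(n, np.uint8)
    mother = np.empty(n, np.uint8)
    daughter = np.empty(n, np.uint8)

    for _gen in range(ngen):
        m_cells = count
        for i in range(m_cells):
            if dd[i] >= ndau:
                continue
            h = ones_of[i] / n
            g = 1.0 + (g_other - 1.0) * h
            p = 2.0 ** g - 1.0
            if p < 1.0 and _rand_unit(state) >= p:
                continue

            # homoplasmic parents beget identical homoplasmic children: the
            # cut/replenish machinery is a no-op on an all-0 or all-1 string
            if ones_of[i] == 0 or ones_of[i] == n:
                for j in range(n):
                    pop[count, j] = pop[i, j]
                ones_of[count] = ones_of[i]
                dd[i] += 1
                dd[count] = 0
                count += 1
                continue

            for j in range(n):
                parent[j] = pop[i, j]

            # nspl distinct internal cut boundaries via partial Fisher-Yates
            for j in range(n - 1):
                positions[j] = j + 1
            for j in range(nspl):
                r = j + _rand_below(state, n - 1 - j)
                tmp = positions[j]
                positions[j] = positions[r]
                positions[r] = tmp
                cuts[j] = positions[j]
            cuts.sort()

            # one bounded draw yields the conditioned coin pattern directly:
            # uniform over the 2^nseg - 2 patterns with both cells non-empty
            coins = 1 + _rand_below(state, coin_cap)

            sm = 0
            sd_ = 0
            m_ones = 0
            d_ones = 0
            seg = 0
            for j in range(n):
                if seg < nspl and j == cuts[seg]:
                    seg += 1
                if (coins >> seg) & 1:
                    mother[sm] = parent[j]
                    m_ones += parent[j]
                    sm += 1
                else:
                    daughter[sd_] = parent[j]
                    d_ones += parent[j]
                    sd_ += 1

            # replenish both children to n: duplicates templated from the
            # parental string, inserted at a random position in the child
            while sm < n:
                pos = _rand_below(state, sm + 1)
                for j in range(sm, pos, -1):
                    mother[j] = mother[j - 1]
                t = parent[_rand_below(state, n)]
                mother[pos] = t
                m_ones += t
                sm += 1
            while sd_ < n:
                pos = _rand_below(state, sd_ + 1)
                for j in range(sd_, pos, -1):
                    daughter[j] = daughter[j - 1]
                t = parent[_rand_below(state, n)]
                daughter[pos] = t
                d_ones += t
                sd_ += 1

            for j in range(n):
                pop[i, j] = mother[j]
                pop[count, j] = daughter[j]
            ones_of[i] = m_ones
            ones_of[count] = d_ones
            dd[i] += 1
            dd[count] = 0
            count += 1

    total_h = 0.0
    for i in range(count):
        total_h += ones_of[i] / n
    return total_h / count, count


def _simulate_once(config: SimConfig, seed: int) -> tuple[float, int]:
    """One full run via the compiled kernel: (population mean h, final cell count)."""
    if config.ngen > 24:
        raise ValueError("ngen > 24 would exceed the preallocated population capacity")
    mean_h, total = _run_kernel(
        int(seed) % (1 << 32),
        config.n_nucleoids,
        config.ratio,
        config.g_other,
        config.ngen,
        config.ndau,
        config.nspl,
        config.n_founders,
    )
    return float(mean_h), int(total)


def _simulate_once_python(config: SimConfig, seed: int) -> tuple[float, int]:
    """Reference interpreted implementation of the same model (small sizes only)."""
    rng = random.Random(seed)
    n = config.n_nucleoids
    cells: list[tuple[list[int], int]] = []
    for _ in range(config.n_founders):
        cells.append((init_founder(n, config.ratio, rng).alleles, 0))
    for _ in range(config.ngen):
        born: list[tuple[list[int], int]] = []
        for idx, (alleles, dd) in enumerate(cells):
            if dd >= config.ndau:
                continue
            h = sum(alleles) / n
            p = division_probability(growth_rate_ratio(h, config.g_other))
            if p >= 1.0 or rng.random() < p:
                mother, daughter = _divide_alleles(alleles, config.nspl, rng)
                cells[idx] = (mother, dd + 1)
                born.append((daughter, 0))
        cells.extend(born)
    mean_h = sum(sum(a) for a, _ in cells) / (n * len(cells))
    return mean_h, len(cells)


def simulate_population(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run a single simulation (one run of ``n_founders`` independent founders)."""
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    mean_h, total = _simulate_once(config, seed)
    return SimResult(
        mean_h=np.array([mean_h]),
        final_cells=np.array([total]),
        config=replace(config, n_runs=1, seed=seed),
    )


def run_replicates(config: SimConfig) -> SimResult:
    """Run ``config.n_runs`` independent seeded simulations."""
    master = config.seed if config.seed is not None else 0
    seeds = np.random.SeedSequence(master).generate_state(config.n_runs, dtype=np.uint32)
    means = np.empty(config.n_runs)
    cells = np.empty(config.n_runs, dtype=np.int64)
    for i, s in enumerate(seeds):
        means[i], cells[i] = _simulate_once(config, int(s))
    return SimResult(mean_h=means, final_cells=cells, config=config)


# ---------------------------------------------------------------------------
# ratio sweep


def _default_ratio_grid() -> np.ndarray:
    return np.round(np.arange(0.10, 1.0001, 0.05), 2)


@dataclass
class SweepResult:
    """Distributions of mean_h across a grid of founding mtDNA ratios."""

    ratios: np.ndarray
    mean_h: dict[float, np.ndarray] = field(repr=False)

    def mean_per_ratio(self) -> np.ndarray:
        return np.array([np.mean(self.mean_h[r]) for r in self.ratios])

    def best_match(self, observed_fraction: float) -> float:
        """Grid ratio whose mean simulated variant fraction is closest to the
        observed dark-cell fraction (ties resolved toward the lower ratio)."""
        means = self.mean_per_ratio()
        return float(self.ratios[int(np.argmin(np.abs(means - observed_fraction)))])

    def to_frame(self):
        import pandas as pd

        rows = [
            {"ratio": float(r), "run": i, "mean_h": float(v)}
            for r in self.ratios
            for i, v in enumerate(self.mean_h[float(r)])
        ]
        return pd.DataFrame(rows)


def sweep_ratios(
    config: SimConfig,
    ratios: Sequence[float] | None = None,
    n_runs_per_ratio: int = 10,
) -> SweepResult:
    """Repeat the simulation across a grid of founding ratios (default 0.10-1.00, step 0.05)."""
    grid = _default_ratio_grid() if ratios is None else np.asarray(list(ratios), dtype=float)
    if grid.size == 0:
        raise ValueError("ratio grid must not be empty")
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("all ratios must be in (0, 1]")
    master = config.seed if config.seed is not None else 0
    child_seeds = np.random.SeedSequence(master).spawn(len(grid))
    out: dict[float, np.ndarray] = {}
    for r, ss in zip(grid, child_seeds):
        cfg = replace(config, ratio=float(r), n_runs=n_runs_per_ratio)
        seeds = ss.generate_state(n_runs_per_ratio, dtype=np.uint32)
        vals = np.array([_simulate_once(cfg, int(s))[0] for s in seeds])
        out[float(r)] = vals
    return SweepResult(ratios=grid, mean_h=out)
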