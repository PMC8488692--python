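"""Forward-in-time neutral drift simulation for a bottlenecked population.

The model is a discrete-generation Wright-Fisher resampling scheme layered
on a deterministic logistic recovery of census size.  A small founding
population (optionally forced to contain exactly one heterozygote, so the
mutant starts at p0 = 1/(copies_per_individual * N0)) recovers toward
carrying capacity K at per-generation growth rate r; each generation the
next gamete pool of ``copies_per_individual * N`` gene copies is drawn
binomially from the current mutant frequency.  Two study designs are
supported:

* bottleneck grids — P(final frequency >= threshold) over founding size x
  generations, the drift explanation for a locally common mutant allele;
* fixation runs — time until either allele absorbs, with optional
  "genetic rescue": a fixed number of wild-type migrant gene copies joins
  the parental pool every generation, diluting the mutant frequency to
  p * c / (c + m) before offspring sampling.

Exact absorbing-Markov-chain oracles (constant-size and time-inhomogeneous
growth chains) are included for validating the stochastic simulator; they
are dense linear-algebra computations feasible for the pool sizes used
here (tens to a few hundred copies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DriftParams",
    "Trajectory",
    "ProbabilityGrid",
    "FixationSummary",
    "OracleResult",
    "logistic_step",
    "next_generation",
    "founder_frequency",
    "population_sizes",
    "simulate_bottleneck",
    "probability_grid",
    "simulate_to_fixation",
    "markov_oracle",
    "markov_oracle_growth",
]


@dataclass
class DriftParams:
    """Parameters for the drift simulations.

    n0 : founding population size (individuals).
    copies_per_individual : gene copies per individual in the gamete pool
        (2 for the diploid bottleneck grids; 1 reproduces a pool equal to
        the census size, the convention used for the fixation runs).
    generations : simulation horizon for bottleneck runs.
    r : per-generation logistic growth rate (0 disables growth).
    K : carrying capacity (individuals).
    reps : replicate count.
    founder_mode : "forced_het" (one heterozygote among the founders) or
        "sampled" (founder copies drawn binomially from p_source).
    threshold : frequency cutoff for the probability grid.
    migrant_copies_per_gen : wild-type gene copies added to the parental
        pool each generation (2 = one wild-type homozygous migrant).
    """

    n0: int = 2
    copies_per_individual: int = 2
    generations: int = 44
    r: float = 0.15
    K: int = 104
    reps: int = 1000
    founder_mode: str = "forced_het"
    p_source: float | None = None
    threshold: float = 0.5
    migrant_copies_per_gen: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.copies_per_individual not in (1, 2):
            raise ValueError("copies_per_individual must be 1 or 2")
        if self.r < 0:
            raise ValueError("growth rate r must be >= 0")
        if self.r > 0 and self.K < self.n0:
            raise ValueError("carrying capacity K must be >= n0 when growing")
        if self.founder_mode not in ("forced_het", "sampled"):
            raise ValueError(f"unknown founder_mode {self.founder_mode!r}")
        if self.p_source is not None and not 0 <= self.p_source <= 1:
            raise ValueError("p_source must lie in [0, 1]")
        if self.migrant_copies_per_gen < 0:
            raise ValueError("migrant_copies_per_gen must be >= 0")


@dataclass
class Trajectory:
    """One replicate: census sizes and mutant frequencies per generation."""

    sizes: np.ndarray
    freqs: np.ndarray


@dataclass
class ProbabilityGrid:
    """P(final frequency >= threshold) over founding size x generations."""

    n0_values: np.ndarray
    generations: np.ndarray
    probs: np.ndarray  # shape (len(n0_values), len(generations))
    reps: int
    threshold: float

    def to_frame(self):
        import pandas as pd

        rows = [
            (int(n0), int(g), float(self.probs[i, j]), self.reps)
            for i, n0 in enumerate(self.n0_values)
            for j, g in enumerate(self.generations)
        ]
        return pd.DataFrame(rows, columns=["n0", "generations", "prob", "reps"])


@dataclass
class FixationSummary:
    """Per-replicate absorption outcomes plus summary statistics."""

    absorbed_gen: np.ndarray  # generation of absorption, -1 if capped
    fixed_mutant: np.ndarray  # True where the mutant allele fixed
    capped: np.ndarray

    @property
    def n_capped(self) -> int:
        return int(self.capped.sum())

    def _done(self) -> np.ndarray:
        return self.absorbed_gen[~self.capped]

    @property
    def mean_time(self) -> float:
        return float(self._done().mean())

    @property
    def sd_time(self) -> float:
        return float(self._done().std(ddof=1))

    @property
    def se_time(self) -> float:
        d = self._done()
        return float(d.std(ddof=1) / math.sqrt(len(d)))

    @property
    def prop_fixed_mutant(self) -> float:
        """Fraction of uncapped replicates in which the mutant fixed."""
        return float(self.fixed_mutant[~self.capped].mean())

    def mean_time_conditional(self, mutant: bool) -> float:
        mask = ~self.capped & (self.fixed_mutant == mutant)
        return float(self.absorbed_gen[mask].mean())


@dataclass
class OracleResult:
    fix_prob_mutant: float
    expected_time: float


# ---------------------------------------------------------------- primitives


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def logistic_step(n: float, r: float, K: float) -> int:
    """One generation of logistic growth, rounded to integers with a floor of 1.

    n' = round(n + r*n*(1 - n/K)); K is a fixed point.  Rounding is
    half-away-from-zero so that e.g. 11.5 -> 12 regardless of parity.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if K <= 0:
        raise ValueError("carrying capacity must be positive")
    grown = n + r * n * (1 - n / K)
    return max(1, math.floor(grown + 0.5))


def next_generation(p: float, n_copies: int, rng) -> int:
    """Binomial(n_copies, p) mutant copies in the next gamete pool."""
    if not 0 <= p <= 1:
        raise ValueError("frequency must lie in [0, 1]")
    if n_copies < 1:
        raise ValueError("pool must contain at least one copy")
    return int(_as_rng(rng).binomial(n_copies, p))


def founder_frequency(params: DriftParams, rng=None) -> float:
    """Initial mutant frequency in the founding gamete pool."""
    pool = params.copies_per_individual * params.n0
    if params.founder_mode == "forced_het":
        return 1.0 / pool
    if params.p_source is None:
        raise ValueError("sampled founder mode requires p_source")
    return float(_as_rng(rng).binomial(pool, params.p_source)) / pool


def population_sizes(n0: int, r: float, K: float, generations: int) -> np.ndarray:
    """Deterministic census-size trajectory (length generations + 1)."""
    sizes = np.empty(generations + 1, dtype=int)
    sizes[0] = n = n0
    for g in range(1, generations + 1):
        if r > 0:
            n = logistic_step(n, r, K)
        sizes[g] = n
    return sizes


# ------------------------------------------------------------- bottleneck grid


def _bottleneck_final_counts(params: DriftParams, rng) -> tuple[np.ndarray, int]:
    """Vectorized final mutant copy counts over params.reps replicates."""
    rng = _as_rng(rng)
    cpi = params.copies_per_individual
    sizes = population_sizes(params.n0, params.r, params.K, params.generations)
    pools = np.maximum(1, cpi * sizes)
    if params.founder_mode == "forced_het":
        counts = np.full(params.reps, 1, dtype=np.int64)
    else:
        if params.p_source is None:
            raise ValueError("sampled founder mode requires p_source")
        counts = rng.binomial(pools[0], params.p_source, size=params.reps)
    for g in range(1, len(pools)):
        counts = rng.binomial(pools[g], counts / pools[g - 1])
    return counts, int(pools[-1])


def simulate_bottleneck(params: DriftParams, rng=None) -> Trajectory:
    """One replicate trajectory of the bottleneck-and-recovery simulation."""
    if params.migrant_copies_per_gen != 0:
        raise ValueError("bottleneck simulation is migration-free")
    rng = _as_rng(params.seed if rng is None else rng)
    cpi = params.copies_per_individual
    sizes = population_sizes(params.n0, params.r, params.K, params.generations)
    pools = np.maximum(1, cpi * sizes)
    freqs = np.empty(len(sizes))
    if params.founder_mode == "forced_het":
        count = 1
    else:
        if params.p_source is None:
            raise ValueError("sampled founder mode requires p_source")
        count = int(rng.binomial(pools[0], params.p_source))
    freqs[0] = count / pools[0]
    for g in range(1, len(sizes)):
        count = int(rng.binomial(pools[g], count / pools[g - 1]))
        freqs[g] = count / pools[g]
    return Trajectory(sizes=sizes, freqs=freqs)


def probability_grid(
    n0_range,
    g_range,
    params: DriftParams | None = None,
    threshold: float | None = None,
) -> ProbabilityGrid:
    """P(final frequency >= threshold) per (founding size, generations) cell.

    Cells are simulated independently with dedicated RNG substreams keyed
    by (n0, generations), so the grid is reproducible cell-by-cell for a
    fixed ``params.seed`` regardless of evaluation order.
    """
    params = params or DriftParams()
    thr = params.threshold if threshold is None else threshold
    n0_values = np.asarray(sorted(n0_range), dtype=int)
    gens = np.asarray(sorted(g_range), dtype=int)
    if n0_values.size == 0 or gens.size == 0:
        raise ValueError("grid ranges must be non-empty")
    probs = np.empty((n0_values.size, gens.size))
    for i, n0 in enumerate(n0_values):
        for j, g in enumerate(gens):
            cell = replace(params, n0=int(n0), generations=int(g))
            ss = np.random.SeedSequence(
                params.seed if params.seed is not None else 0,
                spawn_key=(int(n0), int(g)),
            )
            counts, pool = _bottleneck_final_counts(cell, np.random.default_rng(ss))
            probs[i, j] = np.mean(counts / pool >= thr)
    return ProbabilityGrid(n0_values, gens, probs, params.reps, thr)


# ------------------------------------------------------------- fixation runs


def simulate_to_fixation(
    params: DriftParams,
    p0: float = 0.5,
    rng=None,
    max_generations: int = 100_000,
) -> FixationSummary:
    """Run replicates until one allele absorbs (or a generation cap).

    Starts from mutant frequency ``p0`` in a pool of
    ``copies_per_individual * n0`` copies.  Without migration both
    boundaries absorb; with migrant wild-type copies the mutant can only be
    lost, and the wild-type "fixes" when that happens.  Replicates still
    segregating at ``max_generations`` are reported as capped.
    """
    if params.reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    rng = _as_rng(params.seed if rng is None else rng)
    cpi = params.copies_per_individual
    mig = params.migrant_copies_per_gen
    pool = cpi * params.n0
    if mig > pool:
        raise ValueError("migrant copies exceed the gamete pool")
    grow = params.r > 0
    n = params.n0
    counts = np.full(params.reps, int(round(p0 * pool)), dtype=np.int64)
    absorbed = np.full(params.reps, -1, dtype=np.int64)
    fixed_mut = np.zeros(params.reps, dtype=bool)
    active = np.ones(params.reps, dtype=bool)
    # immediate absorption at g = 0
    done0 = (counts == 0) | ((counts == pool) & (mig == 0))
    absorbed[done0] = 0
    fixed_mut[done0] = counts[done0] == pool
    active[done0] = False
    g = 0
    while active.any() and g < max_generations:
        g += 1
        if grow:
            n = logistic_step(n, params.r, params.K)
        newpool = max(1, cpi * n)
        p = counts[active] / pool
        if mig:
            p = p * pool / (pool + mig)
        counts[active] = rng.binomial(newpool, p)
        pool = newpool
        if mig:
            done = counts[active] == 0
        else:
            done = (counts[active] == 0) | (counts[active] == pool)
        idx = np.flatnonzero(active)[done]
        absorbed[idx] = g
        fixed_mut[idx] = counts[idx] == pool
        active[idx] = False
    return FixationSummary(
        absorbed_gen=absorbed, fixed_mutant=fixed_mut, capped=active.copy()
    )


# ------------------------------------------------------------ exact oracles


def _transition_matrix(n_copies: int, migrant_copies: int) -> np.ndarray:
    states = np.arange(n_copies + 1)
    p_eff = states / (n_copies + migrant_copies)
    return stats.binom.pmf(states[None, :], n_copies, p_eff[:, None])


def _state_from_p0(p0: float, n_copies: int) -> int:
    s = p0 * n_copies
    if abs(s - round(s)) > 1e-9:
        raise ValueError(f"p0={p0} is not a copy count over {n_copies} copies")
    return int(round(s))


def markov_oracle(
    n_copies: int, p0: float, migrant_copies: int = 0
) -> OracleResult:
    """Exact fixation probability and expected absorption time.

    Solves the absorbing-chain linear systems for the binomial
    transition matrix over copy counts 0..n_copies.  With migrant
    wild-type copies the only absorbing state is loss of the mutant.
    """
    if n_copies > 200:
        raise ValueError("oracle limited to pools of <= 200 copies")
    if n_copies < 1:
        raise ValueError("pool must contain at least one copy")
    if migrant_copies < 0:
        raise ValueError("migrant_copies must be >= 0")
    P = _transition_matrix(n_copies, migrant_copies)
    absorbing = [0] + ([n_copies] if migrant_copies == 0 else [])
    trans = [s for s in range(n_copies + 1) if s not in absorbing]
    s0 = _state_from_p0(p0, n_copies)
    if s0 in absorbing:
        return OracleResult(float(s0 == n_copies and migrant_copies == 0), 0.0)
    Q = P[np.ix_(trans, trans)]
    M = np.eye(len(trans)) - Q
    if np.linalg.matrix_rank(M) < len(trans):  # pragma: no cover - degenerate
        raise ValueError("chain is not absorbing for these parameters")
    t = np.linalg.solve(M, np.ones(len(trans)))
    if migrant_copies == 0:
        h = np.linalg.solve(M, P[trans, n_copies])
        fix = float(h[trans.index(s0)])
    else:
        fix = 0.0
    return OracleResult(fix_prob_mutant=fix, expected_time=float(t[trans.index(s0)]))


def markov_oracle_growth(
    params: DriftParams, p0: float = 0.5
) -> OracleResult:
    """Exact absorption quantities for the logistically growing chain.

    The census trajectory is deterministic, so the chain is
    time-inhomogeneous only during the growth phase; once the pool reaches
    its fixed point the homogeneous solution applies and expected times /
    fixation probabilities are backward-propagated through the growth
    generations.
    """
    cpi = params.copies_per_individual
    mig = params.migrant_copies_per_gen
    # grow until the census size stops changing (K is a fixed point)
    sizes = [params.n0]
    while True:
        nxt = logistic_step(sizes[-1], params.r, params.K) if params.r > 0 else sizes[-1]
        if nxt == sizes[-1]:
            break
        sizes.append(nxt)
    pools = [max(1, cpi * s) for s in sizes]
    final_pool = pools[-1]
    if final_pool > 200:
        raise ValueError("oracle limited to pools of <= 200 copies")

    def absorbing_mask(pool: int) -> np.ndarray:
        m = np.zeros(pool + 1, dtype=bool)
        m[0] = True
        if mig == 0:
            m[pool] = True
        return m

    # homogeneous tail at the final pool size
    Pf = _transition_matrix(final_pool, mig)
    maskf = absorbing_mask(final_pool)
    trans = np.flatnonzero(~maskf)
    Q = Pf[np.ix_(trans, trans)]
    M = np.eye(len(trans)) - Q
    t_inf = np.zeros(final_pool + 1)
    t_inf[trans] = np.linalg.solve(M, np.ones(len(trans)))
    h_inf = np.zeros(final_pool + 1)
    if mig == 0:
        h_inf[final_pool] = 1.0
        h_inf[trans] = np.linalg.solve(M, Pf[trans, final_pool])

    T_next, H_next = t_inf, h_inf
    # backward induction through the growth phase
    for g in range(len(pools) - 2, -1, -1):
        c, c_next = pools[g], pools[g + 1]
        states = np.arange(c + 1)
        p_eff = states / (c + mig)
        P = stats.binom.pmf(np.arange(c_next + 1)[None, :], c_next, p_eff[:, None])
        mask = absorbing_mask(c)
        T = np.zeros(c + 1)
        H = np.zeros(c + 1)
        if mig == 0:
            H[c] = 1.0
        live = ~mask
        T[live] = 1.0 + P[live] @ T_next
        H[live] = P[live] @ H_next
        T_next, H_next = T, H
    s0 = _state_from_p0(p0, pools[0])
    return OracleResult(fix_prob_mutant=float(H_next[s0]), expected_time=float(T_next[s0]))
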