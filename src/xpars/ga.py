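"""Evolutionary operators over chart blocks: AUROC fitness, roulette
selection, validity-preserving splice crossover, ±1 mutation with monotone
repair, and the elitist per-block generational loop.

Fitness is *global*: a candidate chromosome is scored by the AUROC of the
whole chart with the candidate substituted into its block, so blocks holding
more people move the objective more.  Because every person's score is one of
the ``n_levels`` ordinal levels, the AUROC reduces to per-level positive /
negative histograms; :class:`FitnessContext` keeps chart-wide histograms and
re-derives a candidate's fitness from the block's (row, col) event counts in
O(cells) instead of O(cohort).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .chart import (
    Cohort,
    RiskChart,
    StructuralError,
    ChartError,
    is_valid,
    repair_chromosome,
)

__all__ = [
    "GAParams",
    "UndefinedFitnessError",
    "fitness_auroc",
    "FitnessContext",
    "roulette_select",
    "enumerate_splice_children",
    "crossover",
    "mutate",
    "evolve_block",
]


class UndefinedFitnessError(ChartError):
    """AUROC is undefined: the labels contain a single class."""


@dataclass
class GAParams:
    """Hyperparameters of the per-block genetic search.

    population_size : number of chromosomes per generation (>= 2).
    generations : maximum generations per block visit.
    stall_limit : stop after this many generations without improvement.
    mutation_prob : per-child probability of one ±1 gene mutation.
    include_incumbent : seed the population with the block's current
        chromosome, guaranteeing the returned solution never scores below it.
    weight_offset : if True, roulette weights use fitness − 0.5 (floored at
        1e-6) instead of raw AUROC, sharpening selection pressure around the
        chance baseline.
    """

    population_size: int = 20
    generations: int = 50
    stall_limit: int = 10
    mutation_prob: float = 1.0
    include_incumbent: bool = True
    weight_offset: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def fitness_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUROC: P(score of a random case > score of a random
    non-case), ties counted half.  Computed from midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedFitnessError(
            f"AUROC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auroc_from_hists(hist_pos: np.ndarray, hist_neg: np.ndarray) -> float:
    """AUROC when scores take the few ordinal level values whose per-class
    counts are given (level order = ascending score)."""
    n_pos = hist_pos.sum()
    n_neg = hist_neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise UndefinedFitnessError("single-class cohort")
    neg_below = np.concatenate(([0.0], np.cumsum(hist_neg)[:-1]))
    u = float(np.dot(hist_pos, neg_below + 0.5 * hist_neg))
    return u / float(n_pos * n_neg)


class FitnessContext:
    """Global-AUROC fitness of candidate chromosomes for one block.

    Holds the working chart, per-block positive/negative event-count matrices
    over (BP row, cholesterol column) cells, and the chart-wide per-level
    score histograms.  ``set_block`` switches the block under optimization;
    ``commit`` writes an accepted chromosome back into the working chart.
    """

    def __init__(self, chart: RiskChart, cohort: Cohort):
        if chart.spec is not cohort.spec and chart.spec != cohort.spec:
            raise StructuralError("chart and cohort use different specs")
        self.chart = chart
        self.cohort = cohort
        self.n_levels = chart.spec.n_levels
        block_id, row, col, self.keys = cohort.indexers()
        nb = len(self.keys)
        nr, nc = chart.spec.block_shape
        y = cohort.outcome
        flat = (block_id * nr + row) * nc + col
        self.pos_counts = np.bincount(
            flat[y == 1], minlength=nb * nr * nc
        ).reshape(nb, nr, nc).astype(float)
        self.neg_counts = np.bincount(
            flat[y == 0], minlength=nb * nr * nc
        ).reshape(nb, nr, nc).astype(float)
        self._key_index = {k: i for i, k in enumerate(self.keys)}
        self._rebuild_histograms()
        self.block_key: Optional[tuple[str, ...]] = None
        self._cache: dict[bytes, float] = {}

    def _block_hists(self, b: int, genes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lv = np.asarray(genes).ravel() - 1
        hp = np.bincount(lv, weights=self.pos_counts[b].ravel(),
                         minlength=self.n_levels)
        hn = np.bincount(lv, weights=self.neg_counts[b].ravel(),
                         minlength=self.n_levels)
        return hp, hn

    def _rebuild_histograms(self) -> None:
        self.hist_pos = np.zeros(self.n_levels)
        self.hist_neg = np.zeros(self.n_levels)
        for b, key in enumerate(self.keys):
            hp, hn = self._block_hists(b, self.chart.blocks[key])
            self.hist_pos += hp
            self.hist_neg += hn

    # -- public API ---------------------------------------------------------
    def block_n(self, key: tuple[str, ...]) -> int:
        b = self._key_index[key]
        return int(self.pos_counts[b].sum() + self.neg_counts[b].sum())

    def chart_auroc(self) -> float:
        """Training AUROC of the working chart as it currently stands."""
        return _auroc_from_hists(self.hist_pos, self.hist_neg)

    def set_block(self, key: tuple[str, ...]) -> None:
        if key not in self._key_index:
            raise StructuralError(f"block key {key} not in chart")
        self.block_key = key
        b = self._key_index[key]
        hp, hn = self._block_hists(b, self.chart.blocks[key])
        self._rest_pos = self.hist_pos - hp
        self._rest_neg = self.hist_neg - hn
        self._cache = {}

    def fitness(self, candidate: np.ndarray) -> float:
        """AUROC of the chart with ``candidate`` substituted at the current
        block.  Identical to the chart AUROC when the candidate equals the
        incumbent; flat in the candidate when the block holds no records."""
        if self.block_key is None:
            raise StructuralError("set_block() must be called first")
        key = np.asarray(candidate, dtype=np.int64).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        b = self._key_index[self.block_key]
        hp, hn = self._block_hists(b, candidate)
        out = _auroc_from_hists(self._rest_pos + hp, self._rest_neg + hn)
        self._cache[key] = out
        return out

    def fitness_many(self, candidates: Sequence[np.ndarray]) -> np.ndarray:
        """Vectorized :meth:`fitness` over a pool of candidates."""
        if self.block_key is None:
            raise StructuralError("set_block() must be called first")
        out = np.empty(len(candidates))
        miss_idx, miss_keys, miss_levels = [], [], []
        for i, cand in enumerate(candidates):
            arr = np.asarray(cand, dtype=np.int64)
            key = arr.tobytes()
            hit = self._cache.get(key)
            if hit is None:
                miss_idx.append(i)
                miss_keys.append(key)
                miss_levels.append(arr.ravel() - 1)
            else:
                out[i] = hit
        if miss_idx:
            b = self._key_index[self.block_key]
            lv = np.stack(miss_levels)  # (m, cells)
            m = lv.shape[0]
            hp = np.zeros((m, self.n_levels))
            hn = np.zeros((m, self.n_levels))
            rows = np.repeat(np.arange(m), lv.shape[1])
            wp = np.tile(self.pos_counts[b].ravel(), m)
            wn = np.tile(self.neg_counts[b].ravel(), m)
            np.add.at(hp, (rows, lv.ravel()), wp)
            np.add.at(hn, (rows, lv.ravel()), wn)
            hp += self._rest_pos
            hn += self._rest_neg
            n_pos = hp.sum(axis=1)
            n_neg = hn.sum(axis=1)
            if np.any(n_pos == 0) or np.any(n_neg == 0):
                raise UndefinedFitnessError("single-class cohort")
            neg_below = np.cumsum(hn, axis=1) - hn
            u = np.sum(hp * (neg_below + 0.5 * hn), axis=1)
            vals = u / (n_pos * n_neg)
            for j, i in enumerate(miss_idx):
                out[i] = vals[j]
                self._cache[miss_keys[j]] = float(vals[j])
        return out

    def commit(self, genes: np.ndarray) -> None:
        """Replace the current block in the working chart."""
        b = self._key_index[self.block_key]
        hp_old, hn_old = self._block_hists(b, self.chart.blocks[self.block_key])
        hp_new, hn_new = self._block_hists(b, genes)
        self.hist_pos += hp_new - hp_old
        self.hist_neg += hn_new - hn_old
        self.chart.blocks[self.block_key] = np.asarray(genes, dtype=np.int64).copy()
        self._rest_pos = self.hist_pos - hp_new
        self._rest_neg = self.hist_neg - hn_new


# ---------------------------------------------------------------------------
# Selection, crossover, mutation
# ---------------------------------------------------------------------------

def roulette_select(items: Sequence, weights: Sequence[float], k: int,
                    rng: np.random.Generator) -> list:
    """Draw ``k`` distinct items, each draw with probability proportional to
    its weight among the remaining items.  All-zero (or degenerate) weights
    fall back to uniform sampling."""
    if k > len(items):
        raise ValueError(f"cannot draw {k} from {len(items)} items")
    w = np.asarray(weights, dtype=float).copy()
    if len(w) != len(items):
        raise ValueError("weights and items length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    alive = list(range(len(items)))
    chosen: list[int] = []
    for _ in range(k):
        ww = w[alive]
        total = ww.sum()
        if total <= 0:
            pick = int(rng.integers(len(alive)))
        else:
            # inverse-CDF draw on the remaining weights
            cum = np.cumsum(ww)
            pick = int(np.searchsorted(cum, rng.random() * total, side="right"))
            pick = min(pick, len(alive) - 1)
        chosen.append(alive.pop(pick))
    return [items[i] for i in chosen]


def enumerate_splice_children(parent_a: np.ndarray, parent_b: np.ndarray,
                              n_levels: int) -> list[np.ndarray]:
    """All valid, unique one-point splice offspring of two chromosomes.

    Both parents are linearized row-major (length L); for every cut point
    k = 1..L−1 the prefix of one parent is joined to the suffix of the other,
    in both orders, then invalid combinations are dropped and duplicates
    removed, preserving first-seen order.
    """
    a = np.asarray(parent_a, dtype=np.int64)
    b = np.asarray(parent_b, dtype=np.int64)
    if a.shape != b.shape:
        raise StructuralError(f"parent shapes differ: {a.shape} vs {b.shape}")
    fa, fb = a.ravel(), b.ravel()
    L = fa.size
    # all 2(L-1) splices at once: rows interleave (A-prefix|B-suffix, cut k)
    # and (B-prefix|A-suffix, cut k) for k = 1..L-1
    take_a = np.arange(L)[None, :] < np.arange(1, L)[:, None]
    cands = np.empty((2 * (L - 1), L), dtype=np.int64)
    cands[0::2] = np.where(take_a, fa, fb)
    cands[1::2] = np.where(take_a, fb, fa)
    grids = cands.reshape(-1, *a.shape)
    ok = (grids >= 1).all(axis=(1, 2)) & (grids <= n_levels).all(axis=(1, 2))
    if a.shape[0] > 1:
        ok &= (np.diff(grids, axis=1) >= 0).all(axis=(1, 2))
    if a.shape[1] > 1:
        ok &= (np.diff(grids, axis=2) >= 0).all(axis=(1, 2))
    seen: dict[bytes, np.ndarray] = {}
    for child in grids[ok]:
        seen.setdefault(child.tobytes(), child)
    return list(seen.values())


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              ctx: FitnessContext, rng: np.random.Generator,
              weight_offset: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Two children drawn from the splice pool by fitness-weighted roulette.

    A pool smaller than two is padded with copies of the fitter parent.
    """
    pool = enumerate_splice_children(parent_a, parent_b, ctx.n_levels)
    if len(pool) < 2:
        fit_a, fit_b = ctx.fitness(parent_a), ctx.fitness(parent_b)
        best = parent_a if fit_a >= fit_b else parent_b
        while len(pool) < 2:
            pool.append(best.copy())
    if len(pool) == 2:
        return pool[0].copy(), pool[1].copy()
    weights = ctx.fitness_many(pool)
    if weight_offset:
        weights = np.maximum(weights - 0.5, 1e-6)
    c1, c2 = roulette_select(pool, weights, 2, rng)
    return c1.copy(), c2.copy()


def mutate(genes: np.ndarray, rng: np.random.Generator,
           n_levels: int) -> np.ndarray:
    """Change one uniformly chosen gene by ±1 (equal probability), clamp to
    [1, n_levels], and repair monotonicity.  Always returns a valid matrix."""
    g = np.asarray(genes, dtype=np.int64).copy()
    nr, nc = g.shape
    idx = int(rng.integers(nr * nc))
    r, c = divmod(idx, nc)
    direction = 1 if rng.random() < 0.5 else -1
    new = g[r, c] + direction
    if new < 1 or new > n_levels:
        return g  # clamped: no change at a boundary level
    return repair_chromosome(g, (r, c), direction)


# ---------------------------------------------------------------------------
# Per-block generational loop
# ---------------------------------------------------------------------------

def evolve_block(
    ctx: FitnessContext,
    params: GAParams,
    init_population: Sequence[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float]]:
    """Run the elitist GA on the block currently selected in ``ctx``.

    Each generation pairs parents by roulette, splices each pair into a child
    pool, roulette-selects two children per pair, mutates them, and forms the
    next generation from the best individual so far (elitism) plus a seeded
    random fill from parents ∪ children.  Returns the best-ever chromosome and
    the per-generation best-ever fitness trace (non-decreasing).
    """
    if len(init_population) == 0:
        raise StructuralError("initial population is empty")
    pop = [np.asarray(p, dtype=np.int64).copy() for p in init_population]
    for p in pop:
        if not is_valid(p, ctx.n_levels):
            raise StructuralError("initial population contains invalid genes")

    fits = ctx.fitness_many(pop)
    best_i = int(np.argmax(fits))
    best, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = [best_fit]
    stall = 0
    for _ in range(params.generations):
        weights = fits - 0.5 if params.weight_offset else fits
        weights = np.maximum(weights, 1e-6)
        children: list[np.ndarray] = []
        for _ in range(max(1, len(pop) // 2)):
            pa, pb = roulette_select(pop, weights, 2, rng)
            c1, c2 = crossover(pa, pb, ctx, rng, params.weight_offset)
            for child in (c1, c2):
                if rng.random() < params.mutation_prob:
                    child = mutate(child, rng, ctx.n_levels)
                children.append(child)
        combined = pop + children
        comb_fits = np.concatenate([fits, ctx.fitness_many(children)])
        gen_best = int(np.argmax(comb_fits))
        improved = comb_fits[gen_best] > best_fit + 1e-15
        if improved:
            best, best_fit = combined[gen_best].copy(), float(comb_fits[gen_best])
            stall = 0
        else:
            stall += 1
        # elitist replacement: keep the generation's best, fill the rest at
        # random without replacement from parents and children
        rest = [i for i in range(len(combined)) if i != gen_best]
        fill = rng.choice(len(rest), size=min(params.population_size - 1,
                                              len(rest)), replace=False)
        next_idx = [gen_best] + [rest[i] for i in fill]
        pop = [combined[i] for i in next_idx]
        fits = comb_fits[next_idx]
        trace.append(best_fit)
        if stall >= params.stall_limit:
            break
    return best, trace
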