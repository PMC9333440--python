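"""Chart-level training: a statsmodels-style Model/Results pair.

:class:`ChartRiskModel` wraps a categorized cohort and a chart geometry;
``fit()`` initializes the chart from empirical cell event rates (or an
external chart), runs blockwise GA rounds ordered by block data size, applies
the ratio-based post-hoc modifier, and returns :class:`ChartRiskResults`
carrying the trained chart, the training history and prediction/summary
methods.  ``cross_validate()`` reports stratified 10-fold validation AUROC.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .chart import (
    ChartSpec,
    Cohort,
    InputError,
    RiskChart,
    cell_count,
    enforce_monotone,
    is_valid,
)
from .ga import FitnessContext, GAParams, evolve_block, fitness_auroc, mutate

__all__ = [
    "TrainHistory",
    "CVResult",
    "ChartRiskModel",
    "ChartRiskResults",
    "init_chart",
    "order_blocks",
    "train_chart",
    "posthoc_adjust",
    "stratified_folds",
    "cross_validate",
    "interpretability_score",
    "chart_auroc",
]


# ---------------------------------------------------------------------------
# History containers
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    """Per-block-update log of one training run.

    ``records`` holds (round, block key, block n, training AUROC after the
    update); with the incumbent included in every initial population the
    AUROC column is non-decreasing.
    """

    initial_auroc: float
    records: list[tuple[int, tuple[str, ...], int, float]] = field(
        default_factory=list
    )
    rounds_completed: int = 0
    final_auroc: float = float("nan")

    @property
    def auroc_trace(self) -> list[float]:
        return [self.initial_auroc] + [r[3] for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, "|".join(k), n, a) for r, k, n, a in self.records],
            columns=["round", "block", "n", "auroc"],
        )


@dataclass
class CVResult:
    """Stratified k-fold cross-validation summary."""

    fold_aurocs: list[float]
    seed: Optional[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aurocs))

    @property
    def k(self) -> int:
        return len(self.fold_aurocs)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _cell_counts(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, list]:
    block, row, col, keys = cohort.indexers()
    nr, nc = cohort.spec.block_shape
    flat = (block * nr + row) * nc + col
    size = len(keys) * nr * nc
    y = cohort.outcome
    pos = np.bincount(flat[y == 1], minlength=size).reshape(len(keys), nr, nc)
    tot = np.bincount(flat, minlength=size).reshape(len(keys), nr, nc)
    return pos, tot, keys


def _nearest_level(p: np.ndarray, midpoints: Sequence[float]) -> np.ndarray:
    mids = np.asarray(midpoints)
    return np.argmin(np.abs(p[..., None] - mids), axis=-1) + 1


def _monotone_round(levels: np.ndarray, weights: np.ndarray,
                    n_levels: int) -> np.ndarray:
    """Weighted isotonic smoothing (rows then columns) + validity sweep."""
    g = levels.astype(float)
    w = np.maximum(weights, 1.0).astype(float)
    for r in range(g.shape[0]):
        g[r] = isotonic_regression(g[r], weights=w[r]).x
    for c in range(g.shape[1]):
        g[:, c] = isotonic_regression(g[:, c], weights=w[:, c]).x
    return enforce_monotone(np.rint(g).astype(np.int64), n_levels)


def init_chart(
    cohort: Cohort,
    spec: Optional[ChartSpec] = None,
    strategy: str = "empirical",
    params: Optional[GAParams] = None,
    rng: Optional[np.random.Generator] = None,
    external_chart: Optional[RiskChart] = None,
) -> tuple[RiskChart, dict[tuple[str, ...], list[np.ndarray]]]:
    """Initial chart + per-block starting populations.

    ``empirical``: each covered cell's event proportion is mapped to the
    nearest band-midpoint level, empty cells inherit the block-mean level,
    and a weighted isotonic pass makes every block valid.  ``external``
    loads a user-supplied chart (e.g. a Cox-derived PARS-style chart) as the
    incumbent.  Populations are the incumbent plus seeded ±1-mutated
    variants, ``population_size`` members per block.
    """
    spec = spec or cohort.spec
    params = params or GAParams()
    rng = rng or np.random.default_rng(params.seed)

    if strategy == "external":
        if external_chart is None:
            raise InputError("external strategy requires external_chart")
        external_chart.validate()
        chart = external_chart.copy()
    elif strategy == "empirical":
        if cohort.n_events == 0:
            raise InputError("cannot initialize from a cohort with zero events")
        pos, tot, keys = _cell_counts(cohort)
        overall_level = int(
            _nearest_level(np.array(cohort.event_rate), spec.band_midpoints)
        )
        blocks = {}
        for b, key in enumerate(keys):
            covered = tot[b] > 0
            levels = np.full(spec.block_shape, overall_level, dtype=np.int64)
            if covered.any():
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(covered, pos[b] / np.maximum(tot[b], 1), 0.0)
                lv = _nearest_level(p, spec.band_midpoints)
                block_mean = int(np.rint(lv[covered].mean()))
                levels = np.where(covered, lv, block_mean)
            blocks[key] = _monotone_round(levels, tot[b], spec.n_levels)
        chart = RiskChart(spec, blocks)
    else:
        raise ValueError(f"unknown initialization strategy {strategy!r}")
    chart.validate()

    populations = {}
    for key in spec.stratum_keys():
        incumbent = chart.blocks[key]
        pop = [incumbent.copy()]
        while len(pop) < params.population_size:
            variant = incumbent.copy()
            for _ in range(int(rng.integers(1, 4))):
                variant = mutate(variant, rng, spec.n_levels)
            pop.append(variant)
        populations[key] = pop
    return chart, populations


def order_blocks(cohort: Cohort,
                 spec: Optional[ChartSpec] = None) -> list[tuple[str, ...]]:
    """Block keys by descending record count; empty blocks are excluded from
    training; ties break lexicographically."""
    spec = spec or cohort.spec
    _, tot, keys = _cell_counts(cohort)
    counts = tot.sum(axis=(1, 2))
    nonempty = [(int(-counts[b]), keys[b]) for b in range(len(keys))
                if counts[b] > 0]
    return [k for _, k in sorted(nonempty)]


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train_chart(
    cohort: Cohort,
    spec: Optional[ChartSpec] = None,
    ga_params: Optional[GAParams] = None,
    max_rounds: int = 2,
    tol: float = 0.001,
    strategy: str = "empirical",
    external_chart: Optional[RiskChart] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RiskChart, TrainHistory]:
    """Blockwise GA training of a full chart.

    Rounds visit every non-empty block in descending data-size order and
    replace it with the solution of :func:`evolve_block`; the loop stops when
    the round-over-round AUROC gain falls below ``tol`` or ``max_rounds`` is
    reached.
    """
    spec = spec or cohort.spec
    params = ga_params or GAParams()
    rng = rng or np.random.default_rng(params.seed)
    if cohort.n_events == 0 or cohort.n_events == cohort.n:
        raise InputError("training requires both outcome classes")

    chart, populations = init_chart(
        cohort, spec, strategy=strategy, params=params, rng=rng,
        external_chart=external_chart,
    )
    ctx = FitnessContext(chart, cohort)
    history = TrainHistory(initial_auroc=ctx.chart_auroc())
    order = order_blocks(cohort, spec)
    last_round_auroc = history.initial_auroc
    for rnd in range(1, max_rounds + 1):
        for key in order:
            ctx.set_block(key)
            incumbent = chart.blocks[key]
            init_pop = list(populations[key])
            if params.include_incumbent:
                init_pop = [incumbent.copy()] + [
                    p for p in init_pop if not np.array_equal(p, incumbent)
                ]
            init_pop = init_pop[: params.population_size]
            best, _ = evolve_block(ctx, params, init_pop, rng)
            ctx.commit(best)
            history.records.append(
                (rnd, key, ctx.block_n(key), ctx.chart_auroc())
            )
        history.rounds_completed = rnd
        round_auroc = ctx.chart_auroc()
        if round_auroc - last_round_auroc < tol:
            last_round_auroc = round_auroc
            break
        last_round_auroc = round_auroc
    history.final_auroc = last_round_auroc
    chart.validate()
    return chart, history


def posthoc_adjust(chart: RiskChart, cohort: Cohort) -> RiskChart:
    """Ratio-based modifier applied once after training.

    For every cell covering at least one training record, the gene is raised
    by one if the cell's positive-label ratio exceeds 50% and lowered by one
    otherwise, clamped to the level range; an adjustment that would break the
    block's monotonicity is skipped.  Empty cells are untouched.
    """
    out = chart.copy()
    pos, tot, keys = _cell_counts(cohort)
    n_levels = chart.spec.n_levels
    for b, key in enumerate(keys):
        genes = out.blocks[key]
        nr, nc = genes.shape
        for r in range(nr):
            for c in range(nc):
                if tot[b, r, c] == 0:
                    continue
                ratio = pos[b, r, c] / tot[b, r, c]
                delta = 1 if ratio > 0.5 else -1
                new = genes[r, c] + delta
                if new < 1 or new > n_levels:
                    continue
                trial = genes.copy()
                trial[r, c] = new
                if is_valid(trial, n_levels):
                    genes[r, c] = new
    out.validate()
    return out


def chart_auroc(chart: RiskChart, cohort: Cohort) -> float:
    """Training/validation AUROC of a chart on a categorized cohort."""
    block, row, col, keys = cohort.indexers()
    levels = np.stack([chart.blocks[k] for k in keys])[block, row, col]
    return fitness_auroc(levels, cohort.outcome)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(labels: Sequence[int], k: int,
                     seed: Optional[int] = None) -> np.ndarray:
    """Fold index per record: class-stratified, sizes within 1 of each other.

    Each class is shuffled with the seed, classes are concatenated and dealt
    cyclically, so per-class counts across folds also differ by at most one.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=np.int64)
    offset = 0
    for cls in sorted(np.unique(y)):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise InputError(
                f"class {cls} has {len(idx)} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        folds[idx] = (offset + np.arange(len(idx))) % k
        offset += len(idx)
    return folds


def cross_validate(
    cohort: Cohort,
    spec: Optional[ChartSpec] = None,
    ga_params: Optional[GAParams] = None,
    k: int = 10,
    seed: Optional[int] = None,
    max_rounds: int = 2,
    tol: float = 0.001,
    posthoc: bool = True,
) -> CVResult:
    """Stratified k-fold validation of the full training pipeline.

    Each fold re-initializes and re-trains on the remaining k−1 segments
    (post-hoc adjustment uses training data only) and is scored by AUROC on
    the held-out segment; the mean over folds is the headline number.
    """
    spec = spec or cohort.spec
    params = ga_params or GAParams()
    folds = stratified_folds(cohort.outcome, k, seed)
    child_seeds = np.random.SeedSequence(seed).spawn(k)
    aurocs = []
    for f in range(k):
        train = cohort.subset(np.flatnonzero(folds != f))
        test = cohort.subset(np.flatnonzero(folds == f))
        rng = np.random.default_rng(child_seeds[f])
        chart, _ = train_chart(
            train, spec, params, max_rounds=max_rounds, tol=tol, rng=rng
        )
        if posthoc:
            chart = posthoc_adjust(chart, train)
        aurocs.append(chart_auroc(chart, test))
    return CVResult(fold_aurocs=aurocs, seed=seed)


def interpretability_score(spec: ChartSpec) -> int:
    """Chart readability measure: the total number of cells (fewer = easier
    to read).  3200 for the 8-feature 2D chart, 80 for the 4-feature 1D."""
    return cell_count(spec)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class ChartRiskModel:
    """Chart-based 10-year CVD risk score learned by a constrained GA.

    Parameters
    ----------
    cohort : Cohort
        Categorized person-level records with binary outcomes.
    spec : ChartSpec, optional
        Chart geometry; defaults to the cohort's.

    Examples
    --------
    >>> from xpars import simulate, chart
    >>> model = simulate.make_planted_model(chart.spec_1d_4feature())
    >>> cohort = simulate.simulate_cohort(model, n=5432, seed=1)
    >>> res = ChartRiskModel(cohort).fit(seed=1)
    >>> 0.5 < res.training_auroc <= 1.0
    True
    """

    def __init__(self, cohort: Cohort, spec: Optional[ChartSpec] = None):
        self.cohort = cohort
        self.spec = spec or cohort.spec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       spec: ChartSpec) -> "ChartRiskModel":
        """Build from a raw DataFrame (continuous or labelled columns plus a
        binary ``outcome`` column); see :meth:`Cohort.from_raw`."""
        return cls(Cohort.from_raw(df, spec), spec)

    def fit(
        self,
        ga_params: Optional[GAParams] = None,
        max_rounds: int = 2,
        tol: float = 0.001,
        posthoc: bool = True,
        strategy: str = "empirical",
        external_chart: Optional[RiskChart] = None,
        seed: Optional[int] = None,
    ) -> "ChartRiskResults":
        params = ga_params or GAParams(seed=seed)
        if seed is not None:
            params.seed = seed
        rng = np.random.default_rng(params.seed)
        t0 = time.perf_counter()
        chart, history = train_chart(
            self.cohort, self.spec, params, max_rounds=max_rounds, tol=tol,
            strategy=strategy, external_chart=external_chart, rng=rng,
        )
        if posthoc:
            chart = posthoc_adjust(chart, self.cohort)
        history.final_auroc = chart_auroc(chart, self.cohort)
        wall = time.perf_counter() - t0
        return ChartRiskResults(
            model=self, chart=chart, history=history, params=params,
            posthoc=posthoc, max_rounds=max_rounds, tol=tol,
            wall_seconds=wall,
        )

    def cross_validate(self, ga_params: Optional[GAParams] = None,
                       k: int = 10, seed: Optional[int] = None,
                       **kwargs) -> CVResult:
        return cross_validate(self.cohort, self.spec, ga_params, k=k,
                              seed=seed, **kwargs)


@dataclass
class ChartRiskResults:
    """Fitted chart plus training diagnostics."""

    model: ChartRiskModel
    chart: RiskChart
    history: TrainHistory
    params: GAParams
    posthoc: bool
    max_rounds: int
    tol: float
    wall_seconds: float

    @property
    def training_auroc(self) -> float:
        return self.history.final_auroc

    @property
    def interpretability(self) -> int:
        return interpretability_score(self.chart.spec)

    def predict(self, cohort: Optional[Cohort] = None) -> pd.DataFrame:
        """Per-person risk level, band label and band-midpoint probability."""
        cohort = cohort or self.model.cohort
        block, row, col, keys = cohort.indexers()
        spec = self.chart.spec
        levels = np.stack([self.chart.blocks[k] for k in keys])[block, row, col]
        return pd.DataFrame({
            "level": levels,
            "band": [spec.band_labels[l - 1] for l in levels],
            "risk_midpoint": [spec.band_midpoints[l - 1] for l in levels],
        })

    def summary(self) -> str:
        spec = self.chart.spec
        h = self.history
        lines = [
            "Chart-based CVD risk score (GA under monotonicity constraints)",
            "=" * 62,
            f"Representation:      {'2D (BP x cholesterol)' if spec.is_2d else '1D (BP only)'}",
            f"Stratifiers:         {', '.join(f.name for f in spec.stratifiers)}",
            f"Blocks (chromosomes): {len(self.chart.blocks)}"
            f"   Cells: {self.interpretability}",
            f"Cohort:              n={self.model.cohort.n}, "
            f"events={self.model.cohort.n_events} "
            f"({100 * self.model.cohort.event_rate:.1f}%)",
            f"GA params:           pop={self.params.population_size}, "
            f"gens={self.params.generations}, stall={self.params.stall_limit}, "
            f"seed={self.params.seed}",
            f"Rounds completed:    {h.rounds_completed} (max {self.max_rounds}, "
            f"tol {self.tol})",
            f"Post-hoc modifier:   {'on' if self.posthoc else 'off'}",
            "-" * 62,
            f"Initial training AUROC: {h.initial_auroc:.4f}",
            f"Final training AUROC:   {h.final_auroc:.4f}",
            f"Wall time:              {self.wall_seconds:.1f} s",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chart": self.chart.to_dict(),
            "training": {
                "initial_auroc": self.history.initial_auroc,
                "final_auroc": self.history.final_auroc,
                "rounds_completed": self.history.rounds_completed,
                "trace": [
                    {"round": r, "block": "|".join(k), "n": n, "auroc": a}
                    for r, k, n, a in self.history.records
                ],
            },
            "params": {
                "population_size": self.params.population_size,
                "generations": self.params.generations,
                "stall_limit": self.params.stall_limit,
                "mutation_prob": self.params.mutation_prob,
                "include_incumbent": self.params.include_incumbent,
                "weight_offset": self.params.weight_offset,
                "seed": self.params.seed,
                "max_rounds": self.max_rounds,
                "tol": self.tol,
                "posthoc": self.posthoc,
            },
            "wall_seconds": self.wall_seconds,
        }
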