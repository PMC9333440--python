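"""Synthetic cohort generator with a planted monotone risk surface.

The generator emulates the statistical shape of a prospective CVD cohort of
middle-aged adults: ~5,432 people, a ~13% ten-year event rate, and event
probabilities that rise monotonically with blood pressure, cholesterol and
age.  Each chart cell (stratum × BP row × cholesterol column) carries a true
event probability from a logistic model with non-negative per-category
log-odds increments, the intercept calibrated so the population event rate
hits the target; outcomes are Bernoulli draws from the person's cell
probability.  The planted probabilities double as an oracle: scoring people
by them yields the best AUROC any cell-constant chart can reach in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import spearmanr

from .chart import ChartSpec, Cohort, RiskChart, StructuralError
from .ga import fitness_auroc, UndefinedFitnessError

__all__ = [
    "EffectParams",
    "PlantedModel",
    "make_planted_model",
    "simulate_cohort",
    "bayes_auroc",
    "recovery_report",
    "DEFAULT_MARGINALS",
    "DEFAULT_EFFECTS",
]

#: Default single-cohort size and 10-year event rate the generator targets.
DEFAULT_N = 5432
DEFAULT_EVENT_RATE = 705 / 5432  # ≈ 0.1298

#: Category marginals for a middle-aged cohort (first category first).
DEFAULT_MARGINALS: dict[str, tuple[float, ...]] = {
    "sex": (0.52, 0.48),
    "age": (0.38, 0.28, 0.20, 0.10, 0.04),
    "whr_high": (0.45, 0.55),
    "fh_cvd": (0.85, 0.15),
    "diabetes": (0.90, 0.10),
    "smoker": (0.80, 0.20),
    "bp": (0.45, 0.30, 0.15, 0.10),
    "chol": (0.25, 0.35, 0.25, 0.10, 0.05),
}

#: Per-category-step log-odds increments (epidemiologically plausible
#: ten-year hazard-ratio magnitudes).  BP/cholesterol/age must be
#: non-negative so the planted surface is monotone.
DEFAULT_EFFECTS: dict[str, float] = {
    "sex": 0.45,      # male vs female
    "age": 0.55,      # per decade group
    "whr_high": 0.30,
    "fh_cvd": 0.35,
    "diabetes": 0.55,
    "smoker": 0.45,
    "bp": 0.35,       # per BP category
    "chol": 0.22,     # per cholesterol category
}

_MONOTONE_FEATURES = ("bp", "chol", "age")


@dataclass
class EffectParams:
    """Log-odds structure of the planted surface.

    ``effects`` maps feature name → per-category-step increment (scalar) or a
    full per-category offset array; increments for BP, cholesterol and age
    must be non-negative (monotone risk).  ``target_rate`` is the population
    event rate the intercept is calibrated to.  ``age_bp_dependence`` > 0
    tilts the joint of age and BP categories positively (real cohorts
    correlate them); 0 keeps all features independent.
    """

    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    marginals: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    target_rate: float = DEFAULT_EVENT_RATE
    age_bp_dependence: float = 0.0


@dataclass
class PlantedModel:
    """Ground truth of a synthetic cohort: per-cell event probabilities.

    ``cell_probs`` maps each stratum key to an (n_rows, n_cols) matrix,
    monotone non-decreasing along both axes; ``cell_joint`` is the sampling
    distribution over (block, row, col) cells.
    """

    spec: ChartSpec
    cell_probs: dict[tuple[str, ...], np.ndarray]
    cell_joint: np.ndarray  # shape (n_blocks, n_rows, n_cols), sums to 1
    params: EffectParams

    @property
    def expected_event_rate(self) -> float:
        probs = np.stack([self.cell_probs[k] for k in self.spec.stratum_keys()])
        return float((self.cell_joint * probs).sum())

    def prob_of(self, cohort: Cohort) -> np.ndarray:
        """Per-record true event probability (the oracle score)."""
        if cohort.spec != self.spec:
            raise StructuralError("cohort spec differs from planted model spec")
        block, row, col, keys = cohort.indexers()
        probs = np.stack([self.cell_probs[k] for k in keys])
        return probs[block, row, col]

    def discretized_chart(self) -> RiskChart:
        """Planted probabilities mapped to the nearest band-midpoint level."""
        mids = np.asarray(self.spec.band_midpoints)
        blocks = {}
        for key, p in self.cell_probs.items():
            lv = np.argmin(np.abs(p[..., None] - mids), axis=-1) + 1
            blocks[key] = np.maximum.accumulate(
                np.maximum.accumulate(lv, axis=0), axis=1
            ).astype(np.int64)
        return RiskChart(self.spec, blocks)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "spec": self.spec.to_dict(),
            "target_rate": self.params.target_rate,
            "effects": dict(self.params.effects),
            "cell_probs": {
                "|".join(k): np.round(v, 10).tolist()
                for k, v in sorted(self.cell_probs.items())
            },
        }


def _feature_offsets(spec: ChartSpec, params: EffectParams) -> dict[str, np.ndarray]:
    offsets = {}
    for f in spec.features:
        eff = params.effects.get(f.name, 0.0)
        if np.isscalar(eff):
            arr = float(eff) * np.arange(f.n_categories, dtype=float)
        else:
            arr = np.asarray(eff, dtype=float)
            if arr.shape != (f.n_categories,):
                raise ValueError(
                    f"effect array for {f.name!r} must have length "
                    f"{f.n_categories}"
                )
            arr = arr - arr[0]
        if f.name in _MONOTONE_FEATURES and np.any(np.diff(arr) < 0):
            raise ValueError(
                f"{f.name!r} effects must be non-decreasing (monotone risk)"
            )
        offsets[f.name] = arr
    return offsets


def make_planted_model(
    spec: ChartSpec,
    effect_params: Optional[EffectParams] = None,
    seed: Optional[int] = None,
) -> PlantedModel:
    """Build the planted logistic risk surface for ``spec``.

    Cell probability = expit(alpha + Σ per-category offsets); ``alpha`` is
    solved so the expected event rate over the cell distribution equals
    ``target_rate``.  Construction is deterministic; ``seed`` is accepted for
    interface symmetry with the samplers and is unused.
    """
    params = effect_params or EffectParams()
    offsets = _feature_offsets(spec, params)
    keys = spec.stratum_keys()
    nr, nc = spec.block_shape
    nb = len(keys)

    # per-cell linear predictor without intercept, and cell sampling joint
    logit = np.zeros((nb, nr, nc))
    joint = np.ones((nb, nr, nc))
    marg = {f.name: np.asarray(params.marginals[f.name], dtype=float)
            for f in spec.features}
    for name, m in marg.items():
        if abs(m.sum() - 1.0) > 1e-9 or np.any(m < 0):
            raise ValueError(f"marginals for {name!r} must be a distribution")
    age_idx = None
    for b, key in enumerate(keys):
        lp = 0.0
        pr = 1.0
        for f, label in zip(spec.stratifiers, key):
            code = f.categories.index(label)
            lp += offsets[f.name][code]
            pr *= marg[f.name][code]
            if f.name == "age":
                age_idx = code
        row_off = offsets[spec.row_axis.name]
        col_off = (offsets[spec.column_axis.name]
                   if spec.is_2d else np.zeros(1))
        logit[b] = lp + row_off[:, None] + col_off[None, :]
        cell_pr = (marg[spec.row_axis.name][:, None]
                   * (marg[spec.column_axis.name][None, :]
                      if spec.is_2d else np.ones((1, 1))))
        if params.age_bp_dependence and age_idx is not None:
            cell_pr = cell_pr * np.exp(
                params.age_bp_dependence * age_idx * np.arange(nr)
            )[:, None]
        joint[b] = pr * cell_pr
    joint /= joint.sum()

    def rate(alpha: float) -> float:
        return float((joint * expit(alpha + logit)).sum()) - params.target_rate

    alpha = brentq(rate, -30.0, 30.0, xtol=1e-12)
    probs = expit(alpha + logit)
    cell_probs = {key: probs[b] for b, key in enumerate(keys)}
    return PlantedModel(spec, cell_probs, joint, params)


def simulate_cohort(
    model: PlantedModel,
    n: int = DEFAULT_N,
    seed: Optional[int] = None,
    raw_values: bool = False,
) -> Cohort | tuple[Cohort, pd.DataFrame]:
    """Draw ``n`` people from the planted model.

    Cells are sampled from the model's joint, outcomes are Bernoulli draws
    from the cell probability.  With ``raw_values=True`` a second DataFrame of
    raw measurements (age in years, BP mm Hg, cholesterol mg/dl, WHR, FBS)
    consistent with each person's categories is returned alongside, so the
    binning/derivation code paths can be exercised end to end.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec = model.spec
    keys = spec.stratum_keys()
    nr, nc = spec.block_shape
    flat_joint = model.cell_joint.ravel()
    cells = rng.choice(flat_joint.size, size=n, p=flat_joint)
    block, rest = np.divmod(cells, nr * nc)
    row, col = np.divmod(rest, nc)

    cols: dict[str, np.ndarray] = {}
    key_arr = np.array(keys, dtype=object).reshape(len(keys), -1)
    for j, f in enumerate(spec.stratifiers):
        labels = key_arr[:, j][block]
        codes = np.array([f.categories.index(x) for x in f.categories])
        lut = {lab: i for i, lab in enumerate(f.categories)}
        cols[f.name] = np.array([lut[x] for x in labels], dtype=np.int64)
    cols[spec.row_axis.name] = row.astype(np.int64)
    if spec.is_2d:
        cols[spec.column_axis.name] = col.astype(np.int64)

    probs = np.stack([model.cell_probs[k] for k in keys])[block, row, col]
    outcome = (rng.random(n) < probs).astype(np.int8)
    cohort = Cohort(spec, pd.DataFrame(cols), outcome)
    if not raw_values:
        return cohort
    return cohort, _raw_frame(cohort, rng)


def _uniform_in_bin(rng, code, edges, lo, hi, decimals=0):
    # floored (not rounded) so printed values never cross a bin edge
    e = np.concatenate([[lo], edges, [hi]])
    v = rng.uniform(e[code], e[code + 1])
    scale = 10.0 ** decimals
    return np.floor(v * scale) / scale


def _raw_frame(cohort: Cohort, rng: np.random.Generator) -> pd.DataFrame:
    """Raw measurements consistent with each record's categories."""
    spec = cohort.spec
    n = cohort.n
    out: dict[str, np.ndarray] = {}
    sex_codes = cohort.codes.get("sex")
    sex = (np.array(["F", "M"])[sex_codes] if sex_codes is not None
           else np.full(n, "F"))
    for f in spec.features:
        code = cohort.codes[f.name].to_numpy()
        if f.name == "sex":
            out["sex"] = sex
        elif f.name == "age":
            out["age"] = _uniform_in_bin(
                rng, code, np.asarray(f.edges), 35.0, 85.0, decimals=1)
        elif f.name == "bp":
            out["sbp"] = _uniform_in_bin(
                rng, code, np.asarray(f.edges), 90.0, 200.0)
        elif f.name == "chol":
            out["tchol"] = _uniform_in_bin(
                rng, code, np.asarray(f.edges), 100.0, 360.0)
        elif f.name == "whr_high":
            thr = np.where(sex == "F", 0.80, 0.95)
            lo = np.where(code == 1, thr, 0.60)
            hi = np.where(code == 1, thr + 0.15, thr)
            out["whr"] = np.floor(rng.uniform(lo, hi) * 1000) / 1000
        elif f.name == "diabetes":
            out["fbs"] = np.floor(np.where(
                code == 1, rng.uniform(126.0, 220.0, n),
                rng.uniform(70.0, 126.0, n)
            ))
        elif f.name == "smoker":
            out["smoker"] = code.astype(int)
        elif f.name == "fh_cvd":
            out["fh_cvd"] = code.astype(int)
    out["outcome"] = cohort.outcome.astype(int)
    return pd.DataFrame(out)


def bayes_auroc(model: PlantedModel, cohort: Cohort) -> float:
    """AUROC of the true planted cell probabilities used as scores — the
    ceiling, in expectation, for any scorer constant within cells.  Returns
    0.5 when every score is tied (e.g. a constant-probability model)."""
    scores = model.prob_of(cohort)
    try:
        return fitness_auroc(scores, cohort.outcome)
    except UndefinedFitnessError:
        return 0.5


def recovery_report(
    model: PlantedModel,
    chart: RiskChart,
    cohort: Cohort,
    min_count: int = 30,
) -> dict:
    """How well a trained chart recovers the planted surface.

    Over cells covered by at least ``min_count`` cohort records, reports the
    Spearman rank correlation between planted cell probabilities and learned
    gene levels, plus the exact-level agreement against the level-discretized
    planted model, overall and per block.
    """
    if chart.spec != model.spec:
        raise StructuralError("chart spec differs from planted model spec")
    spec = model.spec
    block, row, col, keys = cohort.indexers()
    nr, nc = spec.block_shape
    flat = (block * nr + row) * nc + col
    counts = np.bincount(flat, minlength=len(keys) * nr * nc).reshape(
        len(keys), nr, nc
    )
    probs = np.stack([model.cell_probs[k] for k in keys])
    levels = np.stack([chart.blocks[k] for k in keys])
    ref = np.stack([model.discretized_chart().blocks[k] for k in keys])
    mask = counts >= min_count
    n_cells = int(mask.sum())
    if n_cells >= 2 and len(np.unique(levels[mask])) > 1:
        rho = float(spearmanr(probs[mask], levels[mask]).statistic)
    else:
        rho = float("nan")
    per_block = {
        "|".join(keys[b]): float((levels[b] == ref[b])[mask[b]].mean())
        for b in range(len(keys)) if mask[b].any()
    }
    return {
        "spearman": rho,
        "n_cells_covered": n_cells,
        "min_count": min_count,
        "exact_level_agreement": (
            float((levels[mask] == ref[mask]).mean()) if n_cells else float("nan")
        ),
        "per_block_agreement": per_block,
    }
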