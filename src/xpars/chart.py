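"""Chart geometry, risk-factor categorization, chromosome validity and risk lookup.

A chart-based risk score is a lookup table: people are stratified by
categorical risk factors (sex, age group, waist-to-hip ratio, family history,
diabetes, smoking) into *blocks*, and within each block a small matrix indexed
by systolic blood-pressure category (rows) and total-cholesterol category
(columns, absent in the 1D representation) holds an ordinal risk level, the
*gene*.  A block's matrix is the *chromosome* of the genetic search.

Canonical orientation: index 0 is the lowest category on every axis and genes
are non-decreasing along increasing row (BP) and column (cholesterol) indices.
Renderers display the highest BP row first; that flip is presentation only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChartError",
    "InputError",
    "StructuralError",
    "FeatureSpec",
    "ChartSpec",
    "RiskChart",
    "Cohort",
    "BAND_LABELS",
    "BAND_MIDPOINTS",
    "bin_continuous",
    "derive_flags",
    "is_valid",
    "repair_chromosome",
    "stratum_key",
    "lookup_risk",
    "cell_count",
    "block_count",
    "spec_2d_8feature",
    "spec_1d_4feature",
]


class ChartError(ValueError):
    """Base class for chart-domain errors."""


class InputError(ChartError):
    """A person-level record could not be validated or categorized."""


class StructuralError(ChartError):
    """A chart, chromosome or spec violates a structural contract."""


#: Printed risk bands for the 10-year CVD probability, lowest to highest.
BAND_LABELS: tuple[str, ...] = ("≤1%", "2%", "3–4%", "5–9%", "10–14%", "≥15%")

#: Numeric midpoint assigned to each band when a probability-like score is
#: needed (an artifact convention; the chart itself is ordinal).
BAND_MIDPOINTS: tuple[float, ...] = (0.005, 0.02, 0.035, 0.07, 0.12, 0.175)

#: WHR dichotomization thresholds (female, male).
WHR_THRESHOLDS: tuple[float, float] = (0.80, 0.95)


# ---------------------------------------------------------------------------
# Feature and chart specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One categorized risk factor.

    Parameters
    ----------
    name : str
        Canonical feature name (also the cohort column name).
    role : {"stratifier", "row_axis", "column_axis"}
        Where the feature sits in the chart geometry.
    categories : tuple of str
        Ordered category labels, lowest risk exposure first.
    edges : tuple of float, optional
        Strictly increasing cut points for a continuous feature.  Binning is
        left-closed/right-open: values below the first edge map to category 1,
        values at or above the last edge to the last category.
    sex_specific_threshold : (float, float), optional
        (female, male) dichotomization threshold, e.g. for WHR.
    """

    name: str
    role: str
    categories: tuple[str, ...]
    edges: Optional[tuple[float, ...]] = None
    sex_specific_threshold: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.role not in ("stratifier", "row_axis", "column_axis"):
            raise StructuralError(f"unknown feature role {self.role!r}")
        if len(self.categories) < 2 and self.role == "stratifier":
            raise StructuralError(
                f"stratifier {self.name!r} needs >= 2 categories"
            )
        if self.edges is not None:
            edges = tuple(float(e) for e in self.edges)
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise StructuralError(
                    f"edges for {self.name!r} must be strictly increasing"
                )
            if len(self.categories) != len(edges) + 1:
                raise StructuralError(
                    f"{self.name!r}: {len(self.categories)} categories do not "
                    f"match {len(edges)} edges (+1 expected)"
                )
            object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class ChartSpec:
    """Declarative chart geometry: stratifiers plus row/column axes.

    ``column_axis`` is ``None`` for the one-dimensional (cholesterol-free)
    representation, in which every block is a column over BP categories.
    """

    stratifiers: tuple[FeatureSpec, ...]
    row_axis: FeatureSpec
    column_axis: Optional[FeatureSpec] = None
    n_levels: int = 6
    band_labels: tuple[str, ...] = BAND_LABELS
    band_midpoints: tuple[float, ...] = BAND_MIDPOINTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "stratifiers", tuple(self.stratifiers))
        object.__setattr__(self, "band_labels", tuple(self.band_labels))
        object.__setattr__(self, "band_midpoints", tuple(self.band_midpoints))
        if self.row_axis.role != "row_axis":
            raise StructuralError("row_axis feature must have role 'row_axis'")
        if self.column_axis is not None and self.column_axis.role != "column_axis":
            raise StructuralError(
                "column_axis feature must have role 'column_axis'"
            )
        for f in self.stratifiers:
            if f.role != "stratifier":
                raise StructuralError(
                    f"stratifier list contains non-stratifier {f.name!r}"
                )
        if len(self.band_labels) != self.n_levels:
            raise StructuralError("n_levels must equal number of band labels")
        if len(self.band_midpoints) != self.n_levels:
            raise StructuralError("need one band midpoint per level")

    # -- geometry -----------------------------------------------------------
    @property
    def is_2d(self) -> bool:
        return self.column_axis is not None

    @property
    def n_rows(self) -> int:
        return self.row_axis.n_categories

    @property
    def n_cols(self) -> int:
        return self.column_axis.n_categories if self.column_axis else 1

    @property
    def block_shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def features(self) -> tuple[FeatureSpec, ...]:
        axes = (self.row_axis,) + (
            (self.column_axis,) if self.column_axis else ()
        )
        return self.stratifiers + axes

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def stratum_keys(self) -> list[tuple[str, ...]]:
        """All stratum keys, Cartesian product in stratifier order."""
        if not self.stratifiers:
            return [()]
        return list(
            itertools.product(*(f.categories for f in self.stratifiers))
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def fs(f: FeatureSpec) -> dict:
            d: dict = {
                "name": f.name,
                "role": f.role,
                "categories": list(f.categories),
            }
            if f.edges is not None:
                d["edges"] = list(f.edges)
            if f.sex_specific_threshold is not None:
                d["sex_specific_threshold"] = list(f.sex_specific_threshold)
            return d

        return {
            "stratifiers": [fs(f) for f in self.stratifiers],
            "row_axis": fs(self.row_axis),
            "column_axis": fs(self.column_axis) if self.column_axis else None,
            "n_levels": self.n_levels,
            "band_labels": list(self.band_labels),
            "band_midpoints": list(self.band_midpoints),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChartSpec":
        def fs(fd: Mapping) -> FeatureSpec:
            return FeatureSpec(
                name=fd["name"],
                role=fd["role"],
                categories=tuple(fd["categories"]),
                edges=tuple(fd["edges"]) if fd.get("edges") else None,
                sex_specific_threshold=(
                    tuple(fd["sex_specific_threshold"])
                    if fd.get("sex_specific_threshold")
                    else None
                ),
            )

        return cls(
            stratifiers=tuple(fs(f) for f in d["stratifiers"]),
            row_axis=fs(d["row_axis"]),
            column_axis=fs(d["column_axis"]) if d.get("column_axis") else None,
            n_levels=int(d["n_levels"]),
            band_labels=tuple(d["band_labels"]),
            band_midpoints=tuple(float(x) for x in d["band_midpoints"]),
        )


def cell_count(spec: ChartSpec) -> int:
    """Total number of chart cells: blocks x rows x columns.

    The full 8-feature 2D chart has 3200 cells; the 4-feature 1D
    chart has 80.  This is also the interpretability measure.
    """
    return block_count(spec) * spec.n_rows * spec.n_cols


def block_count(spec: ChartSpec) -> int:
    """Number of blocks (chromosomes): product of stratifier category counts."""
    return int(math.prod(f.n_categories for f in spec.stratifiers))


# -- preset chart geometries ------------------------------------------------

def _sex() -> FeatureSpec:
    return FeatureSpec("sex", "stratifier", ("F", "M"))


def _age() -> FeatureSpec:
    # Five age groups from the configurable floor of 35; edges overridable.
    return FeatureSpec(
        "age", "stratifier",
        ("35-44", "45-54", "55-64", "65-74", "75+"),
        edges=(45.0, 55.0, 65.0, 75.0),
    )


def _whr() -> FeatureSpec:
    return FeatureSpec(
        "whr_high", "stratifier", ("normal", "high"),
        sex_specific_threshold=WHR_THRESHOLDS,
    )


def _yes_no(name: str) -> FeatureSpec:
    return FeatureSpec(name, "stratifier", ("no", "yes"))


def _bp() -> FeatureSpec:
    return FeatureSpec(
        "bp", "row_axis",
        ("<120", "120-139", "140-159", "160+"),
        edges=(120.0, 140.0, 160.0),
    )


def _chol() -> FeatureSpec:
    return FeatureSpec(
        "chol", "column_axis",
        ("<150", "150-199", "200-249", "250-299", "300+"),
        edges=(150.0, 200.0, 250.0, 300.0),
    )


def spec_2d_8feature() -> ChartSpec:
    """Eight-feature 2D chart: sex, age, WHR, FH, diabetes, smoking strata;
    4 BP rows x 5 cholesterol columns per block (160 blocks, 3200 cells)."""
    return ChartSpec(
        stratifiers=(
            _sex(), _age(), _whr(), _yes_no("fh_cvd"),
            _yes_no("diabetes"), _yes_no("smoker"),
        ),
        row_axis=_bp(),
        column_axis=_chol(),
    )


def spec_1d_4feature() -> ChartSpec:
    """Four-feature 1D chart (no cholesterol): sex, age, WHR strata;
    4 BP rows per block (20 blocks, 80 cells)."""
    return ChartSpec(
        stratifiers=(_sex(), _age(), _whr()),
        row_axis=_bp(),
        column_axis=None,
    )


# ---------------------------------------------------------------------------
# Categorization of person-level records
# ---------------------------------------------------------------------------

def bin_continuous(value: float, edges: Sequence[float]) -> int:
    """Map a continuous value to a 1-based category index.

    Intervals are left-closed/right-open: ``value < edges[0]`` gives 1 and
    ``value >= edges[-1]`` gives ``len(edges) + 1``.
    """
    v = float(value)
    if not np.isfinite(v):
        raise InputError(f"non-finite value {value!r} cannot be categorized")
    return int(np.searchsorted(np.asarray(edges, dtype=float), v, side="right")) + 1


def derive_flags(record: Mapping) -> dict:
    """Resolve the WHR-high and diabetes booleans for one record.

    WHR is high at >= 0.80 for women and >= 0.95 for men.  Diabetes is present
    if fasting blood sugar >= 126 mg/dL, 2-hour plasma glucose >= 200 mg/dL,
    or the person receives anti-diabetic treatment; an explicit ``diabetes``
    flag short-circuits those inputs.
    """
    out = dict(record)
    _resolve_whr(out)
    _resolve_diabetes(out)
    return out


def _resolve_whr(rec: dict) -> None:
    if "whr" in rec and rec["whr"] is not None and "whr_high" not in rec:
        sex = rec.get("sex")
        if sex not in ("F", "M"):
            raise InputError("WHR given but sex is missing or not F/M")
        thr = WHR_THRESHOLDS[0] if sex == "F" else WHR_THRESHOLDS[1]
        rec["whr_high"] = bool(float(rec["whr"]) >= thr)


def _resolve_diabetes(rec: dict) -> None:
    if "diabetes" not in rec or rec["diabetes"] is None:
        fbs = rec.get("fbs")
        glu = rec.get("glucose_2h")
        trt = rec.get("diabetes_treatment")
        if fbs is None and glu is None and trt is None:
            raise InputError(
                "no diabetes inputs: need fbs, glucose_2h, "
                "diabetes_treatment or an explicit diabetes flag"
            )
        rec["diabetes"] = bool(
            (fbs is not None and float(fbs) >= 126.0)
            or (glu is not None and float(glu) >= 200.0)
            or bool(trt)
        )
    else:
        rec["diabetes"] = bool(rec["diabetes"])


def categorize_value(feature: FeatureSpec, value, sex: Optional[str] = None) -> int:
    """0-based category code of ``value`` under ``feature``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise InputError(f"missing value for feature {feature.name!r}")
    if isinstance(value, str):
        if value not in feature.categories:
            raise InputError(
                f"label {value!r} not a category of {feature.name!r} "
                f"{feature.categories}"
            )
        return feature.categories.index(value)
    if isinstance(value, (bool, np.bool_)):
        # binary features order categories absent-first
        return int(bool(value))
    if feature.edges is not None:
        return bin_continuous(value, feature.edges) - 1
    if feature.sex_specific_threshold is not None:
        if sex not in ("F", "M"):
            raise InputError(
                f"sex needed to dichotomize {feature.name!r} from a ratio"
            )
        thr = feature.sex_specific_threshold[0 if sex == "F" else 1]
        return int(float(value) >= thr)
    # integer-coded category
    code = int(value)
    if not 0 <= code < feature.n_categories:
        raise InputError(
            f"code {code} out of range for {feature.name!r} "
            f"({feature.n_categories} categories)"
        )
    return code


def stratum_key(record: Mapping, spec: ChartSpec) -> tuple[str, ...]:
    """Tuple of the record's stratifier category labels, in spec order."""
    key = []
    for f in spec.stratifiers:
        if f.name not in record:
            raise InputError(f"record is missing stratifier {f.name!r}")
        code = categorize_value(f, record[f.name], sex=record.get("sex"))
        key.append(f.categories[code])
    return tuple(key)


# ---------------------------------------------------------------------------
# Chromosome validity and repair
# ---------------------------------------------------------------------------

def is_valid(genes: np.ndarray, n_levels: int) -> bool:
    """True iff all genes lie in [1, n_levels] and the matrix is monotone
    non-decreasing along both increasing row and column index."""
    g = _as_gene_matrix(genes)
    if g.min() < 1 or g.max() > n_levels:
        return False
    if g.shape[0] > 1 and np.any(np.diff(g, axis=0) < 0):
        return False
    if g.shape[1] > 1 and np.any(np.diff(g, axis=1) < 0):
        return False
    return True


def _as_gene_matrix(genes) -> np.ndarray:
    try:
        g = np.asarray(genes, dtype=np.int64)
    except ValueError as exc:  # ragged input
        raise StructuralError(f"ragged gene matrix: {exc}") from exc
    if g.ndim == 1:
        g = g.reshape(-1, 1)
    if g.ndim != 2 or g.size == 0 or g.dtype == object:
        raise StructuralError(f"gene matrix must be 2D non-empty, got {g.shape}")
    return g


def repair_chromosome(
    genes: np.ndarray, changed_cell: tuple[int, int] | int, direction: int
) -> np.ndarray:
    """Apply a single ±1 gene change to a valid matrix and minimally restore
    monotonicity.

    After an increase, any cell at a weakly higher (row, col) index pulled
    below a monotone predecessor is raised just enough, sweeping outward;
    after a decrease the mirrored lowering runs over weakly lower indices.
    Cells not forced by a violation are untouched, so the result is the
    L1-minimal valid matrix among those keeping the changed cell at its new
    value.
    """
    g = _as_gene_matrix(genes).copy()
    if isinstance(changed_cell, (int, np.integer)):
        changed_cell = (int(changed_cell), 0) if g.shape[1] == 1 \
            else (0, int(changed_cell))
    g[changed_cell] += 1 if direction > 0 else -1
    # A raising (resp. lowering) sweep moves exactly the cells transitively
    # forced by the one changed cell, since the matrix was valid beforehand.
    if direction > 0:
        g = np.maximum.accumulate(g, axis=0)
        g = np.maximum.accumulate(g, axis=1)
    else:
        g = np.minimum.accumulate(g[::-1, ::-1], axis=0)
        g = np.minimum.accumulate(g, axis=1)[::-1, ::-1]
    return g


def enforce_monotone(genes: np.ndarray, n_levels: int) -> np.ndarray:
    """Clip to [1, n_levels] and impose monotonicity by a cumulative-max
    sweep (each cell raised to at least its up/left neighbours)."""
    g = np.clip(_as_gene_matrix(genes), 1, n_levels)
    g = np.maximum.accumulate(g, axis=0)
    g = np.maximum.accumulate(g, axis=1)
    return np.clip(g, 1, n_levels)


# ---------------------------------------------------------------------------
# The deployable chart
# ---------------------------------------------------------------------------

@dataclass
class RiskChart:
    """A complete chart: one valid chromosome per stratum.

    ``blocks`` maps each stratum key (tuple of stratifier labels, possibly
    empty for a single-block chart) to an (n_rows, n_cols) integer matrix of
    gene levels in [1, n_levels].
    """

    spec: ChartSpec
    blocks: dict[tuple[str, ...], np.ndarray]

    def validate(self) -> None:
        expected = set(self.spec.stratum_keys())
        got = set(self.blocks)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            raise StructuralError(
                f"chart blocks do not cover the strata exactly "
                f"(missing e.g. {missing}, extra e.g. {extra})"
            )
        for key, g in self.blocks.items():
            g = _as_gene_matrix(g)
            if g.shape != self.spec.block_shape:
                raise StructuralError(
                    f"block {key}: shape {g.shape} != {self.spec.block_shape}"
                )
            if not is_valid(g, self.spec.n_levels):
                raise StructuralError(f"block {key} violates validity")

    def copy(self) -> "RiskChart":
        return RiskChart(self.spec, {k: v.copy() for k, v in self.blocks.items()})

    @classmethod
    def constant(cls, spec: ChartSpec, level: int = 1) -> "RiskChart":
        blocks = {
            key: np.full(spec.block_shape, level, dtype=np.int64)
            for key in spec.stratum_keys()
        }
        return cls(spec, blocks)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "gene_order": "row-major",
            "spec": self.spec.to_dict(),
            "blocks": {
                "|".join(key): np.asarray(g, dtype=int).tolist()
                for key, g in sorted(self.blocks.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskChart":
        spec = ChartSpec.from_dict(d["spec"])
        blocks = {
            tuple(k.split("|")) if k else (): np.asarray(v, dtype=np.int64)
            for k, v in d["blocks"].items()
        }
        chart = cls(spec, blocks)
        chart.validate()
        return chart


def lookup_risk(chart: RiskChart, record: Mapping) -> tuple[int, str]:
    """Risk (gene level, band label) for one categorizable record."""
    spec = chart.spec
    key = stratum_key(record, spec)
    if key not in chart.blocks:
        raise StructuralError(f"chart has no block for stratum {key}")
    row = categorize_value(spec.row_axis, record[spec.row_axis.name],
                           sex=record.get("sex"))
    if spec.is_2d:
        name = spec.column_axis.name
        if name not in record or record[name] is None:
            raise InputError(
                f"2D chart requires {name!r}; use a 1D spec for lab-free scoring"
            )
        col = categorize_value(spec.column_axis, record[name],
                               sex=record.get("sex"))
    else:
        col = 0
    level = int(chart.blocks[key][row, col])
    return level, spec.band_labels[level - 1]


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Categorized person-level records with a binary 10-year outcome.

    ``codes`` holds one 0-based integer category column per chart feature
    (stratifiers, row axis, column axis if 2D); ``outcome`` is 0/1.
    """

    spec: ChartSpec
    codes: pd.DataFrame
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise InputError("outcome must be binary 0/1")
        for f in self.spec.features:
            if f.name not in self.codes.columns:
                raise InputError(f"cohort is missing feature column {f.name!r}")
            col = self.codes[f.name].to_numpy()
            if col.min() < 0 or col.max() >= f.n_categories:
                raise InputError(f"category codes out of range for {f.name!r}")
        if len(self.codes) != len(self.outcome):
            raise InputError("codes and outcome length mismatch")

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def event_rate(self) -> float:
        return float(self.outcome.mean())

    def subset(self, index: np.ndarray) -> "Cohort":
        return Cohort(
            self.spec,
            self.codes.iloc[index].reset_index(drop=True),
            self.outcome[index],
        )

    # -- index arrays used by the fitness cache -----------------------------
    def indexers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, ...]]]:
        """(block id, row, col) per record plus the ordered stratum-key list.

        Block ids index into ``spec.stratum_keys()`` (mixed-radix encoding of
        the stratifier codes, first stratifier most significant).
        """
        spec = self.spec
        keys = spec.stratum_keys()
        block = np.zeros(self.n, dtype=np.int64)
        for f in spec.stratifiers:
            block = block * f.n_categories + self.codes[f.name].to_numpy()
        row = self.codes[spec.row_axis.name].to_numpy(dtype=np.int64)
        if spec.is_2d:
            col = self.codes[spec.column_axis.name].to_numpy(dtype=np.int64)
        else:
            col = np.zeros(self.n, dtype=np.int64)
        return block, row, col, keys

    @classmethod
    def from_raw(cls, df: pd.DataFrame, spec: ChartSpec) -> "Cohort":
        """Build a cohort from raw or mixed columns.

        Accepts raw continuous values (age in years, BP in mm Hg, cholesterol
        in mg/dl, WHR as a ratio), category labels, or pre-resolved booleans
        and integer codes; diabetes may instead be given via ``fbs`` /
        ``glucose_2h`` / ``diabetes_treatment`` columns.  Requires an
        ``outcome`` column with values 0/1.
        """
        aliases = {"sbp": "bp", "tchol": "chol", "cholesterol": "chol",
                   "systolic_bp": "bp"}
        df = df.rename(columns={c: aliases[c] for c in df.columns
                                if c in aliases})
        if "outcome" not in df.columns:
            raise InputError("cohort is missing the 'outcome' column")
        records = df.to_dict("records")
        cols: dict[str, list[int]] = {f.name: [] for f in spec.features}
        feature_names = {f.name for f in spec.features}
        for i, rec in enumerate(records):
            rec = {k: v for k, v in rec.items() if not _is_missing(v)}
            try:
                if "whr_high" in feature_names and "whr_high" not in rec:
                    _resolve_whr(rec)
                if "diabetes" in feature_names and "diabetes" not in rec:
                    _resolve_diabetes(rec)
                for f in spec.features:
                    if f.name not in rec:
                        raise InputError(f"missing value for {f.name!r}")
                    cols[f.name].append(
                        categorize_value(f, rec[f.name], sex=rec.get("sex"))
                    )
            except ChartError as exc:
                raise InputError(f"row {i}: {exc}") from exc
        outcome = pd.to_numeric(df["outcome"], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isin(outcome, (0, 1)))
        if bad.size:
            raise InputError(
                f"row {bad[0]}: outcome value {df['outcome'].iloc[bad[0]]!r} "
                "is not 0/1"
            )
        return cls(spec, pd.DataFrame(cols, dtype=np.int64),
                   outcome.astype(np.int8))


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


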