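"""File I/O and chart rendering: cohort CSV, versioned chart/spec JSON,
text and HTML chart renderers, and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chart import (
    ChartSpec,
    Cohort,
    InputError,
    RiskChart,
    StructuralError,
)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_chart_json",
    "write_chart_json",
    "read_spec_json",
    "write_spec_json",
    "render_chart",
    "parse_text_chart",
    "write_manifest",
]

#: Common raw-measurement column names mapped onto canonical feature names.
DEFAULT_ALIASES = {"sbp": "bp", "tchol": "chol", "cholesterol": "chol",
                   "systolic_bp": "bp"}


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def read_cohort_csv(path, spec: ChartSpec,
                    mapping: Optional[Mapping[str, str]] = None) -> Cohort:
    """Read and categorize a cohort CSV.

    ``mapping`` maps canonical feature names to the file's column names
    (e.g. ``{"bp": "sys_pressure"}``); common aliases (sbp, tchol) are
    applied automatically.  The outcome column must be binary 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    rename = dict(DEFAULT_ALIASES)
    if mapping:
        rename.update({v: k for k, v in mapping.items()})
    df = df.rename(columns={c: rename[c] for c in df.columns if c in rename})
    missing = [f.name for f in spec.features
               if f.name not in df.columns
               and f.name not in ("whr_high", "diabetes")]
    if "outcome" not in df.columns:
        raise InputError(f"{path.name}: no 'outcome' column")
    if missing:
        raise InputError(f"{path.name}: missing mapped column(s) {missing}")
    return Cohort.from_raw(df, spec)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a categorized cohort as labelled CSV (one column per feature,
    category labels as values, plus the 0/1 outcome)."""
    out = {}
    for f in cohort.spec.features:
        codes = cohort.codes[f.name].to_numpy()
        out[f.name] = np.asarray(f.categories, dtype=object)[codes]
    out["outcome"] = cohort.outcome.astype(int)
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def _dump(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def write_chart_json(chart: RiskChart, path) -> None:
    _dump(chart.to_dict(), path)


def read_chart_json(path) -> RiskChart:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d.get("format_version") != 1:
        raise StructuralError(
            f"unsupported chart format_version {d.get('format_version')!r}"
        )
    return RiskChart.from_dict(d)


def write_spec_json(spec: ChartSpec, path) -> None:
    _dump({"format_version": 1, "spec": spec.to_dict()}, path)


def read_spec_json(path) -> ChartSpec:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if "spec" in d:
        d = d["spec"]
    return ChartSpec.from_dict(d)


def write_manifest(path, *, seed, params: dict, inputs: dict,
                   history: Optional[dict] = None,
                   wall_seconds: Optional[float] = None) -> None:
    """Reproducibility manifest: seed, parameters, input hashes, AUROC trace."""
    hashes = {}
    for name, p in inputs.items():
        p = Path(p)
        hashes[name] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
        }
    _dump({
        "format_version": 1,
        "seed": seed,
        "params": params,
        "inputs": hashes,
        "history": history,
        "wall_seconds": wall_seconds,
    }, path)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_HTML_COLORS = ("#2e7d32", "#8bc34a", "#ffeb3b", "#ff9800", "#f4511e", "#b71c1c")


def render_chart(chart: RiskChart, format: str = "text") -> str:
    """Render a chart for humans: one panel per stratum, rows displayed
    highest BP first, cells annotated (text) or colored (html) by band."""
    if format == "text":
        return _render_text(chart)
    if format == "html":
        return _render_html(chart)
    raise ValueError(f"unknown render format {format!r}")


def _render_text(chart: RiskChart) -> str:
    spec = chart.spec
    lines = [
        "Risk bands: " + "  ".join(
            f"{i + 1}={lab}" for i, lab in enumerate(spec.band_labels)
        ),
    ]
    col_labels = (spec.column_axis.categories if spec.is_2d
                  else ("risk",))
    for key in spec.stratum_keys():
        head = "|".join(
            f"{f.name}={lab}" for f, lab in zip(spec.stratifiers, key)
        )
        lines.append(f"== block {head} ==")
        lines.append(f"{spec.row_axis.name}\\{'|'.join(col_labels)}")
        genes = chart.blocks[key]
        for r in range(spec.n_rows - 1, -1, -1):  # highest BP first
            row_lab = spec.row_axis.categories[r]
            cells = " ".join(str(int(v)) for v in genes[r])
            lines.append(f"row {spec.row_axis.name}={row_lab}: {cells}")
    return "\n".join(lines) + "\n"


def parse_text_chart(text: str, spec: ChartSpec) -> RiskChart:
    """Inverse of the text renderer (used to check rendering is lossless)."""
    blocks: dict[tuple[str, ...], np.ndarray] = {}
    current: Optional[tuple[str, ...]] = None
    rows: dict[int, list[int]] = {}

    def flush():
        if current is not None:
            genes = np.array([rows[r] for r in range(spec.n_rows)],
                             dtype=np.int64)
            blocks[current] = genes

    for line in text.splitlines():
        line = line.strip()
        if line.startswith("== block"):
            flush()
            head = line[len("== block"):].strip().rstrip("=").strip()
            current = tuple(part.split("=", 1)[1]
                            for part in head.split("|")) if head else ()
            rows = {}
        elif line.startswith("row "):
            lab_part, cells = line[4:].split(":", 1)
            row_lab = lab_part.split("=", 1)[1]
            r = spec.row_axis.categories.index(row_lab)
            rows[r] = [int(x) for x in cells.split()]
    flush()
    chart = RiskChart(spec, blocks)
    chart.validate()
    return chart


def _render_html(chart: RiskChart) -> str:
    spec = chart.spec
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<style>table{border-collapse:collapse;margin:8px}"
        "td,th{border:1px solid #444;padding:3px 8px;font:12px sans-serif}"
        "</style></head><body>",
        "<p>Risk bands: " + " ".join(
            f"<span style='background:{c};padding:2px 6px'>{lab}</span>"
            for c, lab in zip(_HTML_COLORS, spec.band_labels)
        ) + "</p>",
    ]
    col_labels = (spec.column_axis.categories if spec.is_2d else ("risk",))
    for key in spec.stratum_keys():
        head = ", ".join(
            f"{f.name}={lab}" for f, lab in zip(spec.stratifiers, key)
        )
        parts.append(f"<h4>{head or 'single block'}</h4><table><tr>"
                     f"<th>{spec.row_axis.name}</th>"
                     + "".join(f"<th>{c}</th>" for c in col_labels) + "</tr>")
        genes = chart.blocks[key]
        for r in range(spec.n_rows - 1, -1, -1):
            cells = "".join(
                f"<td style='background:{_HTML_COLORS[int(v) - 1]}'>"
                f"{spec.band_labels[int(v) - 1]}</td>"
                for v in genes[r]
            )
            parts.append(
                f"<tr><th>{spec.row_axis.categories[r]}</th>{cells}</tr>"
            )
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)
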