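"""Structured QC report generation (JSON + HTML).

A report bundles one omics score card with its percentile rank, category,
per-metric table, provenance and accumulated warnings.  The JSON form is
schema-validated by construction (pydantic model; a JSON Schema export is
shipped alongside the package data) and round-trips losslessly;
regeneration from the same inputs is byte-identical apart from the
timestamp field.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from string import Template
from typing import Any, Mapping, Sequence

from pydantic import BaseModel, Field

from .ranking import PerformanceCategory

__all__ = ["MetricRow", "Provenance", "QCReport", "build_report", "render_html"]

REPORT_SCHEMA_VERSION = "1.0"


class MetricRow(BaseModel):
    name: str
    value: float | int | None = None
    scaled: float | None = None
    note: str | None = None


class Provenance(BaseModel):
    inputs: dict[str, str] = Field(default_factory=dict)
    package: str = "quartet-qc"
    package_version: str = "0.1.0"
    seed: int | None = None
    timestamp: str | None = None


class QCReport(BaseModel):
    schema_version: str = REPORT_SCHEMA_VERSION
    omics: str
    scorecard: dict[str, Any]
    total_score: float
    percentile: float | None = None
    category: str | None = None
    metrics: list[MetricRow] = Field(default_factory=list)
    provenance: Provenance = Field(default_factory=Provenance)
    warnings: list[str] = Field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        return cls.model_validate(json.loads(text))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".html":
            path.write_text(render_html(self))
        else:
            path.write_text(self.to_json())


def build_report(
    omics: str,
    scorecard: Mapping[str, Any],
    total_score: float,
    percentile: float | None = None,
    category: PerformanceCategory | str | None = None,
    metrics: Sequence[MetricRow] | None = None,
    warnings: Sequence[str] = (),
    inputs: Mapping[str, str] | None = None,
    seed: int | None = None,
    timestamp: bool = True,
) -> QCReport:
    """Assemble and validate a QC report.

    ``timestamp=False`` omits the wall-clock field, making the output a
    pure function of its inputs (used by determinism checks).
    """
    if isinstance(category, PerformanceCategory):
        category = category.value
    stamp = (
        _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        if timestamp
        else None
    )
    return QCReport(
        omics=omics,
        scorecard=dict(scorecard),
        total_score=total_score,
        percentile=percentile,
        category=category,
        metrics=list(metrics or []),
        provenance=Provenance(inputs=dict(inputs or {}), seed=seed, timestamp=stamp),
        warnings=list(warnings),
    )


_PAGE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Quartet QC report — $omics</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }
.category { font-size: 1.3em; font-weight: bold; }
.warn { color: #a40; }
</style>
</head>
<body>
<h1>Quartet QC report — $omics</h1>
<p class="category">Total score: $total &nbsp; Percentile: $percentile &nbsp; Category: $category</p>
<h2>Metrics</h2>
<table>
<tr><th>metric</th><th>value</th><th>scaled</th><th>note</th></tr>
$metric_rows
</table>
<h2>Score card</h2>
<pre>$scorecard</pre>
$warning_block
<p><small>Generated by $package $version$stamp</small></p>
</body>
</html>
"""
)


def _fmt(x: Any) -> str:
    if x is None:
        return "—"
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def render_html(report: QCReport) -> str:
    rows = "\n".join(
        f"<tr><td>{m.name}</td><td>{_fmt(m.value)}</td>"
        f"<td>{_fmt(m.scaled)}</td><td>{_fmt(m.note)}</td></tr>"
        for m in report.metrics
    )
    warning_block = ""
    if report.warnings:
        items = "\n".join(f"<li>{w}</li>" for w in report.warnings)
        warning_block = f"<h2>Warnings</h2>\n<ul class=\"warn\">\n{items}\n</ul>"
    prov = report.provenance
    return _PAGE.substitute(
        omics=report.omics,
        total=_fmt(report.total_score),
        percentile=_fmt(report.percentile),
        category=_fmt(report.category),
        metric_rows=rows,
        scorecard=json.dumps(report.scorecard, indent=2, sort_keys=True),
        warning_block=warning_block,
        package=prov.package,
        version=prov.package_version,
        stamp=f" at {prov.timestamp}" if prov.timestamp else "",
    )
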