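"""Metadata "Data Package" loading and validation.

A Data Package is a directory of CSV metadata tables (project, donor,
sample, reference material, library, sequencing, datafile, ...) governed
by a single JSON descriptor (``datapackage.json``) that assigns each table
a schema: field names, types, required flags, enumerations, numeric
ranges and cross-table foreign keys.  Validation walks every table and
returns coded findings — an empty list means the package conforms.

The descriptor dialect is deliberately minimal::

    {
      "name": "...", "version": "...",
      "resources": [
        {"name": "donor", "path": "donor.csv",
         "schema": {"fields": [
            {"name": "donor_id", "type": "string", "required": true},
            {"name": "age", "type": "integer", "min": 0, "max": 120},
            {"name": "sex", "type": "enum", "enum": ["female", "male"]},
            {"name": "project_id", "type": "string",
             "foreign_key": "project.project_id"}]}}
      ]
    }
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

__all__ = [
    "Finding",
    "DataPackage",
    "DataPackageSchemaError",
    "load_datapackage",
    "validate_datapackage",
    "build_demo_datapackage",
    "FINDING_CODES",
]

FINDING_CODES = (
    "MISSING_TABLE",
    "MISSING_COLUMN",
    "MISSING_REQUIRED",
    "TYPE_ERROR",
    "ENUM_VIOLATION",
    "RANGE_VIOLATION",
    "DANGLING_FOREIGN_KEY",
)

_TYPES = {"string", "integer", "number", "date", "enum"}


class DataPackageSchemaError(Exception):
    """The descriptor itself is unreadable or malformed (not a data finding)."""


@dataclass(frozen=True, order=True)
class Finding:
    """One coded validation finding located at (table, row, field)."""

    table: str
    row: int | None
    field: str | None
    code: str
    message: str = ""

    def __str__(self) -> str:
        loc = self.table
        if self.row is not None:
            loc += f"[{self.row}]"
        if self.field:
            loc += f".{self.field}"
        return f"{self.code} at {loc}: {self.message}"


@dataclass
class DataPackage:
    """Named CSV tables plus their per-table field schemas."""

    tables: dict[str, pd.DataFrame]
    schemas: dict[str, list[dict[str, Any]]]
    name: str = "datapackage"
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for table, fields in self.schemas.items():
            names = [f["name"] for f in fields]
            if len(names) != len(set(names)):
                raise DataPackageSchemaError(
                    f"schema for table {table!r} repeats field names"
                )
            for f in fields:
                if f.get("type", "string") not in _TYPES:
                    raise DataPackageSchemaError(
                        f"{table}.{f['name']}: unknown type {f.get('type')!r}"
                    )


def load_datapackage(directory: str | Path) -> DataPackage:
    """Load a Data Package directory via its ``datapackage.json`` descriptor.

    CSV cells are read as strings; empty cells mean missing.
    """
    directory = Path(directory)
    descriptor_path = directory / "datapackage.json"
    try:
        descriptor = json.loads(descriptor_path.read_text())
        resources = descriptor["resources"]
    except (OSError, json.JSONDecodeError, KeyError) as exc:
        raise DataPackageSchemaError(
            f"cannot read descriptor {descriptor_path}: {exc}"
        ) from exc

    tables: dict[str, pd.DataFrame] = {}
    schemas: dict[str, list[dict[str, Any]]] = {}
    for res in resources:
        try:
            name = res["name"]
            schemas[name] = res["schema"]["fields"]
            path = directory / res.get("path", f"{name}.csv")
        except (KeyError, TypeError) as exc:
            raise DataPackageSchemaError(f"malformed resource entry: {res}") from exc
        if path.exists():
            tables[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    return DataPackage(
        tables=tables,
        schemas=schemas,
        name=descriptor.get("name", "datapackage"),
        version=descriptor.get("version", "unversioned"),
    )


def _check_type(value: str, ftype: str) -> bool:
    if ftype in ("string", "enum"):
        return True
    if ftype == "integer":
        try:
            int(value)
        except ValueError:
            return False
        return True
    if ftype == "number":
        try:
            float(value)
        except ValueError:
            return False
        return True
    if ftype == "date":
        try:
            _dt.date.fromisoformat(value)
        except ValueError:
            return False
        return True
    raise DataPackageSchemaError(f"unknown type {ftype!r}")


def validate_datapackage(pkg: DataPackage) -> list[Finding]:
    """Validate every table against its schema; empty list == conformant.

    Checks, in order per field: presence of the column; required cells
    non-empty; type conformance; enumeration membership; numeric range;
    foreign-key resolution against the target table's column values.
    """
    findings: list[Finding] = []
    for table, fields in pkg.schemas.items():
        if table not in pkg.tables:
            findings.append(
                Finding(table, None, None, "MISSING_TABLE", "table file absent")
            )
            continue
        frame = pkg.tables[table]
        for f in fields:
            fname = f["name"]
            ftype = f.get("type", "string")
            if fname not in frame.columns:
                findings.append(
                    Finding(table, None, fname, "MISSING_COLUMN", "column absent")
                )
                continue
            fk_values: set[str] | None = None
            if "foreign_key" in f:
                target_table, target_field = f["foreign_key"].split(".", 1)
                target = pkg.tables.get(target_table)
                if target is not None and target_field in target.columns:
                    fk_values = set(target[target_field])
                else:
                    fk_values = set()
            for row, value in enumerate(frame[fname]):
                value = value.strip()
                if value == "":
                    if f.get("required", False):
                        findings.append(
                            Finding(
                                table, row, fname, "MISSING_REQUIRED",
                                "required cell is empty",
                            )
                        )
                    continue
                if not _check_type(value, ftype):
                    findings.append(
                        Finding(
                            table, row, fname, "TYPE_ERROR",
                            f"{value!r} is not a valid {ftype}",
                        )
                    )
                    continue
                if ftype == "enum" and value not in f.get("enum", []):
                    findings.append(
                        Finding(
                            table, row, fname, "ENUM_VIOLATION",
                            f"{value!r} not in {f.get('enum', [])}",
                        )
                    )
                    continue
                if ftype in ("integer", "number"):
                    x = float(value)
                    lo, hi = f.get("min"), f.get("max")
                    if (lo is not None and x < lo) or (hi is not None and x > hi):
                        findings.append(
                            Finding(
                                table, row, fname, "RANGE_VIOLATION",
                                f"{value} outside [{lo}, {hi}]",
                            )
                        )
                        continue
                if fk_values is not None and value not in fk_values:
                    findings.append(
                        Finding(
                            table, row, fname, "DANGLING_FOREIGN_KEY",
                            f"{value!r} unresolved in {f['foreign_key']}",
                        )
                    )
    return sorted(findings, key=lambda f: (f.table, f.field or "", (-1 if f.row is None else f.row)))


# --------------------------------------------------------------------------
# Demonstration fixture: a small conformant package with optional planted
# defects, used by the test suite and the worked examples.

_DEMO_SCHEMAS: dict[str, list[dict[str, Any]]] = {
    "project": [
        {"name": "project_id", "type": "string", "required": True},
        {"name": "title", "type": "string"},
        {"name": "start_date", "type": "date"},
    ],
    "donor": [
        {"name": "donor_id", "type": "string", "required": True},
        {"name": "sex", "type": "enum", "enum": ["female", "male"]},
        {"name": "age", "type": "integer", "min": 0, "max": 120},
    ],
    "reference_material": [
        {"name": "material_id", "type": "string", "required": True},
        {
            "name": "omics",
            "type": "enum",
            "enum": ["genomics", "transcriptomics", "proteomics", "metabolomics"],
        },
        {"name": "lot", "type": "string"},
    ],
    "sample": [
        {"name": "sample_id", "type": "string", "required": True},
        {
            "name": "donor_id",
            "type": "string",
            "required": True,
            "foreign_key": "donor.donor_id",
        },
        {
            "name": "material_id",
            "type": "string",
            "foreign_key": "reference_material.material_id",
        },
        {
            "name": "sample_type",
            "type": "enum",
            "enum": ["DNA", "RNA", "protein", "metabolite"],
        },
    ],
    "library": [
        {"name": "library_id", "type": "string", "required": True},
        {
            "name": "sample_id",
            "type": "string",
            "required": True,
            "foreign_key": "sample.sample_id",
        },
        {"name": "insert_size", "type": "integer", "min": 0},
    ],
    "sequencing": [
        {"name": "run_id", "type": "string", "required": True},
        {
            "name": "library_id",
            "type": "string",
            "required": True,
            "foreign_key": "library.library_id",
        },
        {"name": "platform", "type": "string", "required": True},
        {"name": "run_date", "type": "date"},
    ],
    "datafile": [
        {"name": "file_id", "type": "string", "required": True},
        {
            "name": "run_id",
            "type": "string",
            "required": True,
            "foreign_key": "sequencing.run_id",
        },
        {"name": "path", "type": "string"},
        {"name": "size_gb", "type": "number", "min": 0},
    ],
}


def _demo_tables() -> dict[str, pd.DataFrame]:
    donors = ["D5", "D6", "F7", "M8"]
    return {
        "project": pd.DataFrame(
            {
                "project_id": ["QP-1"],
                "title": ["Quartet reference-material batch"],
                "start_date": ["2023-06-01"],
            }
        ),
        "donor": pd.DataFrame(
            {
                "donor_id": donors,
                "sex": ["female", "female", "male", "female"],
                "age": ["28", "28", "55", "53"],
            }
        ),
        "reference_material": pd.DataFrame(
            {
                "material_id": [f"RM-{d}" for d in donors],
                "omics": ["genomics"] * 4,
                "lot": ["lot-2023A"] * 4,
            }
        ),
        "sample": pd.DataFrame(
            {
                "sample_id": [f"S-{d}" for d in donors],
                "donor_id": donors,
                "material_id": [f"RM-{d}" for d in donors],
                "sample_type": ["DNA"] * 4,
            }
        ),
        "library": pd.DataFrame(
            {
                "library_id": [f"L-{d}" for d in donors],
                "sample_id": [f"S-{d}" for d in donors],
                "insert_size": ["350"] * 4,
            }
        ),
        "sequencing": pd.DataFrame(
            {
                "run_id": [f"R-{d}" for d in donors],
                "library_id": [f"L-{d}" for d in donors],
                "platform": ["NovaSeq 6000"] * 4,
                "run_date": ["2023-06-15"] * 4,
            }
        ),
        "datafile": pd.DataFrame(
            {
                "file_id": [f"FQ-{d}" for d in donors],
                "run_id": [f"R-{d}" for d in donors],
                "path": [f"fastq/{d}_R1.fastq.gz" for d in donors],
                "size_gb": ["42.5"] * 4,
            }
        ),
    }


def build_demo_datapackage(
    directory: str | Path, violations: Sequence[str] = ()
) -> list[Finding]:
    """Write a small demonstration Data Package, optionally with defects.

    ``violations`` names finding codes to plant (each at a fixed,
    documented location); the returned list is exactly the findings
    :func:`validate_datapackage` must report for the written package.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = _demo_tables()
    expected: list[Finding] = []

    for code in violations:
        if code == "DANGLING_FOREIGN_KEY":
            tables["sample"].loc[0, "donor_id"] = "D9"
            expected.append(
                Finding(
                    "sample", 0, "donor_id", "DANGLING_FOREIGN_KEY",
                    "'D9' unresolved in donor.donor_id",
                )
            )
        elif code == "MISSING_COLUMN":
            tables["sequencing"] = tables["sequencing"].drop(columns=["platform"])
            expected.append(
                Finding("sequencing", None, "platform", "MISSING_COLUMN", "column absent")
            )
        elif code == "MISSING_REQUIRED":
            tables["datafile"].loc[0, "file_id"] = ""
            expected.append(
                Finding(
                    "datafile", 0, "file_id", "MISSING_REQUIRED",
                    "required cell is empty",
                )
            )
        elif code == "TYPE_ERROR":
            tables["donor"].loc[2, "age"] = "fifty-five"
            expected.append(
                Finding(
                    "donor", 2, "age", "TYPE_ERROR",
                    "'fifty-five' is not a valid integer",
                )
            )
        elif code == "ENUM_VIOLATION":
            tables["sample"].loc[1, "sample_type"] = "tissue"
            expected.append(
                Finding(
                    "sample", 1, "sample_type", "ENUM_VIOLATION",
                    "'tissue' not in ['DNA', 'RNA', 'protein', 'metabolite']",
                )
            )
        elif code == "RANGE_VIOLATION":
            tables["donor"].loc[3, "age"] = "200"
            expected.append(
                Finding("donor", 3, "age", "RANGE_VIOLATION", "200 outside [0, 120]")
            )
        elif code == "MISSING_TABLE":
            tables.pop("datafile")
            expected.append(
                Finding("datafile", None, None, "MISSING_TABLE", "table file absent")
            )
        else:
            raise ValueError(f"unknown violation code {code!r}")

    descriptor = {
        "name": "quartet-demo",
        "version": "1.0",
        "resources": [
            {"name": name, "path": f"{name}.csv", "schema": {"fields": fields}}
            for name, fields in _DEMO_SCHEMAS.items()
        ],
    }
    (directory / "datapackage.json").write_text(
        json.dumps(descriptor, indent=2) + "\n"
    )
    for name, frame in tables.items():
        frame.to_csv(directory / f"{name}.csv", index=False)
    return sorted(expected, key=lambda f: (f.table, f.field or "", (-1 if f.row is None else f.row)))
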