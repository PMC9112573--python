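"""Cohort file I/O: CSV data with a JSON sidecar schema.

The CSV dialect is fixed (comma-separated, UTF-8, header row, empty cell =
missing) so round-trips are value-identical including missingness.  The
schema file names every predictor's kind (and levels), the outcome and
region columns, and the region label set.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, Predictor, PredictorSchema
from .exceptions import SchemaError


def write_schema(schema: PredictorSchema, path) -> None:
    doc = {
        "predictors": [
            {"name": p.name, "kind": p.kind,
             "levels": list(p.levels) if p.levels else None, "spline": p.spline}
            for p in schema.predictors
        ],
        "y_cont": schema.y_cont,
        "y_bin": schema.y_bin,
        "region": schema.region,
        "patient_id": schema.patient_id,
        "regions": list(schema.regions),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_schema(path) -> PredictorSchema:
    doc = json.loads(Path(path).read_text())
    preds = tuple(
        Predictor(p["name"], p["kind"],
                  tuple(p["levels"]) if p.get("levels") else None, p.get("spline", False))
        for p in doc["predictors"]
    )
    return PredictorSchema(predictors=preds, y_cont=doc["y_cont"], y_bin=doc["y_bin"],
                           region=doc["region"], patient_id=doc["patient_id"],
                           regions=tuple(doc["regions"]))


def write_cohort(table: CohortTable, csv_path, schema_path=None) -> None:
    table.data.to_csv(csv_path, index=False, na_rep="")
    if schema_path is not None:
        write_schema(table.schema, schema_path)


def read_cohort(csv_path, schema_path) -> CohortTable:
    """Read and validate a cohort against its schema.

    Raises :class:`SchemaError` with row numbers for out-of-range outcomes,
    unknown region labels or levels, and duplicate patient ids.
    """
    schema = read_schema(schema_path)
    df = pd.read_csv(csv_path)
    expected = [schema.patient_id] + schema.names + [schema.region, schema.y_cont, schema.y_bin]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file lacks columns {missing}")
    n_pred = len(schema.predictors)
    if len([c for c in df.columns if c in schema.names]) != n_pred:
        raise SchemaError(f"expected {n_pred} predictor columns")
    dup = df[schema.patient_id].duplicated()
    if dup.any():
        raise SchemaError(f"duplicate patient_id at rows {list(df.index[dup][:5])}")
    yc = df[schema.y_cont]
    bad = yc.notna() & ((yc < 0) | (yc > 27))
    if bad.any():
        raise SchemaError(f"continuous outcome outside [0, 27] at rows {list(df.index[bad][:5])}")
    yb = df[schema.y_bin]
    badb = yb.notna() & ~yb.isin([0, 1])
    if badb.any():
        raise SchemaError(f"binary outcome not in {{0,1}} at rows {list(df.index[badb][:5])}")
    unknown_region = df[schema.region].isna() | ~df[schema.region].isin(schema.regions)
    if unknown_region.any():
        raise SchemaError(f"missing/unknown region at rows {list(df.index[unknown_region][:5])}")
    for p in schema.predictors:
        if p.kind in ("continuous", "binary"):
            df[p.name] = pd.to_numeric(df[p.name], errors="coerce").astype(float)
        else:
            df[p.name] = df[p.name].astype(object)
            vals = df[p.name].dropna()
            unknown = set(vals) - set(p.levels)
            if unknown:
                rows = list(df.index[df[p.name].isin(unknown)][:5])
                raise SchemaError(f"unknown levels {sorted(unknown)} in {p.name!r} at rows {rows}")
            df.loc[df[p.name].isna(), p.name] = np.nan
    df[schema.y_cont] = df[schema.y_cont].astype(float)
    df[schema.y_bin] = df[schema.y_bin].astype(float)
    table = CohortTable(df, schema)
    table.validate()
    return table
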