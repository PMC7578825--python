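"""CSV readers and result serialization.

CSV schemas (all with a header row):

* diet:     ``individual_id,group,prey_taxon,count,mass``
* isotopes: ``sample_id,group,d13C,d15N[,SL]``
* sources:  ``source_name,tracer,mean,sd,tef_mean,tef_sd`` (long format, one
  row per source x tracer; the tracer set must be identical across sources)
* fullness: ``individual_id,group,season,time_h,ff[,Wt,Wgut,Wg]``

Isotope values are always ‰ (δ13C vs VPDB, δ15N vs atmospheric N₂), masses
grams, lengths mm. Group/taxon order follows first appearance in the file and
is preserved in every downstream pairwise output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DietMatrix,
    FullnessTable,
    IsotopeTable,
    MixResult,
    SchemaError,
    SourceSet,
    ValidationError,
)


def read_diet_csv(path: str | Path) -> DietMatrix:
    """Read and validate a per-individual gut-content table."""
    return DietMatrix(pd.read_csv(path))


def read_isotope_csv(path: str | Path) -> IsotopeTable:
    """Read and validate a per-sample isotope table."""
    return IsotopeTable(pd.read_csv(path))


def read_fullness_csv(path: str | Path) -> FullnessTable:
    """Read and validate a gut-fullness observation table."""
    return FullnessTable(pd.read_csv(path))


def read_sources_csv(path: str | Path) -> SourceSet:
    """Read a long-format source-signature table into a :class:`SourceSet`."""
    df = pd.read_csv(path)
    required = ["source_name", "tracer", "mean", "sd", "tef_mean", "tef_sd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"sources: missing column(s) {missing!r}")
    names = list(dict.fromkeys(df["source_name"]))
    tracers = list(dict.fromkeys(df["tracer"]))
    arrays = {k: np.full((len(names), len(tracers)), np.nan) for k in
              ("mean", "sd", "tef_mean", "tef_sd")}
    for _, row in df.iterrows():
        i, j = names.index(row["source_name"]), tracers.index(row["tracer"])
        for k in arrays:
            arrays[k][i, j] = float(row[k])
    if any(np.isnan(a).any() for a in arrays.values()):
        raise ValidationError("sources: tracer set differs across sources")
    return SourceSet(names=names, tracers=tracers, **arrays)


def write_sources_csv(src: SourceSet, path: str | Path) -> None:
    rows = []
    for i, name in enumerate(src.names):
        for j, tracer in enumerate(src.tracers):
            rows.append(
                dict(source_name=name, tracer=tracer, mean=src.mean[i, j],
                     sd=src.sd[i, j], tef_mean=src.tef_mean[i, j],
                     tef_sd=src.tef_sd[i, j])
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# result serialization


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "_type": type(obj).__name__,
            **{k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()},
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(result, path: str | Path, format: str = "json") -> None:
    """Serialize any result dataclass to JSON or CSV.

    JSON round-trips losslessly through :func:`read_results_json`. The CSV
    form is tabular: one row per source for :class:`MixResult`, otherwise one
    row of fields. Floats are written with 9 significant digits.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(result), indent=1) + "\n")
    elif format == "csv":
        if isinstance(result, MixResult):
            df = pd.DataFrame(
                {
                    "source": result.sources,
                    "posterior_mean": result.posterior_mean,
                    "ci95_low": result.ci95_low,
                    "ci95_high": result.ci95_high,
                }
            )
        elif dataclasses.is_dataclass(result):
            flat = {
                k: v
                for k, v in _to_jsonable(result).items()
                if not isinstance(v, (dict, list)) and k != "_type"
            }
            df = pd.DataFrame([flat])
        elif isinstance(result, pd.DataFrame):
            df = result
        else:
            raise TypeError(f"cannot serialize {type(result).__name__} to csv")
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results_json(path: str | Path):
    """Rebuild a result dataclass written by :func:`write_results`."""
    from . import datatypes

    raw = json.loads(Path(path).read_text())
    name = raw.pop("_type")
    cls = getattr(datatypes, name)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in raw.items():
        if isinstance(v, list) and "ndarray" in str(fields[k].type if k in fields else ""):
            v = np.asarray(v, dtype=float)
        kwargs[k] = v
    return cls(**kwargs)
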