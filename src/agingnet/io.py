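"""Cohort file readers/writers, parameter files, and run reports.

Cohort files are delimited text with a header: columns ``age``, ``d1..dN``
(0/1/NA), ``surv_age``, ``censored``.  Parameter files are the JSON layout
of :meth:`agingnet.model.ModelParameters.to_json`.  Reports are
deterministic JSON (sorted keys) so a rerun with the same inputs produces
identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import CohortRecord
from .validation import MetricResult

__all__ = ["read_cohort", "write_cohort", "write_report", "read_report"]


class CohortFormatError(ValueError):
    """A cohort file violates the format or a row-level invariant."""


def read_cohort(path, sep: str = "\t", na_token: str = "NA") -> list:
    """Parse a cohort file into records, validating row by row.

    All violations are collected and reported with their (1-based, header
    excluded) row numbers.
    """
    df = pd.read_csv(path, sep=sep, na_values=[na_token], keep_default_na=False)
    dcols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    dcols.sort(key=lambda c: int(c[1:]))
    missing = {"age", "surv_age", "censored"} - set(df.columns)
    if missing or not dcols:
        raise CohortFormatError(
            f"missing required columns: {sorted(missing) or 'd1..dN'}")
    records = []
    errors = []
    for row_num, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            deficits = np.array([row[c] for c in dcols], dtype=float)
            records.append(CohortRecord(
                baseline_age=float(row["age"]),
                deficits=deficits,
                survival_age=float(row["surv_age"]),
                censored=int(row["censored"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {row_num}: {exc}")
    if errors:
        raise CohortFormatError("invalid cohort rows:\n" + "\n".join(errors))
    return records


def write_cohort(records: list, path, sep: str = "\t",
                 na_token: str = "NA") -> None:
    n = len(records[0].deficits)
    cols = {"age": [r.baseline_age for r in records]}
    for i in range(n):
        cols[f"d{i + 1}"] = [
            na_token if np.isnan(r.deficits[i]) else int(r.deficits[i])
            for r in records]
    cols["surv_age"] = [r.survival_age for r in records]
    cols["censored"] = [r.censored for r in records]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if isinstance(obj, MetricResult):
        return {"estimate": obj.estimate, "ci_low": obj.ci_low,
                "ci_high": obj.ci_high, "stratum": obj.stratum, "n": obj.n,
                "n_dropped": obj.n_dropped}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path, config: dict | None = None,
                 seed: int | None = None) -> dict:
    """Write metrics + config echo + seed + code version; returns the manifest.

    Output bytes are deterministic for fixed inputs (sorted keys, fixed
    float repr)."""
    from . import __version__
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                     allow_nan=True))
    return manifest


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
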