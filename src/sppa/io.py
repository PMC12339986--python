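"""File formats: point CSVs, WKT/GeoJSON windows, result serialisation.

Points travel as comma-separated UTF-8 CSV with a header
(``transect_id,x,y,taxon``; ``transect_id`` and ``taxon`` optional),
coordinates in metres. Windows travel as WKT POLYGON or GeoJSON Polygon
(shapefiles are out of scope — convert externally). Summary-function
estimates and envelopes are written as CSV with a JSON metadata sidecar;
reports as JSON plus a Markdown summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import shape as shapely_shape

from .geometry import ObservationWindow, PointPattern
from .montecarlo import EnvelopeResult
from .summaries import FunctionEstimate

__all__ = ["read_window", "write_window", "read_pattern_csv",
           "write_pattern_csv", "write_function_estimate", "write_envelope",
           "write_report"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending row/field."""


def read_window(path) -> ObservationWindow:
    """Window from a WKT POLYGON (.wkt/.txt) or GeoJSON Polygon (.json/.geojson)."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty window file")
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        geom = obj.get("geometry", obj)  # accept Feature or bare geometry
        poly = shapely_shape(geom)
    else:
        poly = shapely_wkt.loads(text)
    if poly.geom_type != "Polygon":
        raise FormatError(f"{path}: expected a Polygon, got {poly.geom_type}")
    return ObservationWindow(np.asarray(poly.exterior.coords))


def write_window(window: ObservationWindow, path) -> None:
    Path(path).write_text(window.to_wkt() + "\n")


def read_pattern_csv(path, window, transect_id=None,
                     allow_duplicates: bool = False) -> PointPattern:
    """Validated point pattern from a CSV of annotations.

    ``window`` may be an :class:`ObservationWindow` or a path to one.
    Out-of-window points are rejected with their row numbers; missing
    columns and non-numeric coordinates raise a :class:`FormatError`
    naming the problem.
    """
    if not isinstance(window, ObservationWindow):
        window = read_window(window)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if transect_id is not None and "transect_id" in df.columns:
        df = df[df["transect_id"].astype(str) == str(transect_id)]
    if len(df) == 0:
        raise FormatError(f"{path}: no rows"
                          + (f" for transect {transect_id!r}" if transect_id
                             else ""))
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise FormatError(f"{path}: non-numeric {col!r} at rows {bad}")
    x = df["x"].astype(float).to_numpy()
    y = df["y"].astype(float).to_numpy()
    inside = window.contains(x, y)
    if not np.all(inside):
        rows = df.index[~inside].tolist()
        raise FormatError(f"{path}: points outside the window at rows {rows}")
    marks = None
    if "taxon" in df.columns and not df["taxon"].isna().all():
        marks = df["taxon"].astype(str).tolist()
    return PointPattern(x, y, window, marks=marks,
                        allow_duplicates=allow_duplicates)


def write_pattern_csv(pattern: PointPattern, path, transect_id="t1") -> None:
    df = pd.DataFrame({"transect_id": transect_id,
                       "x": pattern.x, "y": pattern.y})
    if pattern.marks is not None:
        df["taxon"] = list(pattern.marks)
    df.to_csv(path, index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def write_function_estimate(est: FunctionEstimate, path) -> None:
    """CSV (r, value) plus a ``.meta.json`` sidecar with the metadata."""
    path = Path(path)
    est.to_frame().to_csv(path, index=False)
    meta = {"variant": est.variant, "correction": est.correction,
            "smoothing_bandwidth": est.smoothing_bandwidth,
            "type_pair": est.type_pair, **est.metadata}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, default=_json_default, indent=1))


def write_envelope(env: EnvelopeResult, path) -> None:
    """CSV (r, obs, lo, hi) plus a JSON sidecar with the excursion list."""
    path = Path(path)
    env.to_frame().to_csv(path, index=False)
    meta = {"n_sim": env.n_sim, "rank": env.rank, "model": env.model,
            "excursions": [list(e) for e in env.excursions]}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, default=_json_default, indent=1))


def write_report(report, out_dir, stem="report") -> dict:
    """Write an :class:`AnalysisReport` as JSON + Markdown; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / f"{stem}.json"
    mpath = out / f"{stem}.md"
    jpath.write_text(json.dumps(report.to_dict(), default=_json_default,
                                indent=1))
    mpath.write_text(report.to_markdown() + "\n")
    return {"json": str(jpath), "markdown": str(mpath)}
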