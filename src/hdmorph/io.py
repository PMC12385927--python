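"""Readers, writers and configuration.

Contours travel as GeoJSON FeatureCollections (closed boundaries as Polygon
exterior rings, open arcs as LineStrings; µm units declared in feature
properties since GeoJSON has no unit field) or as flat CSV point lists.
Measurements, feature tables and cohort statistics are plain CSV (comma
separator, UTF-8, header row, ``.`` decimal); reports rounded for display
use three decimals, applied only here at the reporting layer.  Run logs are
JSON records of parameters, package versions and the seed, with no
timestamps so identical runs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import ALL_LAYERS, Contour, LayerDelineation, SpecimenMeasurement
from .simulate import CohortParameters, LayerEffect

__all__ = [
    "SpecimenContours",
    "RunConfig",
    "write_contours_geojson",
    "read_contours_geojson",
    "write_contours_csv",
    "read_contours_csv",
    "measurements_frame",
    "features_frame",
    "write_cohort_table",
    "load_config",
    "cohort_params_from_config",
    "write_run_log",
]

CONTOUR_CSV_COLUMNS = [
    "patient_id",
    "specimen_id",
    "segment",
    "layer",
    "boundary",
    "point_index",
    "x_um",
    "y_um",
]


@dataclass
class SpecimenContours:
    """One specimen's delineations with identifying metadata."""

    patient_id: str
    specimen_id: str
    segment: str
    delineations: list[LayerDelineation]


@dataclass
class RunConfig:
    """Shared run-time options for the command-line pipeline."""

    spacing_um: float = 14.0
    level: float = 0.95
    policy: str = "ratio_priority"
    seed: int = 0
    out_dir: Path = Path(".")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must be in (0, 1)")
        self.out_dir = Path(self.out_dir)


# ---------------------------------------------------------------------------
# GeoJSON contours
# ---------------------------------------------------------------------------


def _feature(meta, delin: LayerDelineation, boundary: str, contour: Contour) -> dict:
    if contour.closed:
        ring = contour.points.tolist()
        ring.append(ring[0])  # GeoJSON rings repeat the first position
        geometry = {"type": "Polygon", "coordinates": [ring]}
    else:
        geometry = {"type": "LineString", "coordinates": contour.points.tolist()}
    return {
        "type": "Feature",
        "geometry": geometry,
        "properties": {
            "patient_id": meta.patient_id,
            "specimen_id": meta.specimen_id,
            "segment": meta.segment,
            "layer": delin.layer,
            "boundary": boundary,
            "units": "um",
        },
    }


def write_contours_geojson(specimens: Iterable, path: str | Path) -> None:
    """Write specimens (any objects with the SpecimenContours fields)."""
    features = []
    for spec in specimens:
        for delin in spec.delineations:
            features.append(_feature(spec, delin, "inner", delin.inner))
            features.append(_feature(spec, delin, "outer", delin.outer))
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection), encoding="utf-8")


def read_contours_geojson(path: str | Path) -> list[SpecimenContours]:
    """Read a contour FeatureCollection back into specimen delineations."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if raw.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    grouped: dict[tuple, dict[str, dict[str, Contour]]] = {}
    for i, feat in enumerate(raw.get("features", [])):
        try:
            props = feat["properties"]
            geom = feat["geometry"]
            key = (props["patient_id"], props["specimen_id"], props["segment"])
            layer, boundary = props["layer"], props["boundary"]
            if geom["type"] == "Polygon":
                contour = Contour(np.asarray(geom["coordinates"][0]), closed=True, label=layer)
            elif geom["type"] == "LineString":
                contour = Contour(np.asarray(geom["coordinates"]), closed=False, label=layer)
            else:
                raise ValueError(f"unsupported geometry type {geom['type']!r}")
        except (KeyError, TypeError, IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed feature #{i}: {exc}") from exc
        grouped.setdefault(key, {}).setdefault(layer, {})[boundary] = contour

    specimens = []
    for (pid, sid, seg), layers in grouped.items():
        delins = []
        for layer, pair in layers.items():
            if "inner" not in pair or "outer" not in pair:
                raise ValueError(
                    f"{path}: specimen {sid!r} layer {layer!r} lacks an inner/outer pair"
                )
            delins.append(LayerDelineation(layer, pair["inner"], pair["outer"]))
        delins.sort(key=lambda d: ALL_LAYERS.index(d.layer) if d.layer in ALL_LAYERS else 99)
        specimens.append(SpecimenContours(pid, sid, seg, delins))
    specimens.sort(key=lambda s: (s.patient_id, s.specimen_id))
    return specimens


# ---------------------------------------------------------------------------
# CSV contours
# ---------------------------------------------------------------------------


def write_contours_csv(specimens: Iterable, path: str | Path) -> None:
    """Flat point-list export; closed contours repeat their first point."""
    rows = []
    for spec in specimens:
        for delin in spec.delineations:
            for boundary, contour in (("inner", delin.inner), ("outer", delin.outer)):
                pts = contour.vertices_with_closure if contour.closed else contour.points
                for idx, (x, y) in enumerate(pts):
                    rows.append(
                        (spec.patient_id, spec.specimen_id, spec.segment,
                         delin.layer, boundary, idx, x, y)
                    )
    pd.DataFrame(rows, columns=CONTOUR_CSV_COLUMNS).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> list[SpecimenContours]:
    """Read the flat CSV point-list format.

    A contour whose last point repeats its first is treated as closed.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CONTOUR_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    grouped: dict[tuple, dict[str, dict[str, Contour]]] = {}
    keys = ["patient_id", "specimen_id", "segment", "layer", "boundary"]
    for (pid, sid, seg, layer, boundary), g in frame.groupby(keys, sort=True):
        g = g.sort_values("point_index")
        pts = g[["x_um", "y_um"]].to_numpy(dtype=float)
        closed = len(pts) > 3 and np.allclose(pts[0], pts[-1])
        contour = Contour(pts, closed=closed, label=str(layer))
        grouped.setdefault((pid, sid, seg), {}).setdefault(str(layer), {})[str(boundary)] = contour
    specimens = []
    for (pid, sid, seg), layers in grouped.items():
        delins = []
        for layer, pair in layers.items():
            if "inner" not in pair or "outer" not in pair:
                raise ValueError(f"{path}: specimen {sid!r} layer {layer!r} lacks a boundary pair")
            delins.append(LayerDelineation(layer, pair["inner"], pair["outer"]))
        delins.sort(key=lambda d: ALL_LAYERS.index(d.layer) if d.layer in ALL_LAYERS else 99)
        specimens.append(SpecimenContours(str(pid), str(sid), str(seg), delins))
    specimens.sort(key=lambda s: (s.patient_id, s.specimen_id))
    return specimens


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def measurements_frame(measurements: Iterable[SpecimenMeasurement]) -> pd.DataFrame:
    """Long table: one row per specimen-layer, mm-based units."""
    rows = []
    for m in measurements:
        for layer, lm in m.layers.items():
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "specimen_id": m.specimen_id,
                    "segment": m.segment,
                    "layer": layer,
                    "mean_thickness_mm": lm.mean_thickness,
                    "sd_thickness_mm": lm.sd_thickness,
                    "area_mm2": lm.area,
                    "inner_length_mm": lm.inner_length,
                    "outer_length_mm": lm.outer_length,
                    "n_samples": lm.n_samples,
                    "coverage_fraction": lm.coverage_fraction,
                    "n_fallback": lm.n_fallback,
                }
            )
    return pd.DataFrame(rows)


def features_frame(measurements: Iterable[SpecimenMeasurement]) -> pd.DataFrame:
    """Wide table: one row per specimen with the cohort-analysis features."""
    rows = []
    for m in measurements:
        row: dict = {
            "patient_id": m.patient_id,
            "specimen_id": m.specimen_id,
            "segment": m.segment,
        }
        row.update(m.to_features())
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(table: pd.DataFrame, path: str | Path, decimals: int = 3) -> None:
    """Write a cohort statistics table rounded for reporting.

    P-values keep more digits than the measurement columns so significance
    below 0.001 stays visible.
    """
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(6 if col in ("p", "shapiro_p") else decimals)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and run logs
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return raw


def cohort_params_from_config(config: Mapping) -> CohortParameters:
    """Build :class:`CohortParameters` from a configuration mapping.

    Recognised keys mirror the dataclass fields; ``layer_effects`` may remap
    any layer to a ``{aganglionic_mean, aganglionic_sd, diff_mean, diff_sd}``
    mapping (unlisted layers keep their defaults).
    """
    kwargs = dict(config)
    effects = kwargs.pop("layer_effects", None)
    base = CohortParameters()
    if effects is not None:
        merged = dict(base.layer_effects)
        for layer, eff in effects.items():
            if layer not in merged:
                raise ValueError(f"unknown layer {layer!r} in layer_effects")
            merged[layer] = LayerEffect(**eff) if isinstance(eff, Mapping) else eff
        kwargs["layer_effects"] = merged
    for key in ("folding_effect", "ratio_effect"):
        eff = kwargs.get(key)
        if isinstance(eff, Mapping):
            kwargs[key] = LayerEffect(**eff)
    valid = {f.name for f in dataclasses.fields(CohortParameters)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return CohortParameters(**kwargs)


def write_run_log(path: str | Path, command: str, params: Mapping, seed: int | None) -> None:
    """Machine-readable record of one pipeline invocation."""
    import scipy
    import shapely

    from . import __version__

    record = {
        "command": command,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed": seed,
        "versions": {
            "hdmorph": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "shapely": shapely.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True), encoding="utf-8")
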