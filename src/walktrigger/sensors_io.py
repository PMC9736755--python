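"""Readers and writers for epoch, fix, prompt and route tables.

Canonical on-disk forms are plain text: CSV with ISO-8601 local timestamps
for epochs/prompts/routes, and GPX 1.1, GeoJSON or CSV for GPS tracks.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from datetime import datetime
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    AccelEpoch,
    FormatError,
    GpsFix,
    PromptEvent,
    PromptKind,
    ValidationError,
    validate_epoch_stream,
    validate_fix_stream,
)

_GPX_NS = "http://www.topografix.com/GPX/1/1"

# conventional horizontal-error scaling when only HDOP is present in a GPX file
_HDOP_UERE_M = 5.0


# ---------------------------------------------------------------- epochs

def read_epochs(path: str | Path, dialect: str = "csv") -> list[AccelEpoch]:
    """Read a 1-minute epoch stream from CSV.

    Requires columns ``timestamp, movement_acceleration, steps, worn``;
    rejects non-monotone or off-grid timestamps, naming the first bad row.
    """
    if dialect != "csv":
        raise FormatError(f"unknown epoch dialect {dialect!r}")
    df = pd.read_csv(path)
    required = {"timestamp", "movement_acceleration", "steps", "worn"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"epoch file missing columns: {sorted(missing)}")
    epochs = [
        AccelEpoch(
            timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
            movement_acceleration=float(row.movement_acceleration),
            steps=int(row.steps),
            worn=_as_bool(row.worn),
        )
        for row in df.itertuples(index=False)
    ]
    validate_epoch_stream(epochs)
    return epochs


def write_epochs(epochs: Iterable[AccelEpoch], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp": [e.timestamp.isoformat() for e in epochs],
            "movement_acceleration": [e.movement_acceleration for e in epochs],
            "steps": [e.steps for e in epochs],
            "worn": [e.worn for e in epochs],
        }
    ).to_csv(path, index=False)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


# ---------------------------------------------------------------- GPS fixes

def read_fixes(path: str | Path, dialect: str | None = None) -> list[GpsFix]:
    """Read GPS fixes from GPX 1.1, GeoJSON or CSV; returns a sorted, validated stream.

    The dialect is inferred from the suffix when not given.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".gpx": "gpx", ".geojson": "geojson", ".json": "geojson", ".csv": "csv"}.get(
            path.suffix.lower(), "csv"
        )
    if dialect == "gpx":
        fixes = _read_gpx(path)
    elif dialect == "geojson":
        fixes = _read_geojson(path)
    elif dialect == "csv":
        df = pd.read_csv(path)
        required = {"timestamp", "lat", "lon", "accuracy"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"fix file missing columns: {sorted(missing)}")
        fixes = [
            GpsFix(
                timestamp=pd.Timestamp(r.timestamp).to_pydatetime(),
                lat=float(r.lat),
                lon=float(r.lon),
                accuracy=float(r.accuracy),
            )
            for r in df.itertuples(index=False)
        ]
    else:
        raise FormatError(f"unknown fix dialect {dialect!r}")
    fixes.sort(key=lambda f: f.timestamp)
    validate_fix_stream(fixes)
    return fixes


def _read_gpx(path: Path) -> list[GpsFix]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"not parseable as GPX: {exc}") from exc
    fixes = []
    for pt in root.iter(f"{{{_GPX_NS}}}trkpt"):
        t = pt.find(f"{{{_GPX_NS}}}time")
        if t is None or not t.text:
            raise ValidationError("GPX trackpoint without <time>")
        acc_el = pt.find(f"{{{_GPX_NS}}}extensions/{{{_GPX_NS}}}accuracy")
        if acc_el is not None and acc_el.text:
            accuracy = float(acc_el.text)
        else:
            hdop = pt.find(f"{{{_GPX_NS}}}hdop")
            if hdop is None or not hdop.text:
                raise ValidationError("GPX trackpoint without accuracy extension or <hdop>")
            accuracy = float(hdop.text) * _HDOP_UERE_M
        fixes.append(
            GpsFix(
                timestamp=datetime.fromisoformat(t.text.replace("Z", "")),
                lat=float(pt.get("lat")),
                lon=float(pt.get("lon")),
                accuracy=accuracy,
            )
        )
    return fixes


def _read_geojson(path: Path) -> list[GpsFix]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError("GeoJSON fix file must be a FeatureCollection")
    fixes = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        props = feat.get("properties", {}) or {}
        if geom.get("type") != "Point":
            raise FormatError("GeoJSON fix features must be Points")
        if "time" not in props:
            raise ValidationError("GeoJSON fix feature without 'time' property")
        lon, lat = geom["coordinates"][:2]
        fixes.append(
            GpsFix(
                timestamp=datetime.fromisoformat(str(props["time"]).replace("Z", "")),
                lat=float(lat),
                lon=float(lon),
                accuracy=float(props["accuracy"]),
            )
        )
    return fixes


def write_fixes(fixes: Iterable[GpsFix], path: str | Path, dialect: str | None = None) -> None:
    """Write fixes as GPX 1.1 (accuracy in an extension element), GeoJSON or CSV."""
    path = Path(path)
    if dialect is None:
        dialect = {".gpx": "gpx", ".geojson": "geojson", ".json": "geojson"}.get(
            path.suffix.lower(), "csv"
        )
    fixes = list(fixes)
    if dialect == "gpx":
        ET.register_namespace("", _GPX_NS)
        root = ET.Element(f"{{{_GPX_NS}}}gpx", version="1.1", creator="walktrigger")
        seg = ET.SubElement(ET.SubElement(root, f"{{{_GPX_NS}}}trk"), f"{{{_GPX_NS}}}trkseg")
        for f in fixes:
            pt = ET.SubElement(
                seg, f"{{{_GPX_NS}}}trkpt", lat=f"{f.lat:.7f}", lon=f"{f.lon:.7f}"
            )
            ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = f.timestamp.isoformat()
            ext = ET.SubElement(pt, f"{{{_GPX_NS}}}extensions")
            ET.SubElement(ext, f"{{{_GPX_NS}}}accuracy").text = f"{f.accuracy:.2f}"
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    elif dialect == "geojson":
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [round(f.lon, 7), round(f.lat, 7)]},
                    "properties": {"time": f.timestamp.isoformat(), "accuracy": round(f.accuracy, 2)},
                }
                for f in fixes
            ],
        }
        with open(path, "w") as fh:
            json.dump(fc, fh)
    elif dialect == "csv":
        pd.DataFrame(
            {
                "timestamp": [f.timestamp.isoformat() for f in fixes],
                "lat": [round(f.lat, 7) for f in fixes],
                "lon": [round(f.lon, 7) for f in fixes],
                "accuracy": [round(f.accuracy, 2) for f in fixes],
            }
        ).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown fix dialect {dialect!r}")


# ---------------------------------------------------------------- prompts

def read_prompts(path: str | Path) -> list[PromptEvent]:
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "kind", "answered"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"prompt file missing columns: {sorted(missing)}")
    prompts = []
    for r in df.itertuples(index=False):
        sr = getattr(r, "self_report_walking", None)
        sr_val = None if sr is None or pd.isna(sr) else _as_bool(sr)
        prompts.append(
            PromptEvent(
                participant_id=str(r.participant_id),
                timestamp=pd.Timestamp(r.timestamp).to_pydatetime(),
                kind=PromptKind(r.kind),
                answered=_as_bool(r.answered),
                self_report_walking=sr_val,
            )
        )
    return prompts


def write_prompts(prompts: Iterable[PromptEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in prompts],
            "timestamp": [p.timestamp.isoformat() for p in prompts],
            "kind": [p.kind.value for p in prompts],
            "answered": [p.answered for p in prompts],
            "self_report_walking": [
                "" if p.self_report_walking is None else p.self_report_walking for p in prompts
            ],
        }
    ).to_csv(path, index=False)


def write_routes(routes, path: str | Path, participant_id: str = "") -> None:
    """Route summary CSV: route_id, start/end, n_fixes, length, speed."""
    pd.DataFrame(
        {
            "route_id": list(range(len(routes))),
            "participant_id": [participant_id] * len(routes),
            "start": [r.start.isoformat() for r in routes],
            "end": [r.end.isoformat() for r in routes],
            "n_fixes": [len(r.segment.fixes) for r in routes],
            "length_m": [round(r.length, 1) for r in routes],
            "mean_speed_kmh": [round(r.mean_speed, 2) for r in routes],
        }
    ).to_csv(path, index=False)


def routes_to_geojson(routes, path: str | Path) -> None:
    """Optional LineString export of reconstructed routes."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[round(f.lon, 7), round(f.lat, 7)] for f in r.segment.fixes],
                },
                "properties": {
                    "start": r.start.isoformat(),
                    "end": r.end.isoformat(),
                    "length_m": round(r.length, 1),
                    "mean_speed_kmh": round(r.mean_speed, 2),
                },
            }
            for r in routes
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)
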