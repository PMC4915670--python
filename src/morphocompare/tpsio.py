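"""TPS and CSV readers/writers for landmark and distance tables.

TPS records follow the tpsDig layout: ``LM=K`` followed by K coordinate
lines, then optional ``IMAGE=``, ``ID=`` and ``SCALE=`` keys; when SCALE is
present it multiplies the coordinates on read.  The study labels
(species, site, individual, measurer, repeat) are carried in the IMAGE field
joined by ``;``; unknown keys are preserved through a round-trip.  The y
axis is taken as increasing upward (the tpsDig convention); CSV tables are
assumed already Cartesian.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import LABEL_COLUMNS, DistanceDataset, LandmarkDataset, SchemaError

_LABEL_SEP = ";"


class TpsParseError(ValueError):
    """Malformed TPS input, with the offending line number."""


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    lines = []
    for i in range(dataset.n_records):
        lines.append(f"LM={dataset.n_landmarks}")
        for x, y in dataset.coords[i]:
            lines.append(f"{x:.10g} {y:.10g}")
        row = dataset.labels.iloc[i]
        image = _LABEL_SEP.join(str(row[c]) for c in LABEL_COLUMNS)
        lines.append(f"IMAGE={image}")
        lines.append(f"ID={i}")
        lines.append("SCALE=1.0")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tps(path: str | Path, method: str = "GMB",
             landmark_names: list[str] | None = None) -> LandmarkDataset:
    text = Path(path).read_text(encoding="utf-8")
    records: list[dict] = []
    current: dict | None = None
    expect = 0
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        if key.upper() == "LM" and _:
            if current is not None and len(current["coords"]) != current["lm"]:
                raise TpsParseError(
                    f"record starting before line {ln}: LM={current['lm']} but "
                    f"{len(current['coords'])} coordinate lines found")
            current = {"lm": int(val), "coords": [], "keys": {}, "line": ln}
            records.append(current)
            expect = current["lm"]
        elif _ and key.upper() in ("ID", "IMAGE", "SCALE") or (_ and key.isalpha()):
            if current is None:
                raise TpsParseError(f"line {ln}: key {key} before any LM record")
            current["keys"][key.upper()] = val
        else:
            if current is None:
                raise TpsParseError(f"line {ln}: coordinates before LM record")
            parts = line.split()
            if len(parts) != 2:
                raise TpsParseError(f"line {ln}: expected 'x y', got {line!r}")
            if len(current["coords"]) >= expect:
                raise TpsParseError(
                    f"line {ln}: more than LM={expect} coordinate lines in the "
                    f"record starting at line {current['line']}")
            try:
                current["coords"].append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise TpsParseError(f"line {ln}: non-numeric coordinate") from e
    if not records:
        raise TpsParseError("no LM records found")
    k = records[0]["lm"]
    labels_rows = []
    coords = np.empty((len(records), k, 2))
    for i, rec in enumerate(records):
        if len(rec["coords"]) != rec["lm"]:
            name = rec["keys"].get("IMAGE", rec["keys"].get("ID", f"#{i}"))
            raise TpsParseError(
                f"record {name} (line {rec['line']}): LM={rec['lm']} but "
                f"{len(rec['coords'])} coordinate lines")
        if rec["lm"] != k:
            raise SchemaError("mixed landmark counts across TPS records")
        c = np.array(rec["coords"], dtype=float)
        scale = float(rec["keys"].get("SCALE", 1.0))
        coords[i] = c * scale
        image = rec["keys"].get("IMAGE", "")
        parts = image.split(_LABEL_SEP)
        if len(parts) == 5:
            labels_rows.append(dict(zip(LABEL_COLUMNS, parts)))
        else:
            labels_rows.append({"species": "NA", "site": "NA",
                                "individual": image or rec["keys"].get("ID", str(i)),
                                "measurer": "NA", "repeat": 1})
    labels = pd.DataFrame(labels_rows)
    labels["repeat"] = labels["repeat"].astype(int)
    return LandmarkDataset(labels, coords, landmark_names or [], method)


def write_landmarks_csv(dataset: LandmarkDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_landmarks_csv(path: str | Path, method: str = "GMB") -> LandmarkDataset:
    frame = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing label columns {missing}")
    return LandmarkDataset.from_frame(frame, method=method)


def write_distances_csv(dataset: DistanceDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_distances_csv(path: str | Path, method: str = "TRU") -> DistanceDataset:
    frame = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS + ["SL"] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    var_cols = [c for c in frame.columns if c not in LABEL_COLUMNS + ["SL"]]
    bad = frame[var_cols + ["SL"]].apply(
        lambda col: pd.to_numeric(col, errors="coerce")).isna().any(axis=1)
    if bad.any():
        rows = list(frame.index[bad][:5] + 2)  # 1-based, after header
        raise SchemaError(f"{path}: non-numeric measurement values at rows {rows}")
    return DistanceDataset.from_frame(frame, method=method)
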