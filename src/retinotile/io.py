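"""File formats: pattern/RF/trace CSV, connectivity JSON, stimulus TIFF.

All formats are plain text except the stimulus movie, which is a multi-page
TIFF (one page per white-noise frame) with a JSON sidecar carrying the
field geometry.  Readers validate tags and report malformed rows with line
numbers; every write → read round-trip is an identity up to float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .rfmap import ReceptiveField, StimulusEnsemble
from .simgen import ConnectivityRecord, ConnectivitySet
from .tiling import (
    VALID_SPACES,
    VALID_UNITS,
    BootstrapNull,
    MatchResult,
    TilingPattern,
)


# ---------------------------------------------------------------------------
# TilingPattern CSV:  id, x, y, unit, space
# ---------------------------------------------------------------------------

def write_pattern_csv(pattern: TilingPattern, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": pattern.ids,
            "x": pattern.points[:, 0],
            "y": pattern.points[:, 1],
            "unit": pattern.unit,
            "space": pattern.space,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_pattern_csv(path: str | Path) -> TilingPattern:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"id", "x", "y", "unit", "space"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    for col in ("x", "y"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise FormatError(
                f"{path}: non-finite {col!r} at line(s) {[int(i) + 2 for i in bad[:5]]}"
            )
    units = df["unit"].unique()
    spaces = df["space"].unique()
    if len(units) != 1 or units[0] not in VALID_UNITS:
        raise FormatError(
            f"{path}: unit must be one of {list(VALID_UNITS)}, got {list(units)}"
        )
    if len(spaces) != 1 or spaces[0] not in VALID_SPACES:
        raise FormatError(
            f"{path}: space must be one of {list(VALID_SPACES)}, got {list(spaces)}"
        )
    return TilingPattern(
        ids=df["id"].to_numpy(np.int64),
        points=df[["x", "y"]].to_numpy(float),
        unit=str(units[0]),
        space=str(spaces[0]),
    )


# ---------------------------------------------------------------------------
# Receptive-field table CSV
# ---------------------------------------------------------------------------

_RF_COLUMNS = [
    "roi_id", "az", "el", "sd_long", "sd_short", "theta",
    "latency_ms", "size", "amplitude", "on_screen", "fit_ok",
]


def write_rf_csv(rfs: Sequence[ReceptiveField], path: str | Path) -> None:
    rows = [
        {
            "roi_id": rf.roi_id,
            "az": rf.center[0],
            "el": rf.center[1],
            "sd_long": rf.sd_long,
            "sd_short": rf.sd_short,
            "theta": rf.orientation,
            "latency_ms": rf.peak_latency,
            "size": rf.size if rf.fit_ok else np.nan,
            "amplitude": rf.amplitude,
            "on_screen": rf.on_screen,
            "fit_ok": rf.fit_ok,
        }
        for rf in rfs
    ]
    pd.DataFrame(rows, columns=_RF_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_rf_csv(path: str | Path) -> list[ReceptiveField]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_RF_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ReceptiveField(
                center=(float(row["az"]), float(row["el"])),
                sd_long=float(row["sd_long"]),
                sd_short=float(row["sd_short"]),
                orientation=float(row["theta"]),
                amplitude=float(row.get("amplitude", 1.0)),
                peak_latency=float(row["latency_ms"]),
                roi_id=int(row["roi_id"]),
                on_screen=bool(row.get("on_screen", True)),
                fit_ok=bool(row.get("fit_ok", True)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Activity traces CSV:  roi_id, t_index, rate
# ---------------------------------------------------------------------------

def write_traces_csv(
    traces: np.ndarray, roi_ids: Sequence[int], path: str | Path
) -> None:
    n_roi, n_t = traces.shape
    df = pd.DataFrame(
        {
            "roi_id": np.repeat(np.asarray(roi_ids, dtype=np.int64), n_t),
            "t_index": np.tile(np.arange(n_t), n_roi),
            "rate": traces.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_traces_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns ``(traces, roi_ids)`` with traces shaped (n_roi, n_t)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"roi_id", "t_index", "rate"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    pivot = df.pivot(index="roi_id", columns="t_index", values="rate")
    if pivot.isna().any().any():
        raise FormatError(f"{path}: ragged or missing trace samples")
    return pivot.to_numpy(float), pivot.index.to_numpy(np.int64)


# ---------------------------------------------------------------------------
# Connectivity JSON
# ---------------------------------------------------------------------------

def write_connectivity_json(conn: ConnectivitySet, path: str | Path) -> None:
    payload = [
        {
            "sc_id": int(rec.sc_id),
            "axon_ids": [int(a) for a in rec.axon_ids],
            "weights": [float(w) for w in rec.weights],
        }
        for rec in conn
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_connectivity_json(path: str | Path) -> ConnectivitySet:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    records = []
    for i, rec in enumerate(payload):
        try:
            records.append(
                ConnectivityRecord(
                    sc_id=int(rec["sc_id"]),
                    axon_ids=np.asarray(rec["axon_ids"], dtype=np.int64),
                    weights=np.asarray(rec["weights"], dtype=float),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: bad record {i}: {exc}") from exc
    return ConnectivitySet(records=tuple(records))


# ---------------------------------------------------------------------------
# Stimulus TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def stimulus_sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stimulus(stimulus: StimulusEnsemble, tiff_path: str | Path) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stimulus.frames, photometric="minisblack")
    sidecar = {
        "field_w_deg": stimulus.field_w,
        "field_h_deg": stimulus.field_h,
        "rate_hz": stimulus.rate_hz,
        "screen": {"az": stimulus.screen_az, "el": stimulus.screen_el},
        "n_frames": stimulus.n_frames,
    }
    stimulus_sidecar_path(tiff_path).write_text(json.dumps(sidecar, indent=1))


def read_stimulus(tiff_path: str | Path) -> StimulusEnsemble:
    tiff_path = Path(tiff_path)
    sidecar_path = stimulus_sidecar_path(tiff_path)
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: stimulus sidecar not found")
    meta = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(tiff_path)
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        raise FormatError(f"{tiff_path}: expected a multi-page 2D stack")
    if frames.shape[0] != int(meta["n_frames"]):
        raise FormatError(
            f"{tiff_path}: {frames.shape[0]} pages but sidecar declares "
            f"{meta['n_frames']} frames"
        )
    return StimulusEnsemble(
        frames=frames,
        field_w=float(meta["field_w_deg"]),
        field_h=float(meta["field_h_deg"]),
        rate_hz=float(meta["rate_hz"]),
        screen_az=float(meta["screen"]["az"]),
        screen_el=float(meta["screen"]["el"]),
    )


# ---------------------------------------------------------------------------
# Match / bootstrap JSON and sweep CSV
# ---------------------------------------------------------------------------

def write_match_json(
    match: MatchResult,
    path: str | Path,
    bootstrap: BootstrapNull | None = None,
) -> None:
    payload: dict = {
        "fraction": match.fraction,
        "n_common": match.n_common,
        "n_edges_a": match.n_edges_a,
        "n_edges_b": match.n_edges_b,
        "unique_edges_a": match.unique_a.tolist(),
        "unique_edges_b": match.unique_b.tolist(),
    }
    if bootstrap is not None:
        payload["chance"] = {
            "alpha": bootstrap.alpha,
            "threshold": bootstrap.threshold,
            "repetitions": bootstrap.repetitions,
            "seed": bootstrap.seed,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_sweep(sweep, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {
            "param": sweep.grid,
            "median": sweep.median,
            "lo95": sweep.lo95,
            "hi95": sweep.hi95,
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    if json_path is not None:
        meta = {
            "param_name": sweep.param_name,
            "repetitions": sweep.repetitions,
            "seed": sweep.seed,
            "config": vars(sweep.config),
        }
        Path(json_path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
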