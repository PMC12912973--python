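"""Tab-separated file formats, manifests and round-trip helpers.

All tabular artifacts are UTF-8 TSV with '.' decimals. Trajectories carry
the columns ``time_s, position_nm, rodlet_id, end_label, category,
context``; latent phases, fluorescence curves, lattice grids and G2
profiles have their own fixed layouts. Every CLI run writes a JSON
manifest echoing the full configuration, the seed and the package
version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .docklock import ThTCurve
from .errors import FormatError
from .kinetics import EndTrajectory, Phase
from .lattice import CorrelationProfile

TRAJECTORY_COLUMNS = ["time_s", "position_nm", "rodlet_id", "end_label", "category", "context"]
PHASE_COLUMNS = ["rodlet_id", "end_label", "phase_kind", "start_s", "duration_s", "delta_nm"]


def _reprs(values) -> list[str]:
    """Shortest round-trip decimal strings (pandas' own float formatting
    truncates the last digit for some doubles)."""
    return [repr(float(v)) for v in values]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    # float() rather than pandas' fast parser: correctly rounded, so the
    # repr-based writers round-trip exactly
    out = np.empty(len(df), dtype=float)
    for pos, (idx, raw) in enumerate(df[column].items()):
        line = int(idx) + 2  # header line + 1-based
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raise FormatError(f"{path}: empty value in column {column!r} at line {line}")
        try:
            out[pos] = float(raw)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: malformed numeric value in column {column!r} at line {line}"
            ) from None
    return out


def read_trajectories(path) -> list[EndTrajectory]:
    """Read and validate an end-trajectory TSV, one trajectory per
    (rodlet_id, end_label) group, rows sorted by time."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    times = _numeric(df, "time_s", path)
    positions = _numeric(df, "position_nm", path)
    df = df.assign(_t=times, _y=positions)
    out = []
    for (rid, end), grp in df.groupby(["rodlet_id", "end_label"], sort=True):
        grp = grp.sort_values("_t")
        try:
            out.append(
                EndTrajectory(
                    rodlet_id=str(rid),
                    end_label=str(end),
                    category=str(grp["category"].iloc[0]),
                    context=str(grp["context"].iloc[0]),
                    times=grp["_t"].to_numpy(),
                    positions=grp["_y"].to_numpy(),
                )
            )
        except Exception as exc:
            raise FormatError(f"{path}: invalid trajectory ({rid}, {end}): {exc}") from exc
    return out


def write_trajectories(trajs, path) -> None:
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": _reprs(tr.times),
                    "position_nm": _reprs(tr.positions),
                    "rodlet_id": tr.rodlet_id,
                    "end_label": tr.end_label,
                    "category": tr.category,
                    "context": tr.context,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_phases(phases_by_traj: dict[tuple[str, str], list[Phase]], path) -> None:
    """Write latent/detected phases; keys are (rodlet_id, end_label)."""
    rows = []
    for (rid, end), phases in phases_by_traj.items():
        for p in phases:
            rows.append((rid, end, p.kind, repr(float(p.start)), repr(float(p.duration)), repr(float(p.delta))))
    pd.DataFrame(rows, columns=PHASE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phases(path) -> dict[tuple[str, str], list[Phase]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PHASE_COLUMNS, path)
    start = _numeric(df, "start_s", path)
    duration = _numeric(df, "duration_s", path)
    delta = _numeric(df, "delta_nm", path)
    out: dict[tuple[str, str], list[Phase]] = {}
    for n, row in enumerate(df.itertuples(index=False)):
        key = (str(row.rodlet_id), str(row.end_label))
        out.setdefault(key, []).append(Phase(str(row.phase_kind), start[n], duration[n], delta[n]))
    return out


def read_lattice(path) -> np.ndarray:
    """Read a tab-separated integer grid with values in {-1, 0, 1}."""
    path = Path(path)
    try:
        grid = np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=np.int64))
    except ValueError as exc:
        raise FormatError(f"{path}: not a rectangular integer matrix: {exc}") from exc
    if not np.isin(grid, (-1, 0, 1)).all():
        bad = grid[~np.isin(grid, (-1, 0, 1))][0]
        raise FormatError(f"{path}: out-of-alphabet value {bad}")
    return grid.astype(np.int8)


def write_lattice(grid: np.ndarray, path) -> None:
    grid = np.atleast_2d(np.asarray(grid))
    if not np.isin(grid, (-1, 0, 1)).all():
        raise FormatError("grid values must be in {-1, 0, 1}")
    np.savetxt(path, grid, fmt="%d", delimiter="\t")


def read_tht_curve(path, interface_on_at=0.0, seeded=False) -> ThTCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["time_s", "fluorescence_au"], path)
    return ThTCurve(
        times=_numeric(df, "time_s", path),
        fluorescence=_numeric(df, "fluorescence_au", path),
        interface_on_at=interface_on_at,
        seeded=seeded,
    )


def write_tht_curve(curve: ThTCurve, path) -> None:
    pd.DataFrame(
        {"time_s": _reprs(curve.times), "fluorescence_au": _reprs(curve.fluorescence)}
    ).to_csv(path, sep="\t", index=False)


def write_g2_profile(profile: CorrelationProfile, path) -> None:
    pd.DataFrame(
        {"r": profile.r_bins, "G2": profile.G2, "n_pairs": profile.pair_counts}
    ).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(config: dict, seed: int | None, out_dir) -> Path:
    """Write the reproducibility manifest for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rodletkit",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
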