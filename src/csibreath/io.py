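"""CSV/JSON serialisation of CSI tables, ground truth and results.

The CSI table is a plain CSV with one row per sample and the normative
column order ``timestamp_s, tx, rx, subcarrier, freq_hz, re, im``; no
public standard exists for CSI dumps and vendor binary formats are out
of scope.  Ground truth and result summaries travel as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .breath_extract import BreathResult
from .containers import CsiSeries
from .synthetic_csi import SimTruth

CSI_COLUMNS = ["timestamp_s", "tx", "rx", "subcarrier", "freq_hz", "re", "im"]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def write_csi_table(series_map: dict[tuple[int, int, int], CsiSeries], path) -> None:
    frames = []
    for (tx, rx, sub), s in sorted(series_map.items()):
        frames.append(
            pd.DataFrame(
                {
                    "timestamp_s": s.timestamps,
                    "tx": tx,
                    "rx": rx,
                    "subcarrier": sub,
                    "freq_hz": s.freq_hz,
                    "re": s.values.real,
                    "im": s.values.imag,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CSI_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_csi_table(path) -> dict[tuple[int, int, int], CsiSeries]:
    """Read a CSI table; one CsiSeries per (tx, rx, subcarrier) stream.

    Raises :class:`SchemaError` on missing/mistyped columns or
    non-monotone timestamps within a stream (naming the stream and row).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSI_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path}")
    if df.empty:
        return {}
    for col in ("timestamp_s", "freq_hz", "re", "im"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"column {col!r} is not numeric")
    for col in ("tx", "rx", "subcarrier"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise SchemaError(f"column {col!r} is not integer")
        if df.size and (df[col] < 1).any():
            raise SchemaError(f"column {col!r} must be >= 1")

    out: dict[tuple[int, int, int], CsiSeries] = {}
    for (tx, rx, sub), g in df.groupby(["tx", "rx", "subcarrier"], sort=True):
        t = g["timestamp_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = int(g.index[bad[0] + 1])
            raise SchemaError(
                f"timestamps not strictly increasing for stream "
                f"(tx={tx}, rx={rx}, subcarrier={sub}) at file row {row + 2}"
            )
        out[(int(tx), int(rx), int(sub))] = CsiSeries(
            timestamps=t,
            values=g["re"].to_numpy(float) + 1j * g["im"].to_numpy(float),
            link=(int(tx), int(rx)),
            subcarrier=int(sub),
            freq_hz=float(g["freq_hz"].iloc[0]),
        )
    return out


# ----------------------------------------------------------------------
# ground truth sidecar
# ----------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "timestamps": truth.timestamps.tolist(),
        "displacement": truth.displacement.tolist(),
        "transition_times": truth.transition_times.tolist(),
        "true_rate_bpm": truth.true_rate_bpm,
        "motion_mask": truth.motion_mask.astype(int).tolist(),
        "n_full_cycles": truth.n_full_cycles,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> SimTruth:
    try:
        payload = json.loads(Path(path).read_text())
        return SimTruth(
            timestamps=np.asarray(payload["timestamps"], float),
            displacement=np.asarray(payload["displacement"], float),
            transition_times=np.asarray(payload["transition_times"], float),
            true_rate_bpm=float(payload["true_rate_bpm"]),
            motion_mask=np.asarray(payload["motion_mask"], bool),
            n_full_cycles=int(payload.get("n_full_cycles", 0)),
            seed=int(payload.get("seed", 0)),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"invalid truth sidecar {path}: {exc}") from exc


# ----------------------------------------------------------------------
# result directory
# ----------------------------------------------------------------------

def write_result(result: BreathResult, outdir, mask=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wave = pd.DataFrame(
        {
            "timestamp_s": result.timestamps,
            "S": result.waveform,
            "flag": result.flags.astype(int),
        }
    )
    if mask is not None and np.asarray(mask).size == result.timestamps.size:
        wave["interference"] = np.asarray(mask).astype(int)
    wave.to_csv(outdir / "waveform.csv", index=False, float_format="%.10g")
    (outdir / "transitions.json").write_text(
        json.dumps({"transition_times": result.transition_times.tolist()})
    )
    (outdir / "rate.json").write_text(
        json.dumps(
            {
                "rate_bpm": result.rate_bpm,
                "cycle_intervals_s": result.cycle_intervals.tolist(),
                "n_transitions": int(result.transition_times.size),
            }
        )
    )


def read_result(outdir) -> BreathResult:
    outdir = Path(outdir)
    try:
        wave = pd.read_csv(outdir / "waveform.csv")
        trans = json.loads((outdir / "transitions.json").read_text())
        rate = json.loads((outdir / "rate.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"invalid result directory {outdir}: {exc}") from exc
    return BreathResult(
        transition_times=np.asarray(trans["transition_times"], float),
        timestamps=wave["timestamp_s"].to_numpy(float),
        waveform=wave["S"].to_numpy(float),
        flags=wave["flag"].to_numpy(float),
        cycle_intervals=np.asarray(rate["cycle_intervals_s"], float),
        rate_bpm=float(rate["rate_bpm"]),
    )
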