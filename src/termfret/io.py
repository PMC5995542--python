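"""Plain-text readers/writers for traces, manifests and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Trace


def write_trace_tsv(trace: Trace, path) -> None:
    """Trace file: TSV with columns frame, time_s, donor, acceptor."""
    df = pd.DataFrame({
        "frame": trace.frame_index,
        "time_s": np.round(trace.time, 9),
        "donor": np.round(trace.donor, 6),
        "acceptor": np.round(trace.acceptor, 6),
    })
    df.to_csv(path, sep="\t", index=False)


def read_trace_tsv(path, frame_rate: float | None = None) -> Trace:
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "time_s", "donor", "acceptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace file needs columns {sorted(required)}")
    if frame_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        frame_rate = 1.0 / float(np.median(dt)) if dt.size else 30.0
    return Trace(donor=df["donor"].to_numpy(), acceptor=df["acceptor"].to_numpy(),
                 frame_rate=frame_rate, metadata={"source": str(path)})


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_trace_set(traces: list[Trace], manifest: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, trace in enumerate(traces):
        write_trace_tsv(trace, out / f"trace_{i:05d}.tsv")
    write_manifest(manifest, out / "manifest.json")


def read_trace_set(in_dir) -> tuple[list[Trace], dict | None]:
    in_path = Path(in_dir)
    manifest = None
    mpath = in_path / "manifest.json"
    if mpath.exists():
        manifest = read_manifest(mpath)
    frame_rate = (manifest or {}).get("frame_rate")
    traces = []
    for i, f in enumerate(sorted(in_path.glob("trace_*.tsv"))):
        t = read_trace_tsv(f, frame_rate)
        t.metadata["trace_id"] = i
        traces.append(t)
    if not traces:
        raise FileNotFoundError(f"no trace_*.tsv files under {in_dir}")
    return traces, manifest


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
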