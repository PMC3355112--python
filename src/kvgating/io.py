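"""Tab-delimited episodic trace files with a commented header block.

Layout (in the spirit of the Axon Text File format): lines starting
with '#' hold metadata as ``# key<TAB>json-value``; the first data line
is a column header; columns are the shared time grid followed by one
current column per episode. A JSON sidecar (``<path>.json``) carries
provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .protocol import CurrentTrace

__all__ = ["write_episodic", "read_episodic"]


def write_episodic(path: str | Path, traces: Sequence[CurrentTrace],
                   provenance: dict | None = None) -> None:
    path = Path(path)
    if not traces:
        raise ValueError("no traces to write")
    t = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t.shape or not np.allclose(tr.time, t):
            raise ValueError("episodes must share a time grid")
    meta = {
        "kind": traces[0].kind,
        "units": traces[0].metadata.get("units", "pA"),
        "step_voltages": [tr.step_voltage for tr in traces],
        "segment_bounds": traces[0].metadata.get("segment_bounds"),
    }
    lines = [f"# {k}\t{json.dumps(v)}" for k, v in meta.items()]
    header = "time_ms\t" + "\t".join(
        f"I_{tr.step_voltage:g}mV" for tr in traces)
    lines.append(header)
    data = np.column_stack([t] + [tr.current for tr in traces])
    body = "\n".join("\t".join(f"{x:.10g}" for x in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    if provenance is not None:
        Path(str(path) + ".json").write_text(json.dumps(provenance, indent=2))


def read_episodic(path: str | Path) -> list[CurrentTrace]:
    path = Path(path)
    meta: dict = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key] = json.loads(val) if val else None
            elif line.startswith("time"):
                continue
            else:
                rows.append([float(x) for x in line.split("\t")])
    data = np.asarray(rows)
    t = data[:, 0]
    steps = meta.get("step_voltages") or list(range(data.shape[1] - 1))
    traces = []
    for j, sv in enumerate(steps, start=1):
        traces.append(CurrentTrace(
            time=t.copy(), current=data[:, j].copy(),
            step_voltage=float(sv), kind=meta.get("kind", "gating"),
            metadata={"units": meta.get("units", "pA"),
                      "segment_bounds": meta.get("segment_bounds")}))
    return traces
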