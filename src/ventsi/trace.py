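"""CSV persistence for experiment traces and breath waveforms.

All files use a fixed, locale-independent dialect: comma field
separator, ``.`` decimal point, ``\\n`` newlines, UTF-8.  Floats are
written with ``repr`` so a write/read round-trip reproduces every
value exactly (well within 1e-9).

Two formats are defined:

* **experiment trace** — one file holding a small metadata header
  (``# key=value`` lines), a ``# section=snapshots`` table (T0-T4
  measurement snapshots) and a ``# section=actions`` table (logged
  controller actions).
* **waveform CSV** — per-sample breath signals with columns
  ``breath_id,time_s,flow_lps,paw_cmh2o,ppl_cmh2o,volume_ml`` plus a
  metadata header carrying the occlusion readings per breath.
"""

from __future__ import annotations

import csv
import io
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .patient import BreathRecord
from .protocol import ExperimentTrace

TRACE_MAGIC = "ventsi-trace v1"
WAVEFORM_MAGIC = "ventsi-waveform v1"

#: Columns every snapshot table must provide.
SNAPSHOT_REQUIRED = ("T", "t_min", "vt_ml_kg", "rr", "si", "pplat", "ph", "paco2")
#: Columns every action table must provide.
ACTION_REQUIRED = ("time_s", "action")
#: Columns every waveform CSV must provide.
WAVEFORM_COLUMNS = ("breath_id", "time_s", "flow_lps", "paw_cmh2o", "ppl_cmh2o", "volume_ml")


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _parse_cell(text: str):
    if text == "":
        return math.nan
    if text == "true":
        return True
    if text == "false":
        return False
    try:
        f = float(text)
    except ValueError:
        return text
    if f.is_integer() and "." not in text and "e" not in text and "E" not in text:
        return int(f)
    return f


def _write_table(buf: io.StringIO, df: pd.DataFrame) -> None:
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(df.columns.tolist())
    for row in df.itertuples(index=False):
        writer.writerow([_fmt(v) for v in row])


def write_trace(trace: ExperimentTrace, path: str | Path) -> None:
    """Write an experiment trace to the sectioned-CSV trace format."""
    buf = io.StringIO()
    buf.write(f"# {TRACE_MAGIC}\n")
    buf.write(f"# arm={trace.arm}\n")
    buf.write(f"# ol_peep={_fmt(float(trace.ol_peep))}\n")
    buf.write("# section=snapshots\n")
    _write_table(buf, trace.snapshots)
    buf.write("# section=actions\n")
    _write_table(buf, trace.actions)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _require_columns(columns: list[str], required: tuple[str, ...],
                     section: str, line_no: int) -> None:
    missing = [c for c in required if c not in columns]
    if missing:
        raise TraceFormatError(
            f"line {line_no}: {section} table is missing column(s) {', '.join(missing)}"
        )


def _parse_section(lines: list[tuple[int, str]], section: str,
                   required: tuple[str, ...]) -> pd.DataFrame:
    if not lines:
        raise TraceFormatError(f"{section} section is empty")
    header_no, header_line = lines[0]
    columns = next(csv.reader([header_line]))
    _require_columns(columns, required, section, header_no)
    rows = []
    for line_no, line in lines[1:]:
        cells = next(csv.reader([line]))
        if len(cells) != len(columns):
            raise TraceFormatError(
                f"line {line_no}: expected {len(columns)} fields, got {len(cells)}"
            )
        rows.append({c: _parse_cell(v) for c, v in zip(columns, cells)})
    return pd.DataFrame(rows, columns=columns)


def read_trace(path: str | Path) -> ExperimentTrace:
    """Read an experiment trace written by :func:`write_trace`.

    Malformed files raise :class:`TraceFormatError` with the offending
    line number; a table missing a required column raises an error
    naming the column.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].strip() != f"# {TRACE_MAGIC}":
        raise TraceFormatError(f"line 1: expected header '# {TRACE_MAGIC}'")
    meta: dict[str, str] = {}
    sections: dict[str, list[tuple[int, str]]] = {}
    current: list[tuple[int, str]] | None = None
    for idx, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("# section="):
            name = line.split("=", 1)[1].strip()
            if name in sections:
                raise TraceFormatError(f"line {idx}: duplicate section {name!r}")
            current = sections.setdefault(name, [])
        elif line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise TraceFormatError(f"line {idx}: malformed metadata line")
            key, value = body.split("=", 1)
            meta[key.strip()] = value.strip()
        else:
            if current is None:
                raise TraceFormatError(f"line {idx}: data before any section header")
            current.append((idx, line))
    for required_section in ("snapshots", "actions"):
        if required_section not in sections:
            raise TraceFormatError(f"missing section {required_section!r}")
    if "arm" not in meta or "ol_peep" not in meta:
        raise TraceFormatError("missing metadata key 'arm' or 'ol_peep'")
    snapshots = _parse_section(sections["snapshots"], "snapshots", SNAPSHOT_REQUIRED)
    actions = _parse_section(sections["actions"], "actions", ACTION_REQUIRED)
    try:
        ol_peep = float(meta["ol_peep"])
    except ValueError as exc:
        raise TraceFormatError(f"ol_peep metadata is not a number: {meta['ol_peep']!r}") from exc
    return ExperimentTrace(arm=meta["arm"], ol_peep=ol_peep,
                           snapshots=snapshots, actions=actions)


def write_waveform(breaths: list[BreathRecord] | BreathRecord, path: str | Path) -> None:
    """Write one or more breaths to the waveform CSV dialect."""
    if isinstance(breaths, BreathRecord):
        breaths = [breaths]
    buf = io.StringIO()
    buf.write(f"# {WAVEFORM_MAGIC}\n")
    occl = [
        {
            "breath_id": i,
            "pplat": b.pplat, "total_peep": b.total_peep,
            "ppl_ei": b.ppl_ei, "ppl_ee": b.ppl_ee,
            "sample_rate": b.sample_rate, "vt_ml": b.vt_ml,
        }
        for i, b in enumerate(breaths)
    ]
    buf.write(f"# occlusions={json.dumps(occl)}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(WAVEFORM_COLUMNS)
    for i, b in enumerate(breaths):
        for t, q, paw, ppl, v in zip(b.t, b.flow, b.paw, b.ppl, b.volume):
            writer.writerow([i, _fmt(float(t)), _fmt(float(q)),
                             _fmt(float(paw)), _fmt(float(ppl)), _fmt(float(v))])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_waveform(path: str | Path) -> list[BreathRecord]:
    """Read a waveform CSV back into :class:`BreathRecord` objects."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0].strip() != f"# {WAVEFORM_MAGIC}":
        raise TraceFormatError(f"line 1: expected header '# {WAVEFORM_MAGIC}'")
    occl: dict[int, dict] = {}
    data_lines: list[tuple[int, str]] = []
    for idx, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("# occlusions="):
            try:
                occl = {int(d["breath_id"]): d for d in json.loads(line.split("=", 1)[1])}
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise TraceFormatError(f"line {idx}: malformed occlusion metadata") from exc
        elif line.startswith("#"):
            continue
        else:
            data_lines.append((idx, line))
    if not data_lines:
        raise TraceFormatError("waveform file contains no data rows")
    header_no, header_line = data_lines[0]
    columns = next(csv.reader([header_line]))
    _require_columns(columns, WAVEFORM_COLUMNS, "waveform", header_no)
    col_idx = {c: columns.index(c) for c in WAVEFORM_COLUMNS}
    samples: dict[int, dict[str, list[float]]] = {}
    for line_no, line in data_lines[1:]:
        cells = next(csv.reader([line]))
        if len(cells) != len(columns):
            raise TraceFormatError(
                f"line {line_no}: expected {len(columns)} fields, got {len(cells)}"
            )
        try:
            bid = int(cells[col_idx["breath_id"]])
            vals = {c: float(cells[col_idx[c]]) for c in WAVEFORM_COLUMNS[1:]}
        except ValueError as exc:
            raise TraceFormatError(f"line {line_no}: non-numeric value") from exc
        rec = samples.setdefault(bid, {c: [] for c in WAVEFORM_COLUMNS[1:]})
        for c, v in vals.items():
            rec[c].append(v)
    breaths = []
    for bid in sorted(samples):
        s = samples[bid]
        meta = occl.get(bid, {})
        breaths.append(BreathRecord(
            t=np.array(s["time_s"]), flow=np.array(s["flow_lps"]),
            paw=np.array(s["paw_cmh2o"]), ppl=np.array(s["ppl_cmh2o"]),
            volume=np.array(s["volume_ml"]),
            pplat=float(meta.get("pplat", math.nan)),
            total_peep=float(meta.get("total_peep", math.nan)),
            ppl_ei=float(meta.get("ppl_ei", math.nan)),
            ppl_ee=float(meta.get("ppl_ee", math.nan)),
            sample_rate=float(meta.get("sample_rate", _infer_rate(s["time_s"]))),
            vt_ml=float(meta.get("vt_ml", 0.0)),
        ))
    return breaths


def _infer_rate(times: list[float]) -> float:
    if len(times) < 2:
        return math.nan
    return 1.0 / float(np.median(np.diff(times)))


def write_metrics(rows: list[dict], path: str | Path) -> None:
    """Write per-breath metrics rows to a plain CSV."""
    pd.DataFrame(rows).to_csv(path, index=False)
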